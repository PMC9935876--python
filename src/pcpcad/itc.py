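"""One-set-of-sites ITC isotherm: forward model, simulation, and fitting.

The Wiseman single-site model for a perfusion (constant-volume) cell:
``n`` identical independent sites per macromolecule, association constant
``K`` (1/M), enthalpy ``ΔH`` (cal/mol of injectant).  The cumulative heat
after bringing the cell to total concentrations Mt (macromolecule) and
Xt (titrant) is

    Q = (n·Mt·ΔH·V0 / 2) · [1 + Xt/(n·Mt) + 1/(n·K·Mt)
         − sqrt((1 + Xt/(n·Mt) + 1/(n·K·Mt))² − 4·Xt/(n·Mt))]

Each injection of volume dV displaces an equal volume of cell contents, so
running concentrations follow the discrete perfusion dilution
Mt_i = Mt0·Π(1 − dV_j/V0) and Xt_i = X0·(1 − Π(1 − dV_j/V0)), and the
measured per-injection heat carries the displaced-heat correction

    ΔQ_i = Q_i − Q_{i−1} + (dV_i/V0)·(Q_i + Q_{i−1})/2 + offset·X0·dV_i

where ``offset`` (cal/mol injectant) absorbs the dilution baseline.
The dimensionless c-value n·K·Mt0 governs curve sigmoidicity; fits outside
c ∈ [1, 1000] are low-information and flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "ITCParams",
    "Thermogram",
    "BindingFit",
    "default_injection_schedule",
    "running_concentrations",
    "one_site_cumulative_heat",
    "injection_heats",
    "simulate_thermogram",
    "fit_one_site",
    "fold_reduction",
    "average_kd",
    "ND",
]

ND = "ND"  # sentinel for non-binders, matching how null affinities are reported

# Study conditions: 30 µM macromolecule in a 200 µL cell, 300 µM titrant,
# an initial 0.4 µL discard injection followed by nineteen 2.0 µL injections.
DEFAULT_V0 = 200e-6  # L
DEFAULT_MT0 = 30e-6  # M
DEFAULT_X0 = 300e-6  # M
DEFAULT_TEMPERATURE = 293.15  # K (20 °C)


def default_injection_schedule(
    n_injections: int = 19, injection_uL: float = 2.0, discard_uL: float | None = 0.4
) -> list[float]:
    """Injection volumes in liters, optionally led by a small discard shot."""
    vols = [] if discard_uL is None else [discard_uL * 1e-6]
    vols += [injection_uL * 1e-6] * n_injections
    return vols


@dataclass
class ITCParams:
    n: float = 1.0  # sites per macromolecule
    K: float = 1e6  # association constant, 1/M
    delta_H: float = -10_000.0  # cal/mol injectant
    cell_volume_V0: float = DEFAULT_V0  # L
    cell_conc_Mt0: float = DEFAULT_MT0  # M
    syringe_conc_X0: float = DEFAULT_X0  # M
    injection_volumes: list[float] = field(default_factory=default_injection_schedule)
    temperature: float = DEFAULT_TEMPERATURE  # K
    heat_offset: float = 0.0  # cal/mol injectant

    def __post_init__(self) -> None:
        if self.n <= 0 or self.K <= 0:
            raise ValueError("n and K must be positive")
        if self.cell_volume_V0 <= 0 or self.cell_conc_Mt0 <= 0 or self.syringe_conc_X0 <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if not self.injection_volumes or any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be positive and non-empty")

    @property
    def Kd_uM(self) -> float:
        return 1e6 / self.K

    @property
    def c_value(self) -> float:
        return self.n * self.K * self.cell_conc_Mt0


@dataclass
class Thermogram:
    """Per-injection heats plus the cell metadata needed to fit them."""

    data: pd.DataFrame  # injection, volume_L, heat_ucal, molar_heat_cal_per_mol
    cell_volume_V0: float
    cell_conc_Mt0: float
    syringe_conc_X0: float
    temperature: float = DEFAULT_TEMPERATURE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        inj = self.data["injection"].to_numpy()
        if not np.all(np.diff(inj) > 0):
            raise ValueError("injection indices must be strictly increasing")
        if (self.data["volume_L"] <= 0).any():
            raise ValueError("injection volumes must be positive")

    def write(self, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.data.to_csv(csv_path, index=False)
        if meta_path is not None:
            Path(meta_path).write_text(
                json.dumps(
                    {
                        "cell_volume_V0": self.cell_volume_V0,
                        "cell_conc_Mt0": self.cell_conc_Mt0,
                        "syringe_conc_X0": self.syringe_conc_X0,
                        "temperature": self.temperature,
                        **self.metadata,
                    },
                    indent=2,
                )
            )

    @classmethod
    def read(cls, csv_path: str | Path, meta_path: str | Path) -> "Thermogram":
        df = pd.read_csv(csv_path)
        meta = json.loads(Path(meta_path).read_text())
        return cls(
            data=df,
            cell_volume_V0=float(meta["cell_volume_V0"]),
            cell_conc_Mt0=float(meta["cell_conc_Mt0"]),
            syringe_conc_X0=float(meta["syringe_conc_X0"]),
            temperature=float(meta.get("temperature", DEFAULT_TEMPERATURE)),
            metadata={k: v for k, v in meta.items()
                      if k not in {"cell_volume_V0", "cell_conc_Mt0",
                                   "syringe_conc_X0", "temperature"}},
        )


@dataclass
class BindingFit:
    n_hat: float
    Kd_uM: float
    delta_H_hat: float  # cal/mol
    offset_hat: float  # cal/mol injectant
    stderr: dict
    rss: float  # µcal²
    converged: bool
    c_value: float
    n_injections_used: int
    warnings: list[str] = field(default_factory=list)


def running_concentrations(
    injection_volumes: np.ndarray | list[float], V0: float, Mt0: float, X0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Total cell concentrations (Xt, Mt) after each injection, with the
    discrete perfusion displaced-volume correction."""
    dV = np.asarray(injection_volumes, dtype=float)
    dilution = np.cumprod(1.0 - dV / V0)
    Mt = Mt0 * dilution
    Xt = X0 * (1.0 - dilution)
    return Xt, Mt


def _wiseman_Q(Xt, Mt, n, K, dH, V0):
    r = Xt / (n * Mt)
    s = 1.0 / (n * K * Mt)
    term = 1.0 + r + s
    disc = term**2 - 4.0 * r
    if np.any(disc < 0):
        raise FloatingPointError("negative discriminant in the one-site isotherm")
    return (n * Mt * dH * V0 / 2.0) * (term - np.sqrt(disc))


def one_site_cumulative_heat(params: ITCParams, after_injection: int) -> float:
    """Cumulative heat Q (cal) in the cell after injection ``after_injection``
    (1-based; 0 returns 0)."""
    if after_injection < 0 or after_injection > len(params.injection_volumes):
        raise IndexError("injection index outside the schedule")
    if after_injection == 0:
        return 0.0
    Xt, Mt = running_concentrations(
        params.injection_volumes, params.cell_volume_V0,
        params.cell_conc_Mt0, params.syringe_conc_X0,
    )
    Q = _wiseman_Q(Xt, Mt, params.n, params.K, params.delta_H, params.cell_volume_V0)
    return float(Q[after_injection - 1])


def injection_heats(params: ITCParams) -> np.ndarray:
    """Measured per-injection heats ΔQ (cal), displaced-heat corrected,
    including the dilution-offset term."""
    dV = np.asarray(params.injection_volumes, dtype=float)
    Xt, Mt = running_concentrations(
        dV, params.cell_volume_V0, params.cell_conc_Mt0, params.syringe_conc_X0
    )
    Q = _wiseman_Q(Xt, Mt, params.n, params.K, params.delta_H, params.cell_volume_V0)
    Qprev = np.concatenate([[0.0], Q[:-1]])
    dQ = Q - Qprev + (dV / params.cell_volume_V0) * (Q + Qprev) / 2.0
    dQ = dQ + params.heat_offset * params.syringe_conc_X0 * dV
    return dQ


def simulate_thermogram(
    params: ITCParams, noise_sd_ucal: float = 0.0, seed: int = 0
) -> Thermogram:
    """Forward-model thermogram with i.i.d. Gaussian injection noise (µcal)."""
    if noise_sd_ucal < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    dV = np.asarray(params.injection_volumes, dtype=float)
    heats_ucal = injection_heats(params) * 1e6
    if noise_sd_ucal > 0:
        heats_ucal = heats_ucal + rng.normal(0.0, noise_sd_ucal, size=len(dV))
    moles = params.syringe_conc_X0 * dV
    df = pd.DataFrame(
        {
            "injection": np.arange(1, len(dV) + 1),
            "volume_L": dV,
            "heat_ucal": heats_ucal,
            "molar_heat_cal_per_mol": heats_ucal * 1e-6 / moles,
        }
    )
    return Thermogram(
        data=df,
        cell_volume_V0=params.cell_volume_V0,
        cell_conc_Mt0=params.cell_conc_Mt0,
        syringe_conc_X0=params.syringe_conc_X0,
        temperature=params.temperature,
        metadata={"simulated": True, "noise_sd_ucal": noise_sd_ucal, "seed": seed},
    )


def _model_heats_ucal(dV, V0, Mt0, X0, n, K, dH, offset):
    Xt, Mt = running_concentrations(dV, V0, Mt0, X0)
    Q = _wiseman_Q(Xt, Mt, n, K, dH, V0)
    Qprev = np.concatenate([[0.0], Q[:-1]])
    dQ = Q - Qprev + (dV / V0) * (Q + Qprev) / 2.0 + offset * X0 * dV
    return dQ * 1e6


def fit_one_site(
    thermogram: Thermogram,
    init: ITCParams | None = None,
    exclude_first: bool = True,
) -> BindingFit:
    """Least-squares fit of (n, K, ΔH, offset) to a thermogram.

    The first injection (typically a small discard shot) is excluded from
    the residuals by default but still contributes titrant to the running
    concentrations.
    """
    df = thermogram.data
    dV = df["volume_L"].to_numpy(dtype=float)
    heats = df["heat_ucal"].to_numpy(dtype=float)
    use = np.ones(len(dV), dtype=bool)
    if exclude_first and len(dV) > 1:
        use[0] = False
    if use.sum() < 6:
        raise ValueError("need at least 6 usable injections")
    V0, Mt0, X0 = (
        thermogram.cell_volume_V0,
        thermogram.cell_conc_Mt0,
        thermogram.syringe_conc_X0,
    )

    moles = X0 * dV
    molar = heats * 1e-6 / moles
    if init is not None:
        n0, K0, dH0, off0 = init.n, init.K, init.delta_H, init.heat_offset
    else:
        off0 = float(np.mean(molar[use][-2:]))
        dH0 = float(molar[use][0] - off0)
        if abs(dH0) < 1e-6:
            dH0 = -1000.0
        # midpoint heuristic: c ≈ 10 is a featureless but safe starting point
        K0 = 10.0 / Mt0
        n0 = 1.0

    p = lmfit.Parameters()
    p.add("n", value=n0, min=1e-3, max=100)
    p.add("log10K", value=np.log10(K0), min=1.0, max=12.0)
    p.add("dH", value=dH0)
    p.add("offset", value=off0)

    def residual(pars):
        model = _model_heats_ucal(
            dV, V0, Mt0, X0, pars["n"].value, 10.0 ** pars["log10K"].value,
            pars["dH"].value, pars["offset"].value,
        )
        return model[use] - heats[use]

    result = lmfit.minimize(residual, p, method="leastsq")
    converged = bool(result.success)
    warnings_list: list[str] = []
    if not converged:
        return BindingFit(
            n_hat=np.nan, Kd_uM=np.nan, delta_H_hat=np.nan, offset_hat=np.nan,
            stderr={}, rss=np.nan, converged=False,
            c_value=np.nan, n_injections_used=int(use.sum()),
            warnings=["fit did not converge"],
        )
    n_hat = float(result.params["n"].value)
    K_hat = float(10.0 ** result.params["log10K"].value)
    dH_hat = float(result.params["dH"].value)
    off_hat = float(result.params["offset"].value)
    c = n_hat * K_hat * Mt0
    if not (1.0 <= c <= 1000.0):
        warnings_list.append(
            f"c-value {c:.3g} outside [1, 1000]: low-information regime"
        )
    stderr = {}
    for name in ("n", "log10K", "dH", "offset"):
        se = result.params[name].stderr
        stderr[name] = float(se) if se is not None else np.nan
    # propagate log10K uncertainty to Kd (µM scale)
    if np.isfinite(stderr.get("log10K", np.nan)):
        stderr["Kd_uM"] = float(np.log(10) * stderr["log10K"] * 1e6 / K_hat)
    return BindingFit(
        n_hat=n_hat,
        Kd_uM=1e6 / K_hat,
        delta_H_hat=dH_hat,
        offset_hat=off_hat,
        stderr=stderr,
        rss=float(np.sum(result.residual**2)),
        converged=True,
        c_value=float(c),
        n_injections_used=int(use.sum()),
        warnings=warnings_list,
    )


def fold_reduction(
    fit_mutant: BindingFit, fit_wildtype: BindingFit, nd_threshold_uM: float = 1000.0
) -> float | str:
    """Kd(mutant) / Kd(wild type); mutants beyond ``nd_threshold_uM``, or whose
    heats are too small for the fit to converge, are reported as the ``"ND"``
    sentinel, never infinity.  An unconverged wild-type reference is an error."""
    if not fit_wildtype.converged:
        raise ValueError("wild-type fit did not converge")
    if (
        not fit_mutant.converged
        or not np.isfinite(fit_mutant.Kd_uM)
        or fit_mutant.Kd_uM > nd_threshold_uM
    ):
        return ND
    return float(fit_mutant.Kd_uM / fit_wildtype.Kd_uM)


def average_kd(fits: list[BindingFit]) -> tuple[float, float]:
    """Replicate-averaged Kd (µM): arithmetic mean and half-range."""
    kds = [f.Kd_uM for f in fits if f.converged]
    if not kds:
        raise ValueError("no converged fits to average")
    return float(np.mean(kds)), float((max(kds) - min(kds)) / 2.0)
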