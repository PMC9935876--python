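"""One-site isotherm: closed-form model vs an independent mass-action
equilibrium solver, and Monte-Carlo parameter recovery under the study's
injection protocol (30 µM cell, 300 µM syringe, 0.4 µL discard + 19 × 2 µL)."""

import numpy as np
import pytest

from pcpcad.itc import (
    ITCParams,
    average_kd,
    default_injection_schedule,
    fit_one_site,
    fold_reduction,
    injection_heats,
    one_site_cumulative_heat,
    running_concentrations,
    simulate_thermogram,
)

STUDY = dict(n=1.0, K=1e6 / 0.47, delta_H=-9000.0)


def mass_action_heats(params: ITCParams) -> np.ndarray:
    """Independent oracle: solve [complex] per injection from the
    mass-action quadratic (sites n·Mt, free titrant X − MX), then apply
    the same displaced-heat bookkeeping."""
    Xt, Mt = running_concentrations(
        params.injection_volumes, params.cell_volume_V0,
        params.cell_conc_Mt0, params.syringe_conc_X0,
    )
    Q = np.empty(len(Xt))
    for i, (x, m) in enumerate(zip(Xt, Mt)):
        sites = params.n * m
        b = sites + x + 1.0 / params.K
        mx = (b - np.sqrt(b * b - 4.0 * sites * x)) / 2.0
        Q[i] = mx * params.delta_H * params.cell_volume_V0
    dV = np.asarray(params.injection_volumes)
    Qprev = np.concatenate([[0.0], Q[:-1]])
    dQ = Q - Qprev + (dV / params.cell_volume_V0) * (Q + Qprev) / 2.0
    return dQ + params.heat_offset * params.syringe_conc_X0 * dV


def test_zero_enthalpy_means_zero_heat():
    p = ITCParams(delta_H=0.0)
    assert np.allclose(injection_heats(p), 0.0)
    assert one_site_cumulative_heat(p, len(p.injection_volumes)) == 0.0


def test_saturating_limit_all_ligand_binds():
    p = ITCParams(n=1.0, K=1e12, delta_H=-9000.0)
    Xt, Mt = running_concentrations(p.injection_volumes, p.cell_volume_V0,
                                    p.cell_conc_Mt0, p.syringe_conc_X0)
    # well below saturation all injected ligand is bound: Q ≈ ΔH·V0·Xt
    for i in range(1, 6):
        q = one_site_cumulative_heat(p, i)
        assert q == pytest.approx(p.delta_H * p.cell_volume_V0 * Xt[i - 1], rel=1e-4)


def test_closed_form_matches_mass_action_solver():
    p = ITCParams(**STUDY)
    np.testing.assert_allclose(injection_heats(p), mass_action_heats(p), rtol=1e-8)


def test_heat_magnitudes_decay_toward_saturation():
    p = ITCParams(**STUDY)
    dq = np.abs(injection_heats(p)[1:])  # skip the discard shot
    assert (np.diff(dq) < 0).all()


def test_injection_index_bounds():
    p = ITCParams(**STUDY)
    assert one_site_cumulative_heat(p, 0) == 0.0
    with pytest.raises(IndexError):
        one_site_cumulative_heat(p, len(p.injection_volumes) + 1)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        ITCParams(n=-1.0)
    with pytest.raises(ValueError):
        ITCParams(K=0.0)
    with pytest.raises(ValueError):
        ITCParams(injection_volumes=[])


def test_simulation_noiseless_equals_model_and_seeded():
    p = ITCParams(**STUDY)
    tg0 = simulate_thermogram(p, 0.0, seed=1)
    np.testing.assert_allclose(tg0.data.heat_ucal.to_numpy(),
                               injection_heats(p) * 1e6, rtol=1e-12)
    tg1 = simulate_thermogram(p, 0.5, seed=42)
    tg2 = simulate_thermogram(p, 0.5, seed=42)
    assert tg1.data.equals(tg2.data)
    tg3 = simulate_thermogram(p, 0.5, seed=43)
    assert not tg1.data.heat_ucal.equals(tg3.data.heat_ucal)


def test_simulation_noise_is_unbiased():
    p = ITCParams(**STUDY)
    clean = injection_heats(p)[5] * 1e6
    sims = [simulate_thermogram(p, 0.5, seed=s).data.heat_ucal.iloc[5]
            for s in range(300)]
    se = 0.5 / np.sqrt(300)
    assert abs(np.mean(sims) - clean) < 3 * se


def test_noiseless_fit_recovers_parameters_exactly():
    p = ITCParams(**STUDY, heat_offset=-150.0)
    fit = fit_one_site(simulate_thermogram(p, 0.0, seed=0))
    assert fit.converged
    assert fit.n_hat == pytest.approx(1.0, rel=1e-6)
    assert fit.Kd_uM == pytest.approx(0.47, rel=1e-6)
    assert fit.delta_H_hat == pytest.approx(-9000.0, rel=1e-6)
    assert fit.offset_hat == pytest.approx(-150.0, rel=1e-4)


def test_exothermic_sign_preserved():
    p = ITCParams(n=1.0, K=2e6, delta_H=-7500.0)
    fit = fit_one_site(simulate_thermogram(p, 0.1, seed=3))
    assert fit.converged and fit.delta_H_hat < 0


def test_c_value_warning_outside_informative_range():
    p = ITCParams(n=1.0, K=1e4, delta_H=-9000.0)  # c = 0.3
    fit = fit_one_site(simulate_thermogram(p, 0.0, seed=0))
    assert fit.converged
    assert any("c-value" in w for w in fit.warnings)


def test_too_few_injections_rejected():
    p = ITCParams(**STUDY, injection_volumes=default_injection_schedule(5))
    with pytest.raises(ValueError, match="6 usable"):
        fit_one_site(simulate_thermogram(p, 0.0, seed=0))


def test_scale_equivariance_of_isotherm_shape():
    """Doubling both concentrations while halving K keeps the c-value and
    the dimensionless shape; heats simply double."""
    p1 = ITCParams(**STUDY)
    p2 = ITCParams(n=1.0, K=STUDY["K"] / 2, delta_H=-9000.0,
                   cell_conc_Mt0=2 * p1.cell_conc_Mt0,
                   syringe_conc_X0=2 * p1.syringe_conc_X0)
    assert p2.c_value == pytest.approx(p1.c_value)
    np.testing.assert_allclose(injection_heats(p2), 2 * injection_heats(p1), rtol=1e-10)


def test_kd_bias_vanishes_with_noise():
    p = ITCParams(**STUDY)
    max_heat = np.abs(injection_heats(p)).max() * 1e6
    med_err = {}
    for frac in (0.001, 0.02):
        errs = [
            abs(fit_one_site(simulate_thermogram(p, frac * max_heat, seed=s)).Kd_uM
                / 0.47 - 1.0)
            for s in range(25)
        ]
        med_err[frac] = np.median(errs)
    assert med_err[0.001] < 0.01
    assert med_err[0.001] < med_err[0.02]


def test_monte_carlo_kd_recovery_at_c60():
    """2% injection noise at c ≈ 64: the median relative Kd error over many
    seeds stays under 10%."""
    p = ITCParams(**STUDY)
    assert 50 < p.c_value < 70
    sd = 0.02 * np.abs(injection_heats(p)).max() * 1e6
    errs = [
        abs(fit_one_site(simulate_thermogram(p, sd, seed=s)).Kd_uM / 0.47 - 1.0)
        for s in range(100)
    ]
    assert np.median(errs) < 0.10


def test_fold_reduction_basics():
    p_wt = ITCParams(n=1.0, K=1e6 / 0.5, delta_H=-9000.0)
    fit_wt = fit_one_site(simulate_thermogram(p_wt, 0.0, seed=0))
    p_mut = ITCParams(n=1.0, K=1e6 / 1.0, delta_H=-9000.0)
    fit_mut = fit_one_site(simulate_thermogram(p_mut, 0.0, seed=0))
    assert fold_reduction(fit_mut, fit_wt) == pytest.approx(2.0, rel=1e-5)
    assert fold_reduction(fit_wt, fit_wt) == pytest.approx(1.0, rel=1e-9)


def test_fold_reduction_nine_fold_end_to_end():
    """Simulated wild type at 0.5 µM and mutant at 4.5 µM, both fitted from
    noisy thermograms: the recovered ratio lands on the planted 9×."""
    p_wt = ITCParams(n=1.0, K=1e6 / 0.5, delta_H=-9000.0)
    p_mut = ITCParams(n=1.0, K=1e6 / 4.5, delta_H=-9000.0)
    sd = 0.02 * np.abs(injection_heats(p_wt)).max() * 1e6
    ratios = []
    for s in range(5):
        f_wt = fit_one_site(simulate_thermogram(p_wt, sd, seed=s))
        f_mut = fit_one_site(simulate_thermogram(p_mut, sd, seed=s + 500))
        ratios.append(fold_reduction(f_mut, f_wt))
    assert np.median(ratios) == pytest.approx(9.0, rel=0.15)


def test_non_binder_reported_as_nd():
    p_wt = ITCParams(n=1.0, K=1e6 / 0.5, delta_H=-9000.0)
    fit_wt = fit_one_site(simulate_thermogram(p_wt, 0.0, seed=0))
    p_null = ITCParams(n=1.0, K=100.0, delta_H=-9000.0)  # Kd = 10 mM
    fit_null = fit_one_site(simulate_thermogram(p_null, 0.0, seed=0))
    assert fold_reduction(fit_null, fit_wt) == "ND"


def test_replicate_averaging():
    p = ITCParams(**STUDY)
    sd = 0.02 * np.abs(injection_heats(p)).max() * 1e6
    fits = [fit_one_site(simulate_thermogram(p, sd, seed=s)) for s in (1, 2)]
    mean, half_range = average_kd(fits)
    kds = sorted(f.Kd_uM for f in fits)
    assert mean == pytest.approx(sum(kds) / 2)
    assert half_range == pytest.approx((kds[1] - kds[0]) / 2)


def test_thermogram_round_trip(tmp_path):
    p = ITCParams(**STUDY)
    tg = simulate_thermogram(p, 0.3, seed=8)
    tg.write(tmp_path / "tg.csv", tmp_path / "tg.json")
    from pcpcad.itc import Thermogram

    tg2 = Thermogram.read(tmp_path / "tg.csv", tmp_path / "tg.json")
    np.testing.assert_allclose(tg2.data.heat_ucal, tg.data.heat_ucal)
    assert tg2.cell_conc_Mt0 == tg.cell_conc_Mt0
    fit = fit_one_site(tg2)
    assert fit.converged
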