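"""Rigid superposition, RMSD, and interdomain tilt geometry.

Kabsch least-squares superposition (proper rotations only, via SVD with a
determinant correction) plus the tilt-angle measurement used to compare
the bent EC1 conformations of multidomain cadherins: align two structures
on a shared block of domains (EC2–EC3 by default), then measure the angle
between their EC1 long axes.

A domain's axis points from the centroid of its N-terminal third of Cα
atoms toward the centroid of its C-terminal third; this fixes the sign
ambiguity an inertia eigenvector would have.  An inertia-axis mode is
available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .structure import Structure

__all__ = [
    "SuperpositionResult",
    "DomainAxis",
    "kabsch_superpose",
    "pair_common_residues",
    "domain_axis",
    "ec1_tilt_angle",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float  # Å
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class DomainAxis:
    domain: str
    centroid: np.ndarray
    axis: np.ndarray  # unit vector, N-terminal third -> C-terminal third


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Optimal proper rotation/translation mapping ``mobile`` onto
    ``reference`` (paired rows), minimizing RMSD."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(
            f"paired (n, 3) coordinate sets required, got {mobile.shape} vs {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    X = mobile - cm
    Y = reference - cr
    if np.linalg.matrix_rank(X, tol=1e-8) < 2:
        raise ValueError("points are collinear; superposition is degenerate")
    H = X.T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    diff = (mobile @ R.T + t) - reference
    rmsd = float(np.sqrt(np.einsum("ij,ij->", diff, diff) / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def pair_common_residues(
    struct_A: Structure,
    struct_B: Structure,
    atom_name: str = "CA",
    chain_map: Mapping[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair atoms across two structures by (chain, residue number, insertion
    code, atom name); order-independent.

    ``chain_map`` maps chains of A onto equivalent chains of B (identity by
    default).  Returns (coords_A, coords_B, n_unpaired) where unpaired counts
    residues present in exactly one structure.
    """
    if chain_map is None:
        chain_map = {c: c for c in struct_A.chains}
    index_B = {
        (b.chain_id, b.residue_number, b.insertion_code): b.coords
        for b in struct_B.atoms
        if b.atom_name == atom_name and not b.is_hetero
    }
    pairs_A, pairs_B = [], []
    n_unpaired = 0
    matched_keys = set()
    for a in struct_A.atoms:
        if a.atom_name != atom_name or a.is_hetero:
            continue
        if a.chain_id not in chain_map:
            continue
        key = (chain_map[a.chain_id], a.residue_number, a.insertion_code)
        if key in index_B:
            pairs_A.append(a.coords)
            pairs_B.append(index_B[key])
            matched_keys.add(key)
        else:
            n_unpaired += 1
    n_unpaired += sum(1 for key in index_B if key not in matched_keys
                      and key[0] in set(chain_map.values()))
    if not pairs_A:
        raise ValueError("no common residues between the two structures")
    return np.array(pairs_A), np.array(pairs_B), n_unpaired


def domain_axis(
    structure: Structure, chain: str, domain: str, mode: str = "terminal_thirds"
) -> DomainAxis:
    """Long axis of one EC domain from its Cα trace."""
    cas = [
        a for a in structure.atoms
        if a.chain_id == chain and a.domain == domain and a.atom_name == "CA"
    ]
    if len(cas) < 6:
        raise ValueError(
            f"domain {chain}/{domain} has {len(cas)} Cα atoms; need >= 6 for an axis"
        )
    cas.sort(key=lambda a: (a.residue_number, a.insertion_code))
    coords = np.array([a.coords for a in cas])
    centroid = coords.mean(axis=0)
    if mode == "terminal_thirds":
        third = max(2, len(coords) // 3)
        vec = coords[-third:].mean(axis=0) - coords[:third].mean(axis=0)
    elif mode == "inertia":
        centered = coords - centroid
        _, _, Vt = np.linalg.svd(centered)
        vec = Vt[0]
        # orient along the N->C direction to fix the eigenvector sign
        if np.dot(vec, coords[-1] - coords[0]) < 0:
            vec = -vec
    else:
        raise ValueError(f"unknown axis mode {mode!r}")
    norm = np.linalg.norm(vec)
    if norm < 1e-9:
        raise ValueError(f"degenerate axis for domain {chain}/{domain}")
    return DomainAxis(domain=domain, centroid=centroid, axis=vec / norm)


def _domain_cas(structure: Structure, chain: str, domains: Sequence[str]) -> dict:
    out = {}
    for a in structure.atoms:
        if a.chain_id == chain and a.atom_name == "CA" and a.domain in domains:
            out[(a.residue_number, a.insertion_code)] = a.coords
    return out


def ec1_tilt_angle(
    query: Structure,
    reference: Structure,
    query_chain: str,
    reference_chain: str,
    align_on: Sequence[str] = ("EC2", "EC3"),
    domain: str = "EC1",
    axis_mode: str = "terminal_thirds",
) -> float:
    """Tilt of ``domain`` in ``query`` relative to ``reference`` after
    aligning both on the Cα atoms of ``align_on`` domains.

    Structures must be domain-annotated.  The alignment pairs Cα atoms by
    residue number within the shared domains; the returned angle is
    arccos of the dot product of the two domain axes, in [0°, 180°].
    """
    for st, ch in ((query, query_chain), (reference, reference_chain)):
        doms = {a.domain for a in st.atoms if a.chain_id == ch}
        missing = [d for d in list(align_on) + [domain] if d not in doms]
        if missing:
            raise ValueError(f"structure {st.id!r} chain {ch} lacks domains {missing}")
    cas_q = _domain_cas(query, query_chain, align_on)
    cas_r = _domain_cas(reference, reference_chain, align_on)
    common = sorted(set(cas_q) & set(cas_r))
    if len(common) < 3:
        raise ValueError("fewer than 3 shared alignment residues")
    sup = kabsch_superpose(
        np.array([cas_q[k] for k in common]), np.array([cas_r[k] for k in common])
    )
    ax_q = domain_axis(query, query_chain, domain, axis_mode).axis
    ax_q = sup.rotation @ ax_q
    ax_r = domain_axis(reference, reference_chain, domain, axis_mode).axis
    cosang = float(np.clip(np.dot(ax_q, ax_r), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))
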