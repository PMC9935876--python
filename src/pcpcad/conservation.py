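"""MSA conservation scoring, interface painting, and Fj phosphomotif scanning.

Conservation is scored per alignment column, on [0, 1], either as
normalized Shannon entropy (1 − H/ln 20, gaps excluded from frequencies;
the default) or as a min–max-normalized mean BLOSUM62 sum-of-pairs score.
Scores are graded into 9 equal-width categories, mirroring the 9-grade
convention of conservation-painting servers so painted structures are
directly comparable.

The Four-jointed kinase recognition motif D-X-N-D-[X]7-S/T is scanned with
overlapping matches; the terminal S/T is the predicted extracellular
phosphosite.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

from .contacts import InterfaceReport
from .structure import Structure

__all__ = [
    "MSA",
    "ConservationProfile",
    "MotifMatch",
    "read_msa",
    "column_conservation",
    "scan_fj_motif",
    "paint_interface",
    "FJ_MOTIF_PATTERN",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = "-."
FJ_MOTIF_PATTERN = re.compile(r"(?=(D[A-Z]ND[A-Z]{7}[ST]))")


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]  # aligned, upper-case

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        alphabet = set(AMINO_ACIDS + GAP_CHARS + "X")
        for rid, row in zip(self.ids, self.rows):
            bad = sorted(set(row.upper()) - alphabet)
            if bad:
                raise ValueError(f"row {rid!r} has invalid characters: {bad}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def ungapped(self, row_id: str) -> str:
        row = self.rows[self.ids.index(row_id)]
        return "".join(c for c in row if c not in GAP_CHARS)


@dataclass
class ConservationProfile:
    per_column_score: np.ndarray  # [0, 1]; NaN where gap-only
    per_column_category: np.ndarray  # 1..9; 0 where gap-only
    gap_only: np.ndarray  # bool mask
    low_confidence: np.ndarray  # bool, > 50% gaps
    reference_row: str
    column_to_ref_position: list[int | None]  # 1-based ungapped ref position
    method: str = "entropy"


@dataclass(frozen=True)
class MotifMatch:
    start: int  # 1-based position in the ungapped sequence
    matched_span: str  # 12 residues
    phospho_site_position: int  # start + 11, the terminal S/T


def read_msa(path: str | Path, fmt: str | None = None) -> MSA:
    """Read a FASTA or Stockholm alignment."""
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in {".sto", ".stk", ".stockholm"} else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return MSA(ids=[rec.id for rec in aln], rows=[str(rec.seq) for rec in aln])


def _categories(scores: np.ndarray) -> np.ndarray:
    cats = np.zeros(len(scores), dtype=int)
    ok = np.isfinite(scores)
    cats[ok] = np.clip(np.ceil(scores[ok] * 9.0), 1, 9).astype(int)
    return cats


def column_conservation(
    msa: MSA, method: str = "entropy", reference_row: str | None = None
) -> ConservationProfile:
    """Per-column conservation on [0, 1].

    ``entropy``: 1 − H(column)/ln 20 with gap characters excluded from the
    frequency counts.  ``sop_blosum``: mean BLOSUM62 score over all row
    pairs, min–max normalized across columns.  Gap-only columns are flagged
    and left unscored (NaN).
    """
    if reference_row is None:
        reference_row = msa.ids[0]
    n_rows = len(msa.rows)
    L = msa.length
    scores = np.full(L, np.nan)
    gap_only = np.zeros(L, dtype=bool)
    low_conf = np.zeros(L, dtype=bool)

    columns = ["".join(row[c] for row in msa.rows) for c in range(L)]
    gap_frac = np.array(
        [sum(ch in GAP_CHARS for ch in col) / n_rows for col in columns]
    )
    gap_only[:] = gap_frac == 1.0
    low_conf[:] = gap_frac > 0.5

    if method == "entropy":
        for c, col in enumerate(columns):
            residues = [ch for ch in col if ch not in GAP_CHARS]
            if not residues:
                continue
            _, counts = np.unique(residues, return_counts=True)
            p = counts / counts.sum()
            H = -np.sum(p * np.log(p))
            scores[c] = 1.0 - H / np.log(20.0)
    elif method == "sop_blosum":
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        raw = np.full(L, np.nan)
        for c, col in enumerate(columns):
            residues = [ch for ch in col if ch not in GAP_CHARS and ch != "X"]
            if len(residues) < 2:
                continue
            total, npairs = 0.0, 0
            for i in range(len(residues)):
                for j in range(i + 1, len(residues)):
                    total += blosum[residues[i], residues[j]]
                    npairs += 1
            raw[c] = total / npairs
        ok = np.isfinite(raw)
        if ok.any():
            lo, hi = raw[ok].min(), raw[ok].max()
            scores[ok] = (raw[ok] - lo) / (hi - lo) if hi > lo else 1.0
    else:
        raise ValueError(f"unknown conservation method {method!r}")

    ref = msa.rows[msa.ids.index(reference_row)]
    col_to_ref: list[int | None] = []
    pos = 0
    for ch in ref:
        if ch in GAP_CHARS:
            col_to_ref.append(None)
        else:
            pos += 1
            col_to_ref.append(pos)
    return ConservationProfile(
        per_column_score=scores,
        per_column_category=_categories(scores),
        gap_only=gap_only,
        low_confidence=low_conf,
        reference_row=reference_row,
        column_to_ref_position=col_to_ref,
        method=method,
    )


def scan_fj_motif(sequence: str) -> list[MotifMatch]:
    """All (possibly overlapping) D-X-N-D-[X]7-S/T matches in an ungapped
    amino-acid sequence; positions are 1-based."""
    seq = sequence.upper()
    bad = sorted(set(seq) - set(AMINO_ACIDS))
    if bad:
        raise ValueError(f"invalid amino-acid characters: {bad}")
    if len(seq) < 12:
        return []
    out = []
    for m in FJ_MOTIF_PATTERN.finditer(seq):
        span = m.group(1)
        start = m.start() + 1
        out.append(MotifMatch(start=start, matched_span=span,
                              phospho_site_position=start + 11))
    return out


def paint_interface(
    profile: ConservationProfile,
    structure: Structure,
    interface: InterfaceReport,
    chain: str,
    numbering_offset: int = 0,
    buried_residues: set[int] | None = None,
) -> pd.DataFrame:
    """Project conservation onto one chain's residues and mark the interface.

    Residue ``r`` of the structure maps to ungapped reference position
    ``r − numbering_offset``.  Interface residues are those appearing in any
    contact record for the chain, plus any in ``buried_residues`` (e.g., a
    burial footprint from the SASA stage).  Returns one row per residue:
    (chain, residue_number, residue_name, domain, is_interface, score,
    category).
    """
    pos_to_score: dict[int, float] = {}
    pos_to_cat: dict[int, int] = {}
    for col, refpos in enumerate(profile.column_to_ref_position):
        if refpos is not None:
            pos_to_score[refpos] = float(profile.per_column_score[col])
            pos_to_cat[refpos] = int(profile.per_column_category[col])

    iface: set[int] = set(buried_residues or ())
    for rec in interface.contacts:
        for atom in (rec.atom_A, rec.atom_B):
            if atom.chain_id == chain:
                iface.add(atom.residue_number)

    rows = []
    unmapped_first: int | None = None
    for key, atoms in structure.residues(chain=chain).items():
        if atoms[0].is_hetero:
            continue
        resnum = key[1]
        refpos = resnum - numbering_offset
        if refpos not in pos_to_score:
            if unmapped_first is None:
                unmapped_first = resnum
            continue
        rows.append(
            {
                "chain": chain,
                "residue_number": resnum,
                "residue_name": atoms[0].residue_name,
                "domain": atoms[0].domain,
                "is_interface": resnum in iface,
                "score": pos_to_score[refpos],
                "category": pos_to_cat[refpos],
            }
        )
    if not rows:
        raise ValueError(
            f"no residues of chain {chain} map onto reference "
            f"{profile.reference_row!r} (first failing residue: {unmapped_first})"
        )
    return pd.DataFrame(rows)
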