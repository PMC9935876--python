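"""Synthetic fixtures with planted ground truth for every pipeline stage.

Three generators replace the study's raw data:

* :func:`make_toy_complex` — two antiparallel bead-on-string poly-alanine
  chains segmented into EC-like domains, with interchain contacts planted
  at exact distances and an optional hinge bend of one domain.  Geometry is
  deliberately toy-like: every downstream operator depends only on
  distances, labels and axes, not on fold realism.
* :func:`make_msa` — alignments with controlled per-column conservation and
  an optionally planted D-X-N-D-[X]7-S/T phosphomotif.
* :func:`make_cell_image` — a Voronoi cell mosaic whose true boundary
  polylines are known, with tunable per-channel enrichment of signal along
  the cell–cell borders.

All generators are deterministic under their seed, and each returns enough
ground truth to compute the expected downstream results in closed form or
by brute force.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi
from shapely.geometry import LineString, box

from .borders import BoundarySet, rasterize_boundaries
from .structure import AtomRecord, DomainAnnotation, DomainRange, Structure, load_vdw_radii

__all__ = [
    "SyntheticComplexSpec",
    "SyntheticImageSpec",
    "make_toy_complex",
    "make_msa",
    "make_cell_image",
    "write_fixture_suite",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticComplexSpec:
    domains_per_chain: int = 4
    residues_per_domain: int = 12
    # (domain_A, domain_B, kind, distance Å); kinds: hbond, salt_bridge, vdw
    planted_contacts: list[tuple[str, str, str, float]] = field(default_factory=list)
    hinge_bend: tuple[str, float] | None = None  # (chain-A domain, degrees)
    chain_separation: float = 30.0  # Å between chain axes
    seed: int = 0
    jitter: float = 0.0  # Å of coordinate noise (0 keeps geometry exact)

    def __post_init__(self) -> None:
        if self.domains_per_chain < 1 or self.residues_per_domain < 4:
            raise ValueError("need >=1 domain and >=4 residues per domain")
        for *_, d in [c for c in self.planted_contacts]:
            if d <= 0:
                raise ValueError("planted contact distances must be positive")
        if self.hinge_bend is not None and not (0.0 <= self.hinge_bend[1] <= 180.0):
            raise ValueError("hinge bend must be within [0, 180] degrees")


@dataclass
class SyntheticImageSpec:
    image_shape: tuple[int, int] = (128, 128)
    n_cells: int = 6
    border_enrichment_factor: tuple[float, float] = (5.0, 5.0)
    background_level: float = 100.0
    noise_sd: float = 5.0
    boundary_width: float = 2.0  # px, plateau half-width of the border kernel
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_shape) < 16:
            raise ValueError("image too small")
        if any(f < 0 or not np.isfinite(f) for f in self.border_enrichment_factor):
            raise ValueError("enrichment factors must be finite and >= 0")
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells to have a boundary")


_HELIX_RISE = 1.5  # Å per residue
_HELIX_RADIUS = 2.3  # Å
_HELIX_TWIST = np.deg2rad(100.0)

# local heavy-atom offsets from CA, rotated with the helical twist
_LOCAL_OFFSETS = {
    "N": np.array([1.2, -0.9, -0.6]),
    "C": np.array([1.3, 0.7, 0.6]),
    "O": np.array([2.0, 1.2, 1.1]),
    "CB": np.array([-1.4, 0.8, 0.0]),
}
_PLANT_ATOMS = {"hbond": ("N", "O"), "salt_bridge": ("NZ", "OE1"), "vdw": ("CB", "CB")}
_PLANT_RESNAMES = {"hbond": ("ALA", "ALA"), "salt_bridge": ("LYS", "GLU"), "vdw": ("ALA", "ALA")}
_PLANT_STUB = 4.0  # Å from CA to the planted sidechain/backbone atom


def _rotz(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _chain_atoms(chain_id: str, n_dom: int, n_res: int, radii: dict) -> list[AtomRecord]:
    atoms = []
    for i in range(n_dom * n_res):
        resnum = i + 1
        domain_idx = i // n_res
        angle = i * _HELIX_TWIST
        ca = np.array(
            [_HELIX_RADIUS * np.cos(angle), _HELIX_RADIUS * np.sin(angle), i * _HELIX_RISE]
        )
        R = _rotz(angle)
        for name in ("N", "CA", "C", "O", "CB"):
            pos = ca if name == "CA" else ca + R @ _LOCAL_OFFSETS[name]
            element = name[0]
            atoms.append(
                AtomRecord(
                    chain_id=chain_id,
                    residue_number=resnum,
                    insertion_code="",
                    residue_name="ALA",
                    atom_name=name,
                    element=element,
                    coords=pos,
                    vdw_radius=radii.get(element, radii["default"]),
                )
            )
    return atoms


def make_toy_complex(
    spec: SyntheticComplexSpec,
) -> tuple[Structure, DomainAnnotation, list[dict]]:
    """Two-chain toy complex with planted contacts and optional hinge bend.

    Chains are named A and B; domains EC1..ECn from the N terminus, residues
    numbered consecutively from 1 on each chain.  Raises when a planted
    contact is geometrically contradictory (another interchain pair would
    come closer than the planted one, or closer than the detection cutoffs).
    """
    radii = load_vdw_radii()
    n_dom, n_res = spec.domains_per_chain, spec.residues_per_domain
    domains = [f"EC{i + 1}" for i in range(n_dom)]
    bad = [d for pc in spec.planted_contacts for d in pc[:2] if d not in domains]
    if bad:
        raise ValueError(f"planted contact references unknown domains: {sorted(set(bad))}")

    atoms_A = _chain_atoms("A", n_dom, n_res, radii)
    atoms_B = _chain_atoms("B", n_dom, n_res, radii)
    # antiparallel partner: flip z, offset along x
    flip = np.diag([1.0, -1.0, -1.0])
    z_top = (n_dom * n_res - 1) * _HELIX_RISE
    for a in atoms_B:
        a.coords = flip @ a.coords + np.array([spec.chain_separation, 0.0, z_top])

    annotation = DomainAnnotation(
        [
            DomainRange(ch, domains[d], d * n_res + 1, (d + 1) * n_res)
            for ch in ("A", "B")
            for d in range(n_dom)
        ]
    )

    index = {(a.chain_id, a.residue_number, a.atom_name): a for a in atoms_A + atoms_B}

    def mid_residue(domain: str) -> int:
        d = domains.index(domain)
        return d * n_res + n_res // 2 + 1

    # bend first so planted contact geometry survives the rotation
    if spec.hinge_bend is not None:
        dom, degrees = spec.hinge_bend
        if dom not in domains:
            raise ValueError(f"hinge domain {dom!r} not in chain")
        d = domains.index(dom)
        lo, hi = d * n_res + 1, (d + 1) * n_res
        # pivot at the junction with the neighbouring domain
        junction_res = hi if d < n_dom - 1 else lo
        pivot_z = (junction_res - 0.5) * _HELIX_RISE
        pivot = np.array([0.0, 0.0, pivot_z])
        theta = np.deg2rad(degrees)
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])  # about x, tilts the z-axis
        for a in atoms_A:
            if lo <= a.residue_number <= hi:
                a.coords = R @ (a.coords - pivot) + pivot

    truth: list[dict] = []
    for k_contact, (dom_A, dom_B, kind, dist) in enumerate(spec.planted_contacts):
        if kind not in _PLANT_ATOMS:
            raise ValueError(f"unknown planted contact kind {kind!r}")
        res_A, res_B = mid_residue(dom_A), mid_residue(dom_B)
        ca_A = index[("A", res_A, "CA")].coords
        ca_B = index[("B", res_B, "CA")].coords
        u = ca_B - ca_A
        gap = np.linalg.norm(u)
        if gap < dist + 2 * _PLANT_STUB:
            raise ValueError(
                f"planted distance {dist} Å incompatible with geometry: residues are "
                f"only {gap:.1f} Å apart"
            )
        u = u / gap
        # place the pair midway between the chains so it is the unique
        # nearest interchain approach (toy pseudo-linker, not a real
        # sidechain); successive contacts are offset laterally so planted
        # pairs never crowd each other
        perp = np.cross(u, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, np.array([1.0, 0.0, 0.0]))
        perp = perp / np.linalg.norm(perp)
        mid = (ca_A + ca_B) / 2.0 + perp * (8.0 * k_contact)
        pa = mid - u * (dist / 2.0)
        pb = mid + u * (dist / 2.0)
        name_A, name_B = _PLANT_ATOMS[kind]
        resname_A, resname_B = _PLANT_RESNAMES[kind]
        for chain_id, resnum, resname in (("A", res_A, resname_A), ("B", res_B, resname_B)):
            for a in (atoms_A if chain_id == "A" else atoms_B):
                if a.residue_number == resnum:
                    a.residue_name = resname
        atom_A = index.get(("A", res_A, name_A))
        if atom_A is None:
            atom_A = AtomRecord("A", res_A, "", resname_A, name_A, name_A[0], pa,
                                radii.get(name_A[0], radii["default"]))
            atoms_A.append(atom_A)
            index[("A", res_A, name_A)] = atom_A
        else:
            atom_A.coords = pa
        atom_B = index.get(("B", res_B, name_B))
        if atom_B is None:
            atom_B = AtomRecord("B", res_B, "", resname_B, name_B, name_B[0], pb,
                                radii.get(name_B[0], radii["default"]))
            atoms_B.append(atom_B)
            index[("B", res_B, name_B)] = atom_B
        else:
            atom_B.coords = pb
        truth.append(
            {
                "domain_A": dom_A,
                "domain_B": dom_B,
                "kind": kind,
                "distance": float(dist),
                "residue_A": res_A,
                "residue_B": res_B,
                "atom_A": name_A,
                "atom_B": name_B,
            }
        )

    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        for a in atoms_A + atoms_B:
            a.coords = a.coords + rng.normal(0.0, spec.jitter, 3)

    # stable sort keeps per-residue atom order; planted atoms join their residue
    atoms_A.sort(key=lambda a: a.residue_number)
    atoms_B.sort(key=lambda a: a.residue_number)
    structure = Structure(id="toy-complex", atoms=atoms_A + atoms_B,
                          metadata={"synthetic": True, "seed": spec.seed})

    # validate that planted pairs realise their domain-pair minima
    from scipy.spatial.distance import cdist

    c_A = np.array([a.coords for a in atoms_A])
    c_B = np.array([a.coords for a in atoms_B])
    all_d = cdist(c_A, c_B)
    planted_idx = set()
    for t in truth:
        i = next(k for k, a in enumerate(atoms_A)
                 if a.residue_number == t["residue_A"] and a.atom_name == t["atom_A"])
        j = next(k for k, b in enumerate(atoms_B)
                 if b.residue_number == t["residue_B"] and b.atom_name == t["atom_B"])
        planted_idx.add((i, j))
        if spec.jitter == 0 and not np.isclose(all_d[i, j], t["distance"], atol=1e-6):
            raise AssertionError("planted distance not realised")
        dom_mask = np.array(
            [annotation.domain_of("A", a.residue_number) == t["domain_A"] for a in atoms_A]
        )[:, None] & np.array(
            [annotation.domain_of("B", b.residue_number) == t["domain_B"] for b in atoms_B]
        )[None, :]
        if np.min(all_d[dom_mask]) < all_d[i, j] - 1e-9:
            raise ValueError(
                "contradictory spec: another pair in the same domain pair is closer "
                "than the planted contact"
            )
    unplanted = all_d.copy()
    for i, j in planted_idx:
        unplanted[i, j] = np.inf
    if np.min(unplanted) <= 4.5:  # widest detection cutoff
        raise ValueError(
            "contradictory spec: an unplanted interchain pair falls within contact range"
        )
    from .structure import assign_domains

    return assign_domains(structure, annotation), annotation, truth


def make_msa(
    n_rows: int,
    length: int,
    conserved_columns: set[int] | None = None,
    motif_plant: int | None = None,
    seed: int = 0,
):
    """Gap-free MSA with the given 0-based columns identical across rows,
    other columns i.i.d. uniform over the 20 residues, and an optional
    D-X-N-D-[X]7-S/T motif written into all rows at 1-based ``motif_plant``."""
    from .conservation import MSA

    if n_rows < 2:
        raise ValueError("need at least 2 rows")
    conserved_columns = conserved_columns or set()
    if conserved_columns and (min(conserved_columns) < 0 or max(conserved_columns) >= length):
        raise ValueError("conserved column index out of range")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    grid = aa[rng.integers(0, 20, size=(n_rows, length))]
    for c in sorted(conserved_columns):
        grid[:, c] = aa[rng.integers(0, 20)]
    if motif_plant is not None:
        p = motif_plant - 1
        if p < 0 or p + 11 >= length:
            raise ValueError("planted motif overruns the sequence end")
        for row in range(n_rows):
            grid[row, p], grid[row, p + 2], grid[row, p + 3] = "D", "N", "D"
            grid[row, p + 11] = "S" if rng.integers(0, 2) == 0 else "T"
            # keep the wildcard positions motif-free of accidental terminators
    rows = ["".join(r) for r in grid]
    return MSA(ids=[f"seq{i + 1}" for i in range(n_rows)], rows=rows)


def _voronoi_polylines(points: np.ndarray, shape: tuple[int, int]) -> list[np.ndarray]:
    """Finite Voronoi ridges between the given seed points, clipped to the
    image; mirrored ghost points bound every cell."""
    rows, cols = shape
    n = len(points)
    mirrored = [points]
    for axis, bound in ((0, 0.0), (0, rows - 1.0), (1, 0.0), (1, cols - 1.0)):
        m = points.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    clip = box(0.0, 0.0, rows - 1.0, cols - 1.0)
    polylines = []
    for (p, q), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n or q >= n or -1 in verts:
            continue
        seg = LineString(vor.vertices[verts])
        inter = seg.intersection(clip)
        if inter.is_empty or inter.length < 1.0:
            continue
        geoms = getattr(inter, "geoms", [inter])
        for g in geoms:
            if isinstance(g, LineString) and g.length >= 1.0:
                polylines.append(np.array(g.coords))
    if not polylines:
        raise ValueError("no cell boundaries fall inside the image")
    return polylines


def make_cell_image(
    spec: SyntheticImageSpec,
) -> tuple[np.ndarray, BoundarySet, dict]:
    """Two-channel cell-field image with known border enrichment.

    Intensity of channel c is ``background · (1 + (f_c − 1) · k(d))`` plus
    Gaussian noise (clipped at 0), where d is the distance to the nearest
    boundary and k plateaus at 1 within ``boundary_width`` pixels then
    decays as a Gaussian shoulder.  At the border the noiseless intensity
    is exactly f_c × background.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_shape
    margin = max(4.0, 0.1 * min(rows, cols))
    points = np.column_stack(
        [
            rng.uniform(margin, rows - 1 - margin, spec.n_cells),
            rng.uniform(margin, cols - 1 - margin, spec.n_cells),
        ]
    )
    polylines = _voronoi_polylines(points, spec.image_shape)
    boundaries = BoundarySet(polylines=polylines, image_shape=spec.image_shape)

    raster = rasterize_boundaries(boundaries)
    dist = ndimage.distance_transform_edt(~raster)
    w = spec.boundary_width
    shoulder = 1.5  # px, Gaussian falloff beyond the plateau
    kernel = np.where(dist <= w, 1.0, np.exp(-((dist - w) ** 2) / (2 * shoulder**2)))

    channels = []
    noiseless = []
    for f in spec.border_enrichment_factor:
        base = spec.background_level * (1.0 + (f - 1.0) * kernel)
        noiseless.append(base)
        img = base + rng.normal(0.0, spec.noise_sd, size=base.shape) if spec.noise_sd > 0 else base.copy()
        channels.append(np.clip(img, 0.0, None))
    truth = {
        "enrichment_factors": list(spec.border_enrichment_factor),
        "background_level": spec.background_level,
        "noiseless_channels": np.array(noiseless),
        "border_kernel": kernel,
        "seed_points": points,
    }
    return np.array(channels), boundaries, truth


def write_fixture_suite(outdir: str | Path, seed: int = 7) -> dict:
    """Write one fixture of every kind (PDB, domains JSON, FASTA MSA, TIFF
    image + boundary JSON, thermogram CSV + meta JSON); returns a manifest."""
    import tifffile

    from . import itc
    from .structure import write_structure

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    spec = SyntheticComplexSpec(
        planted_contacts=[("EC1", "EC2", "salt_bridge", 3.0), ("EC2", "EC3", "hbond", 3.0)],
        hinge_bend=("EC1", 30.0),
        seed=seed,
    )
    structure, annotation, truth = make_toy_complex(spec)
    write_structure(structure, outdir / "toy_complex.pdb")
    (outdir / "toy_domains.json").write_text(
        json.dumps(
            [
                {"chain": e.chain_id, "domain": e.domain, "start": e.start, "end": e.end}
                for e in annotation.entries
            ],
            indent=2,
        )
    )

    msa = make_msa(18, 60, conserved_columns=set(range(0, 30)), motif_plant=35, seed=seed)
    (outdir / "toy_msa.fasta").write_text(
        "".join(f">{i}\n{r}\n" for i, r in zip(msa.ids, msa.rows))
    )

    img_spec = SyntheticImageSpec(seed=seed)
    channels, boundaries, _ = make_cell_image(img_spec)
    tifffile.imwrite(outdir / "toy_cells.tif", channels.astype(np.float32))
    boundaries.to_json(outdir / "toy_boundaries.json")

    params = itc.ITCParams(K=1e6 / 0.47, delta_H=-9000.0)
    tg = itc.simulate_thermogram(params, noise_sd_ucal=0.05, seed=seed)
    tg.write(outdir / "toy_thermogram.csv", outdir / "toy_thermogram_meta.json")

    return {
        "structure": "toy_complex.pdb",
        "domains": "toy_domains.json",
        "msa": "toy_msa.fasta",
        "image": "toy_cells.tif",
        "boundaries": "toy_boundaries.json",
        "thermogram": "toy_thermogram.csv",
        "thermogram_meta": "toy_thermogram_meta.json",
        "planted_contacts": truth,
        "seed": seed,
    }
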