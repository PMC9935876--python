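"""Cell-boundary fluorescence statistics for trans-binding co-cultures.

Quantifies how much of each fluorescent protein accumulates on cell–cell
borders, and how much of the two-channel *complex* signal coincides there:

* the traced boundary polylines are rasterized (8-connected) and dilated
  with a disk slightly wider than the boundary itself, giving a binary
  edge mask;
* **border accumulation** = Σ intensity over the mask / total boundary
  length L (per channel);
* **border complexes** = Σ (blur(A)·blur(B)) over the mask / L, where both
  channels are Gaussian-blurred with the same sigma before multiplying —
  the product rewards co-localized signal only.

Normalizing by geometric polyline length (not mask area) makes values
comparable across images with different boundary geometries.  Group
comparison uses the classic pooled-variance unpaired t test, one-sided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, stats
from skimage.draw import line as draw_line
from skimage.morphology import dilation

__all__ = [
    "BoundarySet",
    "EdgeMask",
    "BorderStats",
    "GroupComparison",
    "make_edge_mask",
    "border_accumulation",
    "border_complexes",
    "border_stats",
    "compare_groups",
    "DEFAULT_DILATION_RADIUS",
    "DEFAULT_BLUR_SIGMA",
]

DEFAULT_DILATION_RADIUS = 3  # px, slightly wider than a typical boundary
DEFAULT_BLUR_SIGMA = 2.0  # px


@dataclass
class BoundarySet:
    """Traced cell–cell boundaries: 0-based (row, col) vertex polylines."""

    polylines: list[np.ndarray]  # each (k, 2) float, row-major pixel coords
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.polylines = [np.asarray(p, dtype=float).reshape(-1, 2) for p in self.polylines]
        rows, cols = self.image_shape
        for p in self.polylines:
            if len(p) < 2:
                raise ValueError("each polyline needs at least 2 vertices")
            if (p[:, 0] < 0).any() or (p[:, 1] < 0).any() or \
               (p[:, 0] > rows - 1).any() or (p[:, 1] > cols - 1).any():
                raise ValueError("polyline vertex outside image bounds")

    @property
    def total_length(self) -> float:
        """Sum of Euclidean segment lengths, in pixels."""
        return float(
            sum(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)) for p in self.polylines)
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "image_shape": list(self.image_shape),
                    "coordinate_convention": "0-based (row, col), row-major",
                    "polylines": [p.tolist() for p in self.polylines],
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BoundarySet":
        raw = json.loads(Path(path).read_text())
        return cls(
            polylines=[np.array(p, dtype=float) for p in raw["polylines"]],
            image_shape=tuple(raw["image_shape"]),
        )


@dataclass
class EdgeMask:
    mask: np.ndarray  # bool (rows, cols)
    dilation_radius: int


@dataclass
class BorderStats:
    accumulation_per_channel: list[float]
    complexes: float
    dilation_radius: int
    blur_sigma: float
    total_length: float


@dataclass
class GroupComparison:
    t_statistic: float
    p_value: float
    mean_A: float
    mean_B: float
    sem_A: float
    sem_B: float
    df: float
    alternative: str
    equal_var: bool
    degenerate: bool = False


def rasterize_boundaries(boundaries: BoundarySet) -> np.ndarray:
    """8-connected raster of all polyline segments (rounded vertices)."""
    canvas = np.zeros(boundaries.image_shape, dtype=bool)
    for p in boundaries.polylines:
        verts = np.rint(p).astype(int)
        for (r0, c0), (r1, c1) in zip(verts[:-1], verts[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            canvas[rr, cc] = True
    return canvas


def disk_footprint(r: int) -> np.ndarray:
    """Disk structuring element under the pixel-coverage convention: a pixel
    belongs to the disk when its centre lies within ``r + 0.5`` of the
    origin (so r=1 is the full 3×3 neighbourhood)."""
    offsets = np.arange(-r, r + 1)
    dr, dc = np.meshgrid(offsets, offsets, indexing="ij")
    return (dr**2 + dc**2) <= (r + 0.5) ** 2


def make_edge_mask(boundaries: BoundarySet, r: int = DEFAULT_DILATION_RADIUS) -> EdgeMask:
    """Rasterize the traced boundaries and dilate with a disk of radius ``r``."""
    if not boundaries.polylines:
        raise ValueError("boundary set has no polylines")
    if r < 1:
        raise ValueError("dilation radius must be >= 1 pixel")
    raster = rasterize_boundaries(boundaries)
    mask = dilation(raster, disk_footprint(int(r))).astype(bool)
    return EdgeMask(mask=mask, dilation_radius=int(r))


def _check_shapes(image: np.ndarray, mask: EdgeMask) -> None:
    if image.shape != mask.mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.mask.shape}")


def border_accumulation(image: np.ndarray, mask: EdgeMask, L: float) -> float:
    """Σ intensity over the edge mask, per unit boundary length."""
    image = np.asarray(image, dtype=float)
    _check_shapes(image, mask)
    if L <= 0:
        raise ValueError("boundary length must be positive")
    return float(image[mask.mask].sum() / L)


def border_complexes(
    image_A: np.ndarray,
    image_B: np.ndarray,
    blur_sigma: float,
    mask: EdgeMask,
    L: float,
) -> float:
    """Blur both channels, multiply, restrict to the edge mask, sum, and
    normalize by boundary length."""
    image_A = np.asarray(image_A, dtype=float)
    image_B = np.asarray(image_B, dtype=float)
    if image_A.shape != image_B.shape:
        raise ValueError(f"channel shapes differ: {image_A.shape} vs {image_B.shape}")
    _check_shapes(image_A, mask)
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    if L <= 0:
        raise ValueError("boundary length must be positive")
    if blur_sigma > 0:
        image_A = ndimage.gaussian_filter(image_A, blur_sigma)
        image_B = ndimage.gaussian_filter(image_B, blur_sigma)
    product = image_A * image_B
    return float(product[mask.mask].sum() / L)


def border_stats(
    channels: np.ndarray,
    boundaries: BoundarySet,
    r: int = DEFAULT_DILATION_RADIUS,
    blur_sigma: float = DEFAULT_BLUR_SIGMA,
) -> BorderStats:
    """Per-image border statistics for a (2, rows, cols) two-channel stack."""
    channels = np.asarray(channels, dtype=float)
    if channels.ndim != 3 or channels.shape[0] < 1:
        raise ValueError("expected a (n_channels, rows, cols) stack")
    mask = make_edge_mask(boundaries, r)
    L = boundaries.total_length
    acc = [border_accumulation(ch, mask, L) for ch in channels]
    cx = (
        border_complexes(channels[0], channels[1], blur_sigma, mask, L)
        if channels.shape[0] >= 2
        else float("nan")
    )
    return BorderStats(
        accumulation_per_channel=acc,
        complexes=cx,
        dilation_radius=int(r),
        blur_sigma=float(blur_sigma),
        total_length=L,
    )


def compare_groups(
    values_A: list[float] | np.ndarray,
    values_B: list[float] | np.ndarray,
    alternative: str = "greater",
    equal_var: bool = True,
) -> GroupComparison:
    """One-sided unpaired t test between two groups of border statistics.

    ``alternative="greater"`` tests mean(A) > mean(B).  Pooled variance by
    default (the classic unpaired t test); Welch via ``equal_var=False``.
    """
    a = np.asarray(values_A, dtype=float)
    b = np.asarray(values_B, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if alternative not in {"greater", "less"}:
        raise ValueError("alternative must be 'greater' or 'less'")
    degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if degenerate and np.mean(a) == np.mean(b):
        t_stat, p = 0.0, 0.5
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
        t_stat, p = float(res.statistic), float(res.pvalue)
    df = (
        len(a) + len(b) - 2
        if equal_var
        else float(
            (a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)) ** 2
            / (
                (a.var(ddof=1) / len(a)) ** 2 / (len(a) - 1)
                + (b.var(ddof=1) / len(b)) ** 2 / (len(b) - 1)
            )
        )
        if not degenerate
        else len(a) + len(b) - 2
    )
    return GroupComparison(
        t_statistic=t_stat,
        p_value=p,
        mean_A=float(a.mean()),
        mean_B=float(b.mean()),
        sem_A=float(stats.sem(a)),
        sem_B=float(stats.sem(b)),
        df=float(df),
        alternative=alternative,
        equal_var=equal_var,
        degenerate=bool(degenerate),
    )
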