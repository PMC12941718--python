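"""Carpal compactness metrics from bone centroids and mask overlaps.

Ten metrics quantify how tightly the carpal configuration is packed on the
canonical grid. Two are overlap-based: OSS, the total pairwise overlap pixel
count over all unordered bone pairs, and OSSD, the dispersion (population
standard deviation by default) of those pairwise counts. Four are
centroid-distance-based, in pixels: RMSR, the root-mean-square distance of
bone centroids c_k from their global centroid mu = mean(c_k); MPD, the mean
pairwise Euclidean inter-centroid distance; and R50/R90, the median and 90th
percentile of the radial distances ||c_k - mu||. The remaining four are the
distance metrics divided by Lbbox, the diagonal of the axis-aligned bounding
box of the centroids, making them dimensionless and scale-invariant.

Progressive joint space narrowing draws the carpals together, contracting the
centroid configuration, so the distance metrics are expected to correlate
negatively with clinical narrowing scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import DegenerateConfigurationError, EmptyMaskError, MaskSetError
from .mask_io import BoneMask, WristMaskSet

#: Reporting order of the ten metrics.
METRIC_ORDER = (
    "OSS",
    "OSSD",
    "RMSR",
    "MPD",
    "R50",
    "R90",
    "RMSRn",
    "MPDn",
    "R50n",
    "R90n",
)


class Point2D(NamedTuple):
    """A point with x along columns and y along rows (pixel centers)."""

    x: float
    y: float


@dataclass(frozen=True)
class CentroidSet:
    """Per-bone centroids, their global centroid, and radial distances."""

    points: tuple[Point2D, ...]
    labels: tuple[str, ...]
    mu: Point2D
    radii: np.ndarray

    @classmethod
    def from_points(
        cls, points: Sequence[Point2D], labels: Sequence[str] | None = None
    ) -> "CentroidSet":
        pts = tuple(Point2D(float(p[0]), float(p[1])) for p in points)
        if len(pts) < 2:
            raise MaskSetError(f"need at least 2 centroids, got {len(pts)}")
        if labels is None:
            labels = tuple(f"bone{i}" for i in range(len(pts)))
        arr = np.asarray(pts, dtype=float)
        mu = arr.mean(axis=0)
        radii = np.linalg.norm(arr - mu, axis=1)
        return cls(points=pts, labels=tuple(labels), mu=Point2D(*mu), radii=radii)

    @property
    def n(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)


@dataclass(frozen=True)
class OverlapTable:
    """Pairwise overlap pixel counts S_ij over all unordered bone pairs."""

    pairs: tuple[tuple[str, str, int], ...]
    n_bones: int

    def __post_init__(self):
        expected = self.n_bones * (self.n_bones - 1) // 2
        if len(self.pairs) != expected:
            raise MaskSetError(
                f"overlap table has {len(self.pairs)} pairs, "
                f"expected {expected} for {self.n_bones} bones"
            )

    @property
    def sizes(self) -> np.ndarray:
        return np.array([s for _, _, s in self.pairs], dtype=np.int64)


@dataclass(frozen=True)
class CompactnessVector:
    """The ten compactness metrics plus the bounding-box diagonal."""

    OSS: int
    OSSD: float
    RMSR: float
    MPD: float
    R50: float
    R90: float
    Lbbox: float
    RMSRn: float
    MPDn: float
    R50n: float
    R90n: float

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in METRIC_ORDER}
        d["Lbbox"] = self.Lbbox
        return d


def centroid(mask: BoneMask) -> Point2D:
    """Arithmetic mean (x=col, y=row) of a mask's foreground pixel centers."""
    rows, cols = np.nonzero(mask.grid)
    if rows.size == 0:
        raise EmptyMaskError(f"empty mask: {mask.bone_label!r} has no pixels")
    return Point2D(float(cols.mean()), float(rows.mean()))


def pairwise_overlap_sizes(mask_set: WristMaskSet) -> OverlapTable:
    """S_ij = number of pixels where both masks are foreground, for i < j."""
    masks = mask_set.masks
    pairs = []
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            s = int(np.count_nonzero(masks[i].grid & masks[j].grid))
            pairs.append((masks[i].bone_label, masks[j].bone_label, s))
    return OverlapTable(pairs=tuple(pairs), n_bones=len(masks))


def overlap_metrics(table: OverlapTable, ddof: int = 0) -> tuple[int, float]:
    """(OSS, OSSD): total and dispersion of the pairwise overlap sizes.

    OSSD is the standard deviation over all unordered pairs including
    zero-overlap pairs. ``ddof=0`` (default) treats the pairs as the complete
    population of pairs; ``ddof=1`` gives the sample convention.
    """
    sizes = table.sizes
    oss = int(sizes.sum())
    ossd = float(sizes.std(ddof=ddof))
    return oss, ossd


def centroid_set(mask_set: WristMaskSet) -> CentroidSet:
    """Per-bone centroids with their unweighted global centroid and radii."""
    points = [centroid(m) for m in mask_set.masks]
    return CentroidSet.from_points(points, labels=mask_set.labels)


def rmsr(cs: CentroidSet) -> float:
    """Root-mean-square radial distance of the centroids from mu."""
    return float(np.sqrt(np.mean(cs.radii**2)))


def mpd(cs: CentroidSet) -> float:
    """Mean pairwise Euclidean distance over ordered pairs i != j.

    Each unordered distance appears twice among the n(n-1) ordered pairs, so
    this equals the unordered-pair mean.
    """
    arr = cs.as_array()
    diff = arr[:, None, :] - arr[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    n = cs.n
    return float(dist.sum() / (n * (n - 1)))


def radial_quantile(cs: CentroidSet, q: float) -> float:
    """Empirical quantile of the radial distances.

    Linear interpolation between order statistics at fractional rank
    q*(n-1) — the usual type-7 convention (numpy's default).
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile level must be in [0, 1], got {q}")
    return float(np.quantile(cs.radii, q, method="linear"))


def bbox_diagonal(cs: CentroidSet) -> float:
    """Diagonal of the axis-aligned bounding box of the centroids."""
    arr = cs.as_array()
    span = arr.max(axis=0) - arr.min(axis=0)
    return float(math.hypot(span[0], span[1]))


def compactness_from_centroids(
    cs: CentroidSet,
    oss: int,
    ossd: float,
    quantile_levels: tuple[float, float] = (0.5, 0.9),
) -> CompactnessVector:
    """Assemble the full metric vector from precomputed parts."""
    raw = {
        "OSS": oss,
        "OSSD": ossd,
        "RMSR": rmsr(cs),
        "MPD": mpd(cs),
        "R50": radial_quantile(cs, quantile_levels[0]),
        "R90": radial_quantile(cs, quantile_levels[1]),
    }
    lbbox = bbox_diagonal(cs)
    if lbbox == 0.0:
        raise DegenerateConfigurationError(
            "degenerate configuration: all centroids coincide (Lbbox = 0)",
            raw_metrics=raw,
        )
    return CompactnessVector(
        OSS=oss,
        OSSD=ossd,
        RMSR=raw["RMSR"],
        MPD=raw["MPD"],
        R50=raw["R50"],
        R90=raw["R90"],
        Lbbox=lbbox,
        RMSRn=raw["RMSR"] / lbbox,
        MPDn=raw["MPD"] / lbbox,
        R50n=raw["R50"] / lbbox,
        R90n=raw["R90"] / lbbox,
    )


def compactness_vector(mask_set: WristMaskSet, ossd_ddof: int = 0) -> CompactnessVector:
    """Compute all ten metrics (plus Lbbox) for one wrist mask set."""
    cs = centroid_set(mask_set)
    oss, ossd = overlap_metrics(pairwise_overlap_sizes(mask_set), ddof=ossd_ddof)
    return compactness_from_centroids(cs, oss, ossd)
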