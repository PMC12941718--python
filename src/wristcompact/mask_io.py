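"""Reading, validation, and resampling of per-bone carpal segmentation masks.

Each wrist is represented by one binary raster per bone (bones may overlap on
a posteroanterior projection, which a single label map cannot represent). All
masks are resampled to a canonical 600x600 working grid before any metric is
computed. Coordinates are 0-based with ``x`` along columns and ``y`` along
rows; centroids live at pixel centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import imageio.v3 as iio
import numpy as np

from .errors import EmptyMaskError, MaskSetError

CANONICAL_SHAPE = (600, 600)
SIDES = ("left", "right")
TIMEPOINTS = ("BL", "FU")


@dataclass(frozen=True)
class BoneMask:
    """A single bone's binary segmentation mask.

    ``grid`` is a 2-D boolean array; True marks bone pixels.
    """

    bone_label: str
    grid: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise MaskSetError(
                f"mask {self.bone_label!r}: expected a 2-D raster, got {g.ndim}-D"
            )
        if g.dtype != bool:
            vals = np.unique(g)
            if not np.isin(vals, (0, 1)).all():
                raise MaskSetError(
                    f"mask {self.bone_label!r}: grid must be binary, "
                    f"found values {vals[:5]}"
                )
            g = g.astype(bool)
        object.__setattr__(self, "grid", g)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def area(self) -> int:
        """Number of foreground pixels."""
        return int(np.count_nonzero(self.grid))

    @property
    def is_empty(self) -> bool:
        return self.area == 0


@dataclass(frozen=True)
class WristMaskSet:
    """All bone masks for one (subject, side, timepoint) on a common grid."""

    subject_id: str
    side: str
    timepoint: str
    masks: tuple[BoneMask, ...]

    def __post_init__(self):
        if self.side not in SIDES:
            raise MaskSetError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.timepoint not in TIMEPOINTS:
            raise MaskSetError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        masks = tuple(self.masks)
        object.__setattr__(self, "masks", masks)
        labels = [m.bone_label for m in masks]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise MaskSetError(f"duplicate bone labels in mask set: {dupes}")
        shapes = {m.shape for m in masks}
        if len(shapes) > 1:
            raise MaskSetError(f"masks do not share one grid shape: {sorted(shapes)}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(m.bone_label for m in self.masks)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.masks[0].shape

    @property
    def n_bones(self) -> int:
        return len(self.masks)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.side, self.timepoint)


def _binarize(raster: np.ndarray, label: str) -> np.ndarray:
    if raster.ndim == 3 and raster.shape[2] == 1:
        raster = raster[:, :, 0]
    if raster.ndim != 2:
        raise MaskSetError(
            f"mask file for {label!r} is not single-channel (shape {raster.shape})"
        )
    return raster > 0


def load_wrist_mask_set(directory_path, manifest=None) -> WristMaskSet:
    """Load one wrist's per-bone masks as described by a manifest.

    The manifest is either a mapping or a path to a JSON file (defaults to
    ``manifest.json`` inside ``directory_path``) with keys ``subject_id``,
    ``side``, ``timepoint`` and ``bones`` = list of ``{label, file}``.
    Grayscale rasters are binarized as pixel > 0. Masks are returned at
    native resolution; call :func:`resample_mask_set` for the canonical grid.
    """
    directory = Path(directory_path)
    if manifest is None:
        manifest = directory / "manifest.json"
    if isinstance(manifest, (str, Path)):
        with open(manifest) as fh:
            manifest = json.load(fh)

    bones = manifest["bones"]
    labels = [b["label"] for b in bones]
    if len(set(labels)) != len(labels):
        raise MaskSetError(f"manifest lists duplicate bone labels: {labels}")

    masks = []
    for bone in bones:
        path = directory / bone["file"]
        if not path.exists():
            raise MaskSetError(
                f"incomplete mask set: no file for bone {bone['label']!r} "
                f"(expected {path})"
            )
        try:
            raster = np.asarray(iio.imread(path))
        except Exception as exc:  # unreadable raster
            raise MaskSetError(f"cannot read mask for {bone['label']!r}: {exc}") from exc
        masks.append(BoneMask(bone["label"], _binarize(raster, bone["label"])))

    return WristMaskSet(
        subject_id=str(manifest["subject_id"]),
        side=manifest["side"],
        timepoint=manifest["timepoint"],
        masks=tuple(masks),
    )


def _nn_index_map(n_out: int, n_in: int) -> np.ndarray:
    # Pixel-center aligned nearest-neighbor source index: output pixel i
    # covers input interval [i*n_in/n_out, (i+1)*n_in/n_out); its center maps
    # to source index floor((i + 0.5) * n_in / n_out).
    idx = np.floor((np.arange(n_out) + 0.5) * (n_in / n_out)).astype(np.intp)
    return np.clip(idx, 0, n_in - 1)


def resample_mask(mask: BoneMask, target_shape: tuple[int, int]) -> BoneMask:
    """Nearest-neighbor (label-preserving) resampling of one mask."""
    if mask.is_empty:
        raise EmptyMaskError(f"mask {mask.bone_label!r} is empty before resampling")
    rows_in, cols_in = mask.shape
    rows_out, cols_out = target_shape
    if (rows_in, cols_in) == (rows_out, cols_out):
        return mask
    rmap = _nn_index_map(rows_out, rows_in)
    cmap = _nn_index_map(cols_out, cols_in)
    out = mask.grid[np.ix_(rmap, cmap)]
    result = BoneMask(mask.bone_label, out)
    if result.is_empty:
        raise EmptyMaskError(
            f"degenerate mask after resampling: bone {mask.bone_label!r} "
            f"lost all pixels going from {mask.shape} to {target_shape}"
        )
    return result


def resample_mask_set(
    mask_set: WristMaskSet, target_shape: tuple[int, int] = CANONICAL_SHAPE
) -> WristMaskSet:
    """Resample every mask in the set to ``target_shape``.

    Non-square inputs are stretched anisotropically (no padding); metadata is
    unchanged. A 600x600 input round-trips bit-for-bit.
    """
    return WristMaskSet(
        subject_id=mask_set.subject_id,
        side=mask_set.side,
        timepoint=mask_set.timepoint,
        masks=tuple(resample_mask(m, target_shape) for m in mask_set.masks),
    )


@dataclass
class MaskSetReport:
    """Validation summary for one wrist mask set (reporting only)."""

    key: tuple[str, str, str]
    pixel_counts: dict[str, int]
    empty_labels: list[str]
    fusion_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    fusion_threshold: float = 0.8

    @property
    def has_flags(self) -> bool:
        return bool(self.empty_labels or self.fusion_pairs)


def validate_mask_set(
    mask_set: WristMaskSet, fusion_threshold: float = 0.8
) -> MaskSetReport:
    """Report per-bone pixel counts, empty masks, and suspected bone fusion.

    A pair is flagged as fusion-suspect when its overlap covers at least
    ``fusion_threshold`` of the smaller bone's area (severely fused carpals
    cannot be reliably differentiated and should be excluded upstream).
    """
    counts = {m.bone_label: m.area for m in mask_set.masks}
    empty = [label for label, n in counts.items() if n == 0]
    fusion = []
    masks = mask_set.masks
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            a, b = masks[i], masks[j]
            smaller = min(a.area, b.area)
            if smaller == 0:
                continue
            overlap = int(np.count_nonzero(a.grid & b.grid))
            frac = overlap / smaller
            if frac >= fusion_threshold:
                fusion.append((a.bone_label, b.bone_label, frac))
    return MaskSetReport(
        key=mask_set.key,
        pixel_counts=counts,
        empty_labels=empty,
        fusion_pairs=fusion,
        fusion_threshold=fusion_threshold,
    )


def write_wrist_mask_set(mask_set: WristMaskSet, directory_path) -> Path:
    """Write one PNG per bone plus a manifest.json; returns the directory."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    bones = []
    for mask in mask_set.masks:
        fname = f"{mask.bone_label}.png"
        iio.imwrite(directory / fname, (mask.grid.astype(np.uint8) * 255))
        bones.append({"label": mask.bone_label, "file": fname})
    manifest = {
        "subject_id": mask_set.subject_id,
        "side": mask_set.side,
        "timepoint": mask_set.timepoint,
        "bones": bones,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return directory


def write_cohort_index(entries: Sequence[dict], root) -> Path:
    """Write the top-level index.json listing wrist directories."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    index_path = root / "index.json"
    with open(index_path, "w") as fh:
        json.dump({"wrists": list(entries)}, fh, indent=1, sort_keys=True)
    return index_path


def iter_cohort_mask_sets(root) -> Iterator[WristMaskSet]:
    """Yield wrist mask sets listed in ``<root>/index.json``, in index order."""
    root = Path(root)
    with open(root / "index.json") as fh:
        index = json.load(fh)
    for entry in index["wrists"]:
        yield load_wrist_mask_set(root / entry["path"])
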