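"""Synthetic wrist-phantom cohorts for exercising the whole pipeline.

No clinical radiographs ship with this package, so validation runs on
synthetic cohorts that emulate the study structure: per subject, bilateral
wrists imaged at baseline (BL) and follow-up (FU), each wrist represented by
seven ellipse "carpal bones" rasterized on the 600x600 grid in a two-row,
carpal-like arrangement with deliberate partial overlaps.

A latent severity s in [0, 1] per wrist drives everything:

* geometry — bone anchor positions are contracted toward their common
  centroid by lambda = lambda_max * s (bone sizes are unchanged, so crowding
  also increases overlap, as when cartilage is lost);
* the wrist narrowing subscore (jsns) — each scored joint site receives an
  ordinal grade 0-4 from fixed thresholds on s, perturbed by +/-1
  misclassification noise, and the grades are summed;
* the total damage score (tss) — a wrist-linked component proportional to
  the bilateral jsns mixed with an independent whole-body damage background,
  so tss correlates with wrist geometry more weakly than jsns does.

Projection variability is emulated by per-bone centroid jitter and a global
rotation/scale of each wrist. Severity is correlated between sides
(symmetric polyarthritis) and nondecreasing from BL to FU (progressive
damage). Every cohort is byte-reproducible from (parameters, seed); each
randomness purpose has its own named stream so adding a stage never perturbs
earlier ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.draw import ellipse as draw_ellipse

from .compactness import Point2D
from .errors import GenerationError
from .mask_io import (
    BoneMask,
    WristMaskSet,
    write_cohort_index,
    write_wrist_mask_set,
)

GRID_SHAPE = (600, 600)

#: Standard carpals visible on a posteroanterior projection, minus the
#: pisiform (which overlies the triquetrum). Free-form configuration.
DEFAULT_LABELS = (
    "scaphoid",
    "lunate",
    "triquetrum",
    "trapezium",
    "trapezoid",
    "capitate",
    "hamate",
)


@dataclass(frozen=True)
class WristLayout:
    """Anchor positions and ellipse shapes of the seven phantom bones.

    The default is a proximal row of three and a distal row of four with
    plausible relative sizes; the values are fixture constants, not claimed
    anatomical truth. ``overlap_margin`` enlarges every semi-axis to create
    partial pairwise overlaps even at zero severity.
    """

    anchors: tuple[Point2D, ...] = (
        Point2D(230.0, 380.0),
        Point2D(305.0, 395.0),
        Point2D(375.0, 385.0),
        Point2D(195.0, 290.0),
        Point2D(262.0, 275.0),
        Point2D(330.0, 270.0),
        Point2D(405.0, 290.0),
    )
    semi_axes: tuple[tuple[float, float], ...] = (
        (48.0, 40.0),
        (34.0, 32.0),
        (36.0, 30.0),
        (38.0, 32.0),
        (30.0, 28.0),
        (38.0, 46.0),
        (40.0, 36.0),
    )
    orientations: tuple[float, ...] = (0.4, 0.0, -0.3, 0.3, 0.0, 0.1, -0.2)
    labels: tuple[str, ...] = DEFAULT_LABELS
    overlap_margin: float = 10.0
    grid_shape: tuple[int, int] = GRID_SHAPE

    def __post_init__(self):
        n = len(self.anchors)
        if not (len(self.semi_axes) == len(self.orientations) == len(self.labels) == n):
            raise GenerationError("layout fields must all have one entry per bone")
        if len({(p.x, p.y) for p in self.anchors}) != n:
            raise GenerationError("layout anchors must be pairwise distinct")

    @property
    def n_bones(self) -> int:
        return len(self.anchors)


def apply_contraction(points: Sequence[Point2D], lam: float) -> list[Point2D]:
    """Move every point toward the set's centroid: c' = mu + (1-lam)(c - mu).

    lam = 0 is the identity; lam = 1 collapses all points onto mu. The global
    centroid is unchanged, and every centroid-distance metric scales by
    exactly (1 - lam).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"contraction lambda must be in [0, 1], got {lam}")
    arr = np.asarray(points, dtype=float)
    mu = arr.mean(axis=0)
    moved = mu + (1.0 - lam) * (arr - mu)
    return [Point2D(*p) for p in moved]


def render_wrist(
    layout: WristLayout,
    lam: float = 0.0,
    jitter_sd: float = 0.0,
    rotation: float = 0.0,
    scale: float = 1.0,
    rng: np.random.Generator | int | None = None,
    subject_id: str = "synthetic",
    side: str = "left",
    timepoint: str = "BL",
) -> WristMaskSet:
    """Rasterize the seven phantom bones for one wrist.

    Anchors are contracted by ``lam``, jittered per bone (N(0, jitter_sd)
    on each coordinate), then the whole configuration is rotated by
    ``rotation`` radians and scaled by ``scale`` about the grid center
    (bone sizes scale too). Deterministic for fixed inputs and rng state.
    """
    if abs(rotation) > np.deg2rad(15.0) + 1e-12:
        raise GenerationError(f"|rotation| must be <= 15 degrees, got {rotation} rad")
    if not 0.8 <= scale <= 1.2:
        raise GenerationError(f"scale must be in [0.8, 1.2], got {scale}")
    rng = np.random.default_rng(rng)

    anchors = np.asarray(apply_contraction(layout.anchors, lam), dtype=float)
    anchors = anchors + rng.normal(0.0, jitter_sd, size=anchors.shape)

    center = np.array([(layout.grid_shape[1] - 1) / 2.0, (layout.grid_shape[0] - 1) / 2.0])
    cos_t, sin_t = np.cos(rotation), np.sin(rotation)
    rot = np.array([[cos_t, -sin_t], [sin_t, cos_t]])
    placed = center + scale * (anchors - center) @ rot.T

    rows_max, cols_max = layout.grid_shape
    masks = []
    for k, label in enumerate(layout.labels):
        cx, cy = placed[k]
        a = (layout.semi_axes[k][0] + layout.overlap_margin) * scale
        b = (layout.semi_axes[k][1] + layout.overlap_margin) * scale
        extent = max(a, b)
        if not (extent <= cx <= cols_max - 1 - extent and extent <= cy <= rows_max - 1 - extent):
            raise GenerationError(
                f"bone {label!r} falls off the grid at ({cx:.1f}, {cy:.1f}) "
                f"with extent {extent:.1f}"
            )
        grid = np.zeros(layout.grid_shape, dtype=bool)
        rr, cc = draw_ellipse(
            cy, cx, b, a, shape=layout.grid_shape,
            rotation=layout.orientations[k] + rotation,
        )
        grid[rr, cc] = True
        if not grid.any():
            raise GenerationError(f"bone {label!r} rasterized to an empty mask")
        masks.append(BoneMask(label, grid))

    return WristMaskSet(
        subject_id=subject_id, side=side, timepoint=timepoint, masks=tuple(masks)
    )


@dataclass(frozen=True)
class SeverityModel:
    """Links the latent severity to geometry and clinical scores.

    ``grade_thresholds`` are the four cutpoints on s giving ordinal joint
    grades 0-4; ``grade_noise`` is the per-joint probability of a +/-1
    misclassification; ``n_joint_sites`` wrist joints are summed into the
    subscore. ``lambda_max`` scales severity into geometric contraction.
    tss = round(w * K * bilateral_jsns + (1 - w) * background) with
    w = ``tss_mixing``, K = ``tss_wrist_scale`` and a gamma-distributed,
    slowly progressing whole-body background.
    """

    grade_thresholds: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    grade_noise: float = 0.1
    n_joint_sites: int = 3
    lambda_max: float = 0.5
    tss_mixing: float = 0.9
    tss_wrist_scale: float = 4.0
    tss_background_shape: float = 1.2
    tss_background_scale: float = 80.0

    def __post_init__(self):
        th = np.asarray(self.grade_thresholds, dtype=float)
        if len(th) != 4 or not (np.diff(th) > 0).all():
            raise GenerationError("grade_thresholds must be 4 strictly increasing cutpoints")
        if not 0.0 <= self.tss_mixing <= 1.0:
            raise GenerationError("tss_mixing must be in [0, 1]")
        if not 0.0 <= self.lambda_max <= 1.0:
            raise GenerationError("lambda_max must be in [0, 1]")

    def lambda_of_severity(self, s) -> np.ndarray:
        """Monotone severity -> contraction map (linear by construction)."""
        return self.lambda_max * np.asarray(s, dtype=float)


def grade_from_severity(
    s: float, model: SeverityModel, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Ordinal grades (one per joint site) and their sum for one wrist."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"severity must be in [0, 1], got {s}")
    base = int(np.searchsorted(model.grade_thresholds, s, side="right"))
    grades = np.full(model.n_joint_sites, base, dtype=int)
    flips = rng.random(model.n_joint_sites) < model.grade_noise
    signs = rng.choice((-1, 1), size=model.n_joint_sites)
    grades = np.clip(grades + flips * signs, 0, 4)
    return grades, int(grades.sum())


@dataclass(frozen=True)
class CohortParams:
    """Study-structure parameters of the synthetic cohort."""

    n_subjects: int = 50
    side_correlation: float = 0.7
    severity_alpha: float = 2.0
    severity_beta: float = 3.0
    progression_mu: float = 0.05
    progression_sd: float = 0.05
    missing_tss_rate: float = 0.0
    jitter_sd: float = 3.0
    rotation_sd_deg: float = 3.0
    scale_low: float = 0.95
    scale_high: float = 1.05

    def __post_init__(self):
        if self.n_subjects < 1:
            raise GenerationError("n_subjects must be >= 1")
        if not 0.0 <= self.side_correlation <= 1.0:
            raise GenerationError("side_correlation must be in [0, 1]")
        if not 0.0 <= self.missing_tss_rate < 1.0:
            raise GenerationError("missing_tss_rate must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticWrist:
    """Render recipe and ground truth for one (subject, side, timepoint)."""

    subject_id: str
    side: str
    timepoint: str
    severity: float
    lam: float
    jitter_sd: float
    rotation: float
    scale: float
    render_seed: tuple[int, ...]


# named randomness streams, all derived from the master seed
_STREAM_SEVERITY, _STREAM_GRADES, _STREAM_TSS, _STREAM_RENDER, _STREAM_MISSING = range(5)


@dataclass
class SyntheticCohort:
    """A fully reproducible synthetic cohort: geometry recipes + scores."""

    seed: int
    params: CohortParams
    model: SeverityModel
    layout: WristLayout
    wrists: list[SyntheticWrist]
    scores: pd.DataFrame
    ground_truth: pd.DataFrame

    def render(self, wrist: SyntheticWrist) -> WristMaskSet:
        rng = np.random.default_rng(np.random.SeedSequence(list(wrist.render_seed)))
        return render_wrist(
            self.layout,
            lam=wrist.lam,
            jitter_sd=wrist.jitter_sd,
            rotation=wrist.rotation,
            scale=wrist.scale,
            rng=rng,
            subject_id=wrist.subject_id,
            side=wrist.side,
            timepoint=wrist.timepoint,
        )

    def iter_mask_sets(self) -> Iterator[WristMaskSet]:
        for wrist in self.wrists:
            yield self.render(wrist)

    def generating_correlation(self, score: str = "jsns") -> float:
        """Pearson correlation between the ground-truth contraction factor
        (1 - lambda) and the generated score, over all wrists.

        This is the correlation the geometry pipeline should recover, up to
        rasterization/jitter noise, since every distance metric is
        proportional to (1 - lambda) for a fixed layout.
        """
        merged = self.ground_truth.merge(
            self.scores, on=["subject_id", "side", "timepoint"]
        )
        return float(
            sps.pearsonr(1.0 - merged["lam"], merged[score].astype(float)).statistic
        )

    def write(self, out_dir) -> Path:
        """Write masks + manifests + scores.csv + ground_truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries = []
        for wrist in self.wrists:
            rel = f"{wrist.subject_id}_{wrist.side}_{wrist.timepoint}"
            write_wrist_mask_set(self.render(wrist), out / rel)
            entries.append(
                {
                    "subject_id": wrist.subject_id,
                    "side": wrist.side,
                    "timepoint": wrist.timepoint,
                    "path": rel,
                }
            )
        write_cohort_index(entries, out)
        self.scores.to_csv(out / "scores.csv", index=False)
        truth = {
            "seed": self.seed,
            "params": dataclasses.asdict(self.params),
            "model": dataclasses.asdict(self.model),
            "wrists": self.ground_truth.to_dict(orient="records"),
        }
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True, default=float)
        return out


def _severities(params: CohortParams, rng: np.random.Generator) -> np.ndarray:
    """(n_subjects, 2 sides, 2 timepoints) latent severities in [0, 1].

    Sides share a Gaussian copula with correlation ``side_correlation``;
    the marginal at BL is Beta(alpha, beta); FU adds a nonnegative
    progression increment (truncated at 1).
    """
    n = params.n_subjects
    rho = params.side_correlation
    z_common = rng.normal(size=n)
    z_sides = np.sqrt(rho) * z_common[:, None] + np.sqrt(1 - rho) * rng.normal(size=(n, 2))
    u = sps.norm.cdf(z_sides)
    s_bl = sps.beta.ppf(u, params.severity_alpha, params.severity_beta)
    prog = np.abs(rng.normal(params.progression_mu, params.progression_sd, size=(n, 2)))
    s_fu = np.minimum(1.0, s_bl + prog)
    return np.stack([s_bl, s_fu], axis=2)


def simulate_cohort(
    params: CohortParams | None = None,
    model: SeverityModel | None = None,
    layout: WristLayout | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a bilateral, two-timepoint synthetic cohort."""
    params = params or CohortParams()
    model = model or SeverityModel()
    layout = layout or WristLayout()

    rng_sev = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_SEVERITY]))
    rng_grades = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_GRADES]))
    rng_tss = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_TSS]))
    rng_render = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_RENDER]))
    rng_missing = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_MISSING]))

    sev = _severities(params, rng_sev)
    rot_limit = np.deg2rad(15.0)

    wrists: list[SyntheticWrist] = []
    score_rows, truth_rows = [], []
    jsns_by_subject_tp: dict[tuple[int, str], int] = {}

    for i in range(params.n_subjects):
        sid = f"S{i + 1:03d}"
        for side_idx, side in enumerate(("left", "right")):
            for tp_idx, tp in enumerate(("BL", "FU")):
                s = float(sev[i, side_idx, tp_idx])
                lam = float(model.lambda_of_severity(s))
                rotation = float(
                    np.clip(rng_render.normal(0.0, np.deg2rad(params.rotation_sd_deg)),
                            -rot_limit, rot_limit)
                )
                scale = float(rng_render.uniform(params.scale_low, params.scale_high))
                _, jsns = grade_from_severity(s, model, rng_grades)
                jsns_by_subject_tp[(i, tp)] = jsns_by_subject_tp.get((i, tp), 0) + jsns
                wrists.append(
                    SyntheticWrist(
                        subject_id=sid, side=side, timepoint=tp,
                        severity=s, lam=lam,
                        jitter_sd=params.jitter_sd, rotation=rotation, scale=scale,
                        render_seed=(seed, _STREAM_RENDER, i, side_idx, tp_idx),
                    )
                )
                score_rows.append({"subject_id": sid, "side": side, "timepoint": tp,
                                   "jsns": jsns})
                truth_rows.append({"subject_id": sid, "side": side, "timepoint": tp,
                                   "severity": s, "lam": lam})

    # subject-level total damage score: wrist-linked component + independent
    # whole-body background, both nondecreasing in time
    w, k = model.tss_mixing, model.tss_wrist_scale
    bg_bl = rng_tss.gamma(model.tss_background_shape, model.tss_background_scale,
                          size=params.n_subjects)
    bg_fu = bg_bl + np.abs(rng_tss.normal(1.0, 2.0, size=params.n_subjects))
    tss = {}
    for i in range(params.n_subjects):
        for tp, bg in (("BL", bg_bl[i]), ("FU", bg_fu[i])):
            bilateral = jsns_by_subject_tp[(i, tp)]
            value = float(np.round(w * k * bilateral + (1.0 - w) * bg))
            if rng_missing.random() < params.missing_tss_rate:
                value = np.nan
            tss[(f"S{i + 1:03d}", tp)] = value

    scores = pd.DataFrame(score_rows)
    scores["tss"] = [tss[(r["subject_id"], r["timepoint"])] for r in score_rows]
    ground_truth = pd.DataFrame(truth_rows)

    return SyntheticCohort(
        seed=seed, params=params, model=model, layout=layout,
        wrists=wrists, scores=scores, ground_truth=ground_truth,
    )
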