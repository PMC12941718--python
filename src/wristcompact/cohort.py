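"""Cohort assembly and the analysis designs of the validation battery.

A cohort is a tidy table with one row per (subject, side, timepoint) holding
the ten compactness metrics, the wrist joint-space-narrowing subscore (jsns),
and the subject-level total damage score (tss, possibly missing). The
analysis designs derive paired (metric, score) observation sets:

====================  =========================================  =========
design                observations                               n (full
                                                                 50-subject
                                                                 cohort)
====================  =========================================  =========
entire_wrist_level    every wrist at both timepoints vs jsns     200
wrist_level_at:TP     both hands at one timepoint vs jsns        100
bilateral_sum_at:TP   left+right sums per subject vs summed      50
                      jsns
per_hand_at:SIDE:TP   one hand, one timepoint vs jsns            50
per_hand_pooled:SIDE  one hand, both timepoints pooled vs jsns   100
delta_bilateral       FU-BL change of the bilateral sums         50
tss_pooled            bilateral-sum metrics at both timepoints   92 (46
                      vs tss                                     subjects)
tss_at:TP             bilateral-sum metrics at one timepoint     46
                      vs tss
tss_delta             FU-BL change of bilateral sums vs          46
                      change in tss
====================  =========================================  =========

Total-damage designs use only subjects with tss present at BOTH timepoints
(listwise deletion, so pooled/per-timepoint/delta n's stay consistent).
Pooled designs treat a subject's BL and FU rows as independent observations;
no repeated-measures correction is applied, which the battery output notes.
Metrics are aggregated to subject level by summing left+right by default
(matching how the bilateral score is formed); mean aggregation is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .compactness import METRIC_ORDER, compactness_vector
from .errors import DataJoinError, DegenerateConfigurationError, DesignError, EmptyMaskError
from .mask_io import WristMaskSet

KEY = ["subject_id", "side", "timepoint"]

ALL_DESIGNS = (
    "entire_wrist_level",
    "wrist_level_at:BL",
    "wrist_level_at:FU",
    "delta_bilateral",
    "bilateral_sum_at:BL",
    "bilateral_sum_at:FU",
    "per_hand_at:left:BL",
    "per_hand_at:left:FU",
    "per_hand_at:right:BL",
    "per_hand_at:right:FU",
    "per_hand_pooled:left",
    "per_hand_pooled:right",
    "tss_pooled",
    "tss_at:BL",
    "tss_at:FU",
    "tss_delta",
)

#: Output grouping used by the reporting layer: one battery CSV per group.
TABLE_GROUPS = {
    "table3": ("entire_wrist_level",),
    "table4": ("wrist_level_at:BL", "wrist_level_at:FU"),
    "table5": ("delta_bilateral",),
    "table6": ("bilateral_sum_at:BL", "bilateral_sum_at:FU"),
    "table7": (
        "per_hand_at:left:BL",
        "per_hand_at:left:FU",
        "per_hand_at:right:BL",
        "per_hand_at:right:FU",
    ),
    "table8": ("per_hand_pooled:left", "per_hand_pooled:right"),
    "table9": ("tss_pooled",),
    "table10": ("tss_at:BL", "tss_at:FU"),
    "table11": ("tss_delta",),
}


def metrics_table(mask_sets: Iterable[WristMaskSet], ossd_ddof: int = 0):
    """Compute one metric row per wrist; unanalyzable wrists are excluded.

    Returns ``(frame, exclusions)`` where exclusions is a list of
    ``(subject_id, side, timepoint, reason)`` for wrists whose metrics could
    not be computed (empty mask, coincident centroids).
    """
    rows, exclusions = [], []
    for ms in mask_sets:
        try:
            vec = compactness_vector(ms, ossd_ddof=ossd_ddof)
        except (EmptyMaskError, DegenerateConfigurationError) as exc:
            exclusions.append((*ms.key, str(exc)))
            continue
        row = dict(zip(KEY, ms.key))
        row.update(vec.as_dict())
        rows.append(row)
    cols = KEY + list(METRIC_ORDER) + ["Lbbox"]
    frame = pd.DataFrame(rows, columns=cols)
    return frame, exclusions


def read_scores(path) -> pd.DataFrame:
    """Read the clinical-scores CSV (subject_id, side, timepoint, jsns, tss).

    Empty tss cells mean the total damage score is missing for that
    (subject, timepoint).
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(KEY + ["jsns"]) - set(df.columns)
    if missing:
        raise DataJoinError(f"scores file lacks required columns: {sorted(missing)}")
    if "tss" not in df.columns:
        df["tss"] = np.nan
    return df


@dataclass
class CohortTable:
    """Joined metrics + clinical scores, one row per (subject, side, timepoint)."""

    data: pd.DataFrame
    excluded_metric_rows: list = field(default_factory=list)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject_id"].unique())

    @property
    def n_rows(self) -> int:
        return len(self.data)


def build_cohort_table(metric_rows: pd.DataFrame, scores: pd.DataFrame) -> CohortTable:
    """Inner-join metric rows with clinical scores on (subject, side, timepoint).

    Rows with missing tss are retained (they drop out only of total-damage
    designs). Metric rows without a matching score row are excluded with a
    warning and listed in the result; duplicated keys are an error.
    """
    for name, df in (("metrics", metric_rows), ("scores", scores)):
        dup = df.duplicated(subset=KEY)
        if dup.any():
            keys = df.loc[dup, KEY].to_records(index=False).tolist()
            raise DataJoinError(f"duplicate (subject, side, timepoint) in {name}: {keys}")

    merged = metric_rows.merge(scores, on=KEY, how="inner", validate="one_to_one")
    unmatched = metric_rows.merge(scores[KEY], on=KEY, how="left", indicator=True)
    excluded = unmatched.loc[unmatched["_merge"] == "left_only", KEY]
    excluded_list = [tuple(t) for t in excluded.to_records(index=False)]
    if excluded_list:
        warnings.warn(
            f"{len(excluded_list)} metric row(s) had no matching score row "
            f"and were excluded: {excluded_list[:5]}",
            stacklevel=2,
        )

    tss_chk = merged.dropna(subset=["tss"]).groupby(["subject_id", "timepoint"])["tss"].nunique()
    if (tss_chk > 1).any():
        bad = tss_chk[tss_chk > 1].index.tolist()
        raise DataJoinError(
            f"tss must be constant across sides within a subject-timepoint: {bad}"
        )
    return CohortTable(data=merged.reset_index(drop=True), excluded_metric_rows=excluded_list)


def _bilateral_sums(df: pd.DataFrame, aggregation: str = "sum") -> pd.DataFrame:
    """Aggregate left+right to one row per (subject, timepoint).

    Only subjects with both sides present at a timepoint contribute. Scores
    (jsns) are always summed, matching the bilateral subscore definition;
    ``aggregation`` controls the metric columns only.
    """
    agg = {"sum": "sum", "mean": "mean"}[aggregation]
    complete = df.groupby(["subject_id", "timepoint"]).filter(
        lambda g: set(g["side"]) == {"left", "right"}
    )
    grouped = complete.groupby(["subject_id", "timepoint"], as_index=False).agg(
        {**{m: agg for m in METRIC_ORDER}, "jsns": "sum", "tss": "first"}
    )
    return grouped


def compute_deltas(table: CohortTable, aggregation: str = "sum") -> pd.DataFrame:
    """FU - BL change of the bilateral-sum quantities, one row per subject.

    Subjects lacking a complete BL/FU pair of bilateral sums are skipped.
    """
    bil = _bilateral_sums(table.data, aggregation)
    cols = list(METRIC_ORDER) + ["jsns", "tss"]
    if bil.empty or not {"BL", "FU"} <= set(bil["timepoint"]):
        return pd.DataFrame(columns=["subject_id"] + cols)
    wide = bil.pivot(index="subject_id", columns="timepoint")
    out = {"subject_id": wide.index}
    complete = np.ones(len(wide), dtype=bool)
    for c in cols:
        fu, bl = wide[(c, "FU")], wide[(c, "BL")]
        out[c] = fu - bl
        if c != "tss":
            complete &= fu.notna().to_numpy() & bl.notna().to_numpy()
    frame = pd.DataFrame(out).loc[complete].reset_index(drop=True)
    return frame


def _tss_complete_subjects(df: pd.DataFrame) -> set[str]:
    """Subjects with tss present at both BL and FU (paired-complete)."""
    has = (
        df.dropna(subset=["tss"])
        .groupby("subject_id")["timepoint"]
        .agg(lambda t: {"BL", "FU"} <= set(t))
    )
    return set(has[has].index)


@dataclass(frozen=True)
class DesignView:
    """Aligned metric/score observations for one analysis design."""

    design: str
    score: str
    n: int
    data: pd.DataFrame  # columns: the ten metrics + "score"


def _finish(design: str, score_name: str, df: pd.DataFrame, score_col: str) -> DesignView:
    if df.empty:
        raise DesignError(f"no observations for design {design!r}")
    out = df[list(METRIC_ORDER)].copy()
    out["score"] = df[score_col].to_numpy(dtype=float)
    return DesignView(design=design, score=score_name, n=len(out), data=out.reset_index(drop=True))


def design_view(table: CohortTable, design: str, aggregation: str = "sum") -> DesignView:
    """Paired (metric, score) observation set for one analysis design."""
    df = table.data
    parts = design.split(":")
    head = parts[0]

    if head == "entire_wrist_level" and len(parts) == 1:
        return _finish(design, "jsns", df, "jsns")

    if head == "wrist_level_at" and len(parts) == 2:
        return _finish(design, "jsns", df[df["timepoint"] == parts[1]], "jsns")

    if head == "bilateral_sum_at" and len(parts) == 2:
        bil = _bilateral_sums(df, aggregation)
        return _finish(design, "jsns", bil[bil["timepoint"] == parts[1]], "jsns")

    # bilateral sums pooled over both timepoints vs the summed subscore; the
    # jsns-side mirror of tss_pooled, used to compare score attenuation
    if head == "bilateral_pooled" and len(parts) == 1:
        return _finish(design, "jsns", _bilateral_sums(df, aggregation), "jsns")

    if head == "per_hand_at" and len(parts) == 3:
        side, tp = parts[1], parts[2]
        sel = df[(df["side"] == side) & (df["timepoint"] == tp)]
        return _finish(design, "jsns", sel, "jsns")

    if head == "per_hand_pooled" and len(parts) == 2:
        return _finish(design, "jsns", df[df["side"] == parts[1]], "jsns")

    if head == "delta_bilateral" and len(parts) == 1:
        deltas = compute_deltas(table, aggregation)
        return _finish(design, "jsns", deltas, "jsns")

    if head in ("tss_pooled", "tss_at", "tss_delta"):
        keep = _tss_complete_subjects(df)
        sub = df[df["subject_id"].isin(keep)]
        if head == "tss_delta" and len(parts) == 1:
            deltas = compute_deltas(CohortTable(sub), aggregation)
            deltas = deltas.dropna(subset=["tss"])
            return _finish(design, "tss", deltas, "tss")
        bil = _bilateral_sums(sub, aggregation).dropna(subset=["tss"])
        if head == "tss_pooled" and len(parts) == 1:
            return _finish(design, "tss", bil, "tss")
        if head == "tss_at" and len(parts) == 2:
            return _finish(design, "tss", bil[bil["timepoint"] == parts[1]], "tss")

    raise DesignError(f"unknown design: {design!r}")


def design_counts(table: CohortTable, designs=ALL_DESIGNS, aggregation: str = "sum") -> dict:
    """n per design (designs with no observations are reported as 0)."""
    out = {}
    for d in designs:
        try:
            out[d] = design_view(table, d, aggregation).n
        except DesignError:
            out[d] = 0
    return out
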