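import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from wristcompact import BoneMask, WristMaskSet, build_cohort_table, simulate_cohort
from wristcompact.cohort import KEY, METRIC_ORDER

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def random_mask_set(seed, n_bones=7, grid=64, subject="S001", side="left", tp="BL"):
    """Seven random disc-ish blobs on a small grid, some overlapping."""
    rng = np.random.default_rng(seed)
    masks = []
    yy, xx = np.mgrid[0:grid, 0:grid]
    for k in range(n_bones):
        cy, cx = rng.uniform(10, grid - 10, size=2)
        ry, rx = rng.uniform(4, 12, size=2)
        g = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        if not g.any():
            g[int(cy), int(cx)] = True
        masks.append(BoneMask(f"bone{k}", g))
    return WristMaskSet(subject_id=subject, side=side, timepoint=tp, masks=tuple(masks))


@pytest.fixture
def mask_set_factory():
    return random_mask_set


def fabricated_cohort(n_subjects=50, seed=0, missing_tss_subjects=()):
    """A cohort table with plausible fabricated metrics (no rendering).

    Metrics are monotone functions of the synthetic latent severity plus
    noise, so correlations exist but the table is cheap to build.
    """
    cohort = simulate_cohort(seed=seed, params=_params(n_subjects))
    rng = np.random.default_rng(seed + 10_000)
    truth = cohort.ground_truth
    rows = []
    for _, t in truth.iterrows():
        base = 1.0 - t["lam"]
        row = {"subject_id": t["subject_id"], "side": t["side"], "timepoint": t["timepoint"]}
        for i, m in enumerate(METRIC_ORDER):
            scale = 100.0 if not m.endswith("n") else 0.5
            row[m] = scale * base * (1 + 0.02 * i) + rng.normal(0, 0.02 * scale)
        row["Lbbox"] = 250.0 * base
        rows.append(row)
    frame = pd.DataFrame(rows, columns=KEY + list(METRIC_ORDER) + ["Lbbox"])
    scores = cohort.scores.copy()
    if missing_tss_subjects:
        drop = scores["subject_id"].isin(missing_tss_subjects)
        scores.loc[drop & (scores["timepoint"] == "FU"), "tss"] = np.nan
    return build_cohort_table(frame, scores)


def _params(n_subjects):
    from wristcompact import CohortParams

    return CohortParams(n_subjects=n_subjects)


@pytest.fixture(scope="session")
def cohort50():
    """Complete fabricated 50-subject cohort (200 wrist rows)."""
    return fabricated_cohort(n_subjects=50, seed=3)


@pytest.fixture(scope="session")
def rendered_cohort():
    """Small fully rendered synthetic cohort shared by integration tests."""
    cohort = simulate_cohort(seed=11, params=_params(8))
    from wristcompact import metrics_table

    frame, exclusions = metrics_table(cohort.iter_mask_sets())
    assert not exclusions
    return cohort, build_cohort_table(frame, cohort.scores)
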