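# wristcompact

Centroid-based **carpal compactness metrics** for assessing wrist joint space
narrowing (JSN) on conventional radiographs in rheumatoid arthritis, together
with the correlation-validation machinery used to compare them against
Sharp/van der Heijde (SvdH) clinical scores, and a synthetic wrist-phantom
generator so the entire pipeline is testable without patient data.

## The problem and the idea

Rheumatoid arthritis progressively destroys cartilage; on a radiograph this
appears as narrowing of the spaces between joints. In the wrist, where seven
small carpal bones overlap heavily on a posteroanterior projection,
measuring individual joint spaces is unreliable. Instead of local
measurements, this package quantifies the **global spatial contraction** of
the carpus: as joint spaces narrow, the bones crowd together, and the
configuration of their centroids contracts.

Given per-bone binary segmentation masks `M_1 … M_n` (default `n = 7`),
resampled to a common 600×600 grid, with centroids `c_k` and global centroid
`μ = (1/n) Σ c_k`, the ten metrics are:

| metric | definition |
|---|---|
| `OSS`  | `Σ_{i<j} \|M_i ∩ M_j\|` — total pairwise overlap pixel count |
| `OSSD` | standard deviation of the pairwise overlap counts |
| `RMSR` | `sqrt((1/n) Σ_k ‖c_k − μ‖²)` — RMS radius |
| `MPD`  | `(1/(n(n−1))) Σ_{i≠j} ‖c_i − c_j‖` — mean pairwise distance |
| `R50`, `R90` | median / 90th-percentile of the radial distances `‖c_k − μ‖` |
| `RMSRn, MPDn, R50n, R90n` | the four distance metrics divided by `Lbbox`, the diagonal of the centroids' axis-aligned bounding box (scale-invariant forms) |

Contraction of the configuration by a factor `(1−λ)` scales all four raw
distance metrics and `Lbbox` by exactly `(1−λ)` and leaves the normalized
metrics unchanged, so distance metrics are expected to correlate
**negatively** with clinical narrowing scores.

Validation batteries report, per analysis design (whole cohort, per
timepoint, per hand, bilateral sums, longitudinal deltas, and total-Sharp
designs), the Pearson `r`, its Fisher-z 95% confidence interval
`tanh(atanh(r) ± 1.96/√(n−3))`, and a two-sided t-test p-value
(`t = r√(n−2)/√(1−r²)`, `df = n−2`).

## Worked example

```python
from wristcompact import (WristLayout, render_wrist, compactness_vector,
                          simulate_cohort, metrics_table, build_cohort_table,
                          correlation_battery, battery_frame)

# one noise-free phantom wrist
ms = render_wrist(WristLayout(), lam=0.0, jitter_sd=0, rng=0)
vec = compactness_vector(ms)
print(f"RMSR = {vec.RMSR:.2f} px   MPD = {vec.MPD:.2f} px   R50 = {vec.R50:.2f} px")
print(f"Lbbox = {vec.Lbbox:.2f} px   RMSRn = {vec.RMSRn:.4f}   OSS = {vec.OSS} px")

# contracting the layout 30% scales the distance metrics by 0.7
contracted = compactness_vector(render_wrist(WristLayout(), lam=0.3, jitter_sd=0, rng=0))
print(f"after 30% contraction: RMSR = {contracted.RMSR:.2f} px "
      f"(ratio {contracted.RMSR/vec.RMSR:.3f})")

# a full synthetic cohort: 50 subjects x 2 sides x 2 timepoints
cohort = simulate_cohort(seed=1)
frame, _ = metrics_table(cohort.iter_mask_sets())
table = build_cohort_table(frame, cohort.scores)
battery = battery_frame(correlation_battery(table, ["entire_wrist_level"]))
print(battery[battery.metric.isin(["RMSR", "MPD", "R50"])])
```

prints

```
RMSR = 88.18 px   MPD = 127.86 px   R50 = 88.37 px
Lbbox = 244.39 px   RMSRn = 0.3608   OSS = 3857 px
after 30% contraction: RMSR = 61.73 px (ratio 0.700)
            design metric   n      r  ci_low  ci_high   p
entire_wrist_level   RMSR 200 -0.899  -0.923   -0.869 0.0
entire_wrist_level    MPD 200 -0.899  -0.923   -0.868 0.0
entire_wrist_level    R50 200 -0.857  -0.890   -0.815 0.0
```

The RMSR ratio confirms the exact contraction law (up to rasterization); the
battery recovers the strong negative link between centroid compactness and
the generated narrowing subscore (the synthetic link is deliberately
stronger than what is observed clinically).

The same pipeline is available from the shell:

```bash
wristcompact simulate --seed 1 --out cohort/
wristcompact metrics --masks cohort/ --out out/metrics.csv
wristcompact correlate --metrics out/metrics.csv --scores cohort/scores.csv --out out/
```

`correlate` writes one CSV per analysis table (`table3.csv` … `table11.csv`)
plus scatter plots of RMSR, MPD and R50 against the score.

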