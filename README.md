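# fossa-gii

Transseptal puncture (TSP) site scoring and training analytics.

TSP — crossing the interatrial septum through the fossa ovalis (FO) — is the
gateway step for left-sided cardiac interventions such as atrial
fibrillation ablation.  Where the needle crosses matters, because the
puncture site becomes the pivot for every subsequent catheter maneuver
inside the left atrium (LA).  This package is for researchers and simulator
builders who want to quantify that choice: it scores every candidate site on
an FO mesh by catheter maneuverability, maps which LA regions a site can
reach, and computes the statistics used to evaluate operator performance on
a TSP training phantom.

## The model

The inserted catheter segment is a constant-curvature arc launched along the
inward FO normal at the pivot, with controls **u** = (φ, θ, s): bending-plane
angle, total bend θ = κℓ, and normalized insertion s = ℓ/ℓ_max.  The tip
Jacobian

&nbsp;&nbsp;&nbsp;&nbsp;J = ∂**x**/∂**u**

maps control motion at the FO to tip motion **x** in the LA, and each
candidate site is scored by the global isotropy index

&nbsp;&nbsp;&nbsp;&nbsp;GII = σ_min(J) / σ_max(J) ∈ [0, 1],

aggregated over the workspace of LA sample points the site can reach under
configuration limits that forbid looping (θ ≤ π, bounded insertion and
curvature).  GII = 1 means the catheter moves equally easily in every
direction; 0 means a direction of motion is lost.  The optimal puncture site
is the GII argmax.  Reachability from a pivot is decided by closed-form
inverse kinematics.  The analysis stack adds per-operator puncture-distance
tables, Pearson correlations with procedural time, Bland–Altman agreement
of caliper-vs-STL measurements, a Kruskal–Wallis inter-rater test and Likert
questionnaire descriptives.  A synthetic-study generator produces all inputs
(geometry, puncture cohorts, measurement pairs, questionnaires) with known
ground truth; see `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from scipy.spatial import cKDTree
from fossa_gii import (
    SyntheticConfig, make_geometry, make_fo_patch, sample_la_interior,
    score_field, mode_score, pivot_frame_at, map_reachability,
    make_cohort, distance_metrics, correlate,
)

cfg = SyntheticConfig(seed=1)
la, fo, thickness = make_geometry(cfg)          # LA ellipsoid + FO disc (mm)
patch = make_fo_patch(cfg, fo, thickness)       # candidates, normals, centroid
samples = sample_la_interior(la, spacing=2.5)   # discrete LA workspace
field = score_field(patch, samples)             # GII per candidate
center, count = mode_score(field)
print(f"FO candidates: {len(patch)}, LA samples: {len(samples)}")
print(f"optimal site: {np.round(field.argmax_point, 2)} mm, GII = {field.argmax_score:.4f}")
print(f"modal GII bin: {center:.3f} (count {count})")
reach = map_reachability(pivot_frame_at(patch, field.argmax_index), samples)
print(f"reachable from optimum: {100 * reach.fraction_reachable:.1f}% of the LA")

cohort = make_cohort(cfg, field, patch.centroid)      # simulated punctures
table = distance_metrics(cohort, field.argmax_point, patch.centroid)
print(table[["participant", "experience_years",
             "mean_dist_centroid", "sd_dist_centroid"]].round(2).to_string(index=False))
pts = cohort[["x", "y", "z"]].to_numpy()
_, idx = cKDTree(field.fo_points).query(pts)
r = correlate(field.scores[idx], cohort["time_s"].to_numpy())
print(f"GII-time correlation: r = {r.r:.3f}, p = {r.p:.4f} (n = {r.n})")
```

prints

```
FO candidates: 193, LA samples: 2062
optimal site: [-24.   -0.   -3.46] mm, GII = 0.0174
modal GII bin: 0.015 (count 99)
reachable from optimum: 90.0% of the LA
participant  experience_years  mean_dist_centroid  sd_dist_centroid
  cardio_25              25.0                3.48              0.59
  cardio_14              14.0                4.34              1.86
 cardio_10a              10.0                3.21              1.00
 cardio_10b              10.0                2.50              1.52
    trainee               0.0                6.06              2.37
GII-time correlation: r = 0.588, p = 0.0064 (n = 20)
```

The optimal site sits in the inferior half of the synthetic fossa, 90% of
the sampled LA is reachable when pivoting there, the trainee's punctures
scatter about twice as far from the FO centroid (its thinnest point) as the
experienced operators', and procedural time rises with the puncture site's
GII — sites offering better maneuverability take longer to select and
engage.

The same flows are scriptable from a shell: `fossa-gii synth`, `fossa-gii
score`, `fossa-gii reach`, `fossa-gii analyze`, `fossa-gii run --synth
--seed 0 --out run/` (see `--help` on each verb).  A full run writes
`report.json`, the per-candidate GII field, reachability and distance
tables, STL/PLY exports and a provenance manifest; two runs with the same
seed are byte-identical apart from the manifest timestamp.

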