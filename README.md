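# sausi

Quantification of rodent **social aversion** in a two-chamber + tunnel
assay, from two-mouse keypoint trajectories and scored behavioral event
logs. Built for computational-ethology work where an experimental mouse
(after a 3-minute solo baseline) can freely approach, investigate, hesitate
toward, or avoid a conspecific during a 10-minute dyadic test.

The package provides:

- **Ethogram scoring** — every standard behavioral measure per subject:
  sniffing (face/body/anogenital/tail and their sum *All Sniff*),
  conspecific sniff bouts, social reactivity
  (`reactivity bouts / conspecific sniffs x 100%`), social freezing, tunnel
  hesitancy (first-entry sheltering, reversing, latency to the social
  chamber), prosocial initiations, social-chamber preference
  (`social time / total time x 100%`), grooming, non-social freezing,
  aggression, jumps, baseline thigmotaxis.
- **A composite social-aversion index** — each behavior z-scored over the
  cohort, sign-aligned so that higher = more aversive (motivation metrics
  negated), then averaged:
  `aversion_i = mean_b [ s_b * (x_ib - mean(x_b)) / sd(x_b) ]`
  with per-category sub-scores (social fear / hesitancy / motivation) and
  pooled-variance two-tailed t-tests between groups.
- **Housing-state decoding** — L2-penalized binary logistic regression on
  standardized features (scikit-learn style `HousingDecoder`), reporting
  training accuracy and coefficient magnitudes as feature importances.
- **An unsupervised behavior map** — track interpolation, posture angle
  features, PCA (95% variance), 2-D UMAP embedding, Gaussian-KDE density,
  watershed segmentation into regions by steepest-ascent basins,
  per-subject region occupancy, per-region statistics, and occupancy-based
  decoding.
- **Threat-imminence profiles** — behavior rates binned on nose-nose
  distance, plus lossless per-session raster structures.
- **A synthetic cohort generator** — fully ground-truthed two-mouse
  sessions with condition-dependent behavioral structure (group-housed vs
  isolated contrasts), rigid 8-node skeletons, keypoint jitter, missing
  points and identity-swap artifacts, so the entire pipeline is testable
  without any video data.

See `docs/methods.md` for the model, conventions, and limitations.

## Worked example

Simulate a small cohort, score it, and compute the aversion index:

```bash
sausi simulate --n-per-group 4 --seed 7 --out demo/cohort
sausi score    --cohort demo/cohort --out demo/scores.csv
sausi aversion --scores demo/scores.csv --out demo/aversion.json
sausi decode   --features demo/scores.csv --label-col condition --out demo/decoder.json
```

prints

```
wrote 8 sessions to demo/cohort
scored 8 subjects -> demo/scores.csv
aversion index -> demo/aversion.json
training accuracy 1.000 -> demo/decoder.json
```

and `demo/aversion.json` contains (abridged):

```json
{
  "group_means": { "GH": -0.272, "SI": 0.272 },
  "t": -1.608,
  "p_two_tailed": 0.159,
  "df": 6
}
```

Read: isolated (SI) subjects score about half a standard unit higher on the
composite aversion index than group-housed (GH) subjects; at 4 animals per
group this particular draw does not reach significance (p = 0.16) — at the
default 18 per group the contrast is large (standardized effect ~2) and
highly significant. The decoder separates the 8 training subjects
perfectly, which at this size mostly reflects the optimism of training
accuracy (see `docs/methods.md`).

The same workflow in Python:

```python
from sausi.study import run_cohort

res = run_cohort(seed=0)      # 18 GH + 18 SI subjects, full pipeline
print(res.effect_size)        # composite aversion effect (SI - GH), d units
print(res.feature_accuracy)   # behavior-score decoding (training)
print(res.occupancy_accuracy) # behavior-map occupancy decoding (training)
```

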