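# Methods

## The assay and what the package computes

The package quantifies social aversion in a two-chamber assay: an
experimental mouse spends a 3-minute solo baseline in its home chamber,
then a 10-minute dyadic test in which a docile conspecific occupies the
social chamber, reachable through a tunnel. The animal is free to approach,
investigate, hesitate in the tunnel, or retreat, so the assay exposes the
full threat-imminence continuum — pre-encounter hesitancy (sheltering in the
tunnel, reversing, long latency), encounter-range fear (freezing during or
within 1 s of being sniffed, darting/flinching reactivity), and social
motivation (prosocial initiations, social-chamber preference).

Analysis proceeds in four stages, each usable on real scored data and on
synthetic cohorts:

1. **Ethogram metrics** (`sausi.ethogram`). Every behavior-score-table
   column is computed from the event log and trajectory. Conventions that
   matter: spans are half-open `[start, end)` for point-event inclusion and
   state intervals are clipped to the span; `All Sniff` is defined as the
   sum of the face, body, anogenital and tail sniff durations; social
   reactivity is reactivity bouts / conspecific sniff bouts x 100%, and is
   *flagged* (NaN) rather than zeroed when the conspecific never sniffed;
   chamber preference is social-chamber time / span length x 100% with
   tunnel and untracked time in the denominator only; first tunnel
   sheltering sums *all* shelter intervals that precede the first
   social-chamber entry; latency is flagged NaN for a subject that never
   enters. Zone membership uses the trunk node inside the chamber polygons —
   the closest stable single-node surrogate for the "all four paws"
   convention of manual scoring, since paws are not tracked. Thigmotaxis is
   the fraction of baseline frames with the trunk within 2 cm of the
   home-chamber wall (no threshold is standard; 2 cm is roughly one body
   half-width).

2. **Composite aversion index** (`sausi.aversion.AversionIndex`). Each
   behavior entering the index is z-scored against a reference population —
   the pooled cohort by default, with sample (n-1) sd — and multiplied by an
   aversion sign: fear and hesitancy metrics carry +1, motivation metrics
   (prosocial initiations, chamber preference) carry -1 so that the index is
   monotone increasing in aversion. The composite is the mean of the
   sign-aligned z-scores over the behaviors defined for that subject;
   flagged entries are skipped rather than imputed. Per-category sub-means
   (fear / hesitancy / motivation) are reported alongside. Group differences
   use Student's pooled-variance two-tailed t-test (Welch available via
   `equal_var=False`).

3. **Decoding** (`sausi.aversion.HousingDecoder`). Binary logistic
   regression on internally standardized features minimizing
   `sum log(1+exp(-s_i(x_i.w+b))) + l2/2 ||w||^2` by L-BFGS from a zero
   start (deterministic; tolerance 1e-10 so the gradient at the reported
   optimum is numerically zero). The reported quantity is *training*
   accuracy — the fraction of subjects correctly labelled on the fitting
   data — which is the assay-summary convention this package mirrors; it is
   optimistically biased at small n and must not be read as generalization
   accuracy (on null cohorts of 36 subjects with ~20 features it sits near
   0.8). The default penalty `l2_strength=1` is deliberately weak (penalty
   << n at the default cohort sizes) and is recorded in every report.
   Flagged-missing feature values are mean-imputed before decoding, which is
   neutral (z=0) on the standardized scale.

4. **Behavior map** (`sausi.behavior_map`). Gap interpolation (linear, per
   node, gaps <= 0.5 s; longer gaps stay invalid and those frames are
   dropped) -> posture angle features -> per-feature z-normalization over
   pooled frames -> PCA keeping the smallest dimensionality reaching 95%
   variance (deterministic sign convention) -> 2-D UMAP
   (n_neighbors=15, min_dist=0.1, fixed random_state; a deterministic
   PCA backend is available for degraded environments) -> binned Gaussian
   KDE on a 200x200 grid over the 5%-padded bounding box (Scott's-rule
   bandwidth) -> watershed into regions -> per-subject occupancy ->
   per-region t-tests and occupancy decoding.

   The angle set is: interior angles nose-head-trunk (head flexion),
   left_ear-head-right_ear (ear spread), head-trunk-tail_base (spine bend)
   and left_hip-trunk-right_hip (hip spread) for each animal, plus the
   cosine of the inter-animal heading difference — nine rotation- and
   translation-invariant features. Temporal derivatives are available behind
   a flag and off by default; a wavelet stage is deliberately not part of
   the default pipeline.

   The watershed is implemented directly as steepest-ascent basin
   assignment: every grid cell points to the maximum-density cell among
   itself and its 8 neighbors (ties broken toward the lowest flat index),
   chains are collapsed by pointer jumping, and each local maximum seeds a
   region. Regions are numbered 1..K by descending peak density — a stable,
   data-derived ordering. Regions smaller than 0.1% of occupied cells merge
   into the neighbor with the densest shared boundary. Regions whose member
   frames are >50% flagged (missing or interpolated source coordinates) are
   excluded from decoding by default, mirroring the practice of dropping
   map regions dominated by tracking failures.

5. **Imminence profiles** (`sausi.continuum`). Test-phase frames with a
   valid nose-nose distance are binned on distance (2-cm bins from 0 to the
   arena diagonal by default); state behaviors report the fraction of bin
   frames active, point behaviors report events per bin-second; empty bins
   are flagged NaN, and frames with an invalid nose are excluded, not
   imputed. Rasters are lossless: the interval structure reconstructs the
   event log exactly.

## The synthetic cohort generator

No trajectory data are deposited for this assay, so the generator *is* the
study condition for every quantitative check. It simulates the session as a
semi-Markov sequence of behavioral segments, with the test phase split into
a hesitancy stage (home exploration -> tunnel shelter -> reverse-or-commit
loop, which generates latency, sheltering and reversing organically) and a
dyadic stage (idle / locomote / groom / approach-and-sniff / aggression /
home visits, with conspecific sniff bouts arriving as a Poisson process
while the subject is unengaged in the social chamber; each sniff triggers
social freezing or reactivity with condition-dependent probabilities).

Rendering: the body center follows straight polyline legs at state-specific
speeds; heading follows motion; the 8-node skeleton is rigid within each
segment, with per-segment posture draws — elongation, head yaw (nose and
ears rotated about the head), spine bend (rear nodes rotated about the
trunk), and hip spread. Postures are state-specific (freezing is hunched,
wide, still; sheltering compressed; grooming curled with large head yaw;
sniffing stretched with the head cocked), which is exactly what gives the
angle-feature embedding its multimodal structure. Gaussian keypoint jitter
(sd 0.12 cm), random missing points (1% of cells), and optional identity
swap windows are added on top; the conspecific is absent (invalid) during
the baseline.

Group contrast defaults (GH = group housed, SI = isolated) are **invented
calibrations, not measured effect sizes** — the source material reports
direction and significance, not magnitudes. SI multiplies
P(freeze | sniffed) x10, P(react | sniffed) x3, mean shelter dwell x4 and
aggression propensity x5, halves initiation propensity, doubles the
tunnel-reverse probability, and leaves chamber-preference parameters
untouched. At 18 subjects per group these defaults give a composite
aversion effect of d about 1.5-2.9 with the isolation direction on every
category, i.e. clearly separated but overlapping groups.

What the generator does *not* emulate: video pixels, pose-estimation error
structure (its misses are uniform, not occlusion-driven), ultrasonic
vocalizations, conspecific deterrent shocks, within-bout kinematic texture
(gait), or sex differences. Passing tests therefore demonstrate that the
analysis chain is correct and sensitive under known ground truth — not that
any particular real cohort will show these effect sizes.

## Numerical choices and degenerate inputs

- Event times in the generator land on the frame grid, so event-derived
  durations and frame-based recomputation agree exactly.
- z-scoring raises on zero-spread behaviors (the error names the behavior);
  decoding guards zero-spread features by leaving them at zero after
  standardization.
- The pooled t-test flags zero-pooled-sd inputs as degenerate instead of
  dividing by zero.
- The KDE density is normalized to integrate to 1 on the grid; watershed
  ties (exactly equal neighboring densities) break toward the lower flat
  index, deterministically.
- UMAP is run with a fixed `random_state`, making the whole pipeline
  bit-reproducible for a fixed master seed.
- Analyses that embed frames subsample the test phase at one frame per two
  seconds (stride 60 at 30 fps); occupancy fractions are unbiased under
  uniform subsampling and the embedding stays tractable on one core.

## Known limitations

- Training accuracy (the reported decoding quantity) is not a
  generalization estimate; no cross-validation is offered by design.
- The trunk-in-polygon zone rule differs from the manual "all four paws"
  convention near chamber boundaries.
- Region identities are cohort-specific: region k of one cohort has no
  correspondence to region k of another beyond its density rank.
- The reverse-in-tunnel contrast is mild by design; it is usually
  non-significant on its own at the default cohort size.
- With undersmoothed KDE bandwidths the estimated density genuinely has
  extra modes and the watershed reports them; region counts are a property
  of (bandwidth, grid, data), not of the underlying behavior alone.
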