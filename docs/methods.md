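# Methods

`multisplit` implements the multi-reader multi-split approach to acquiring
slice-wise visual emphysema annotations on chest CT, together with the
statistical machinery needed to judge whether such annotations are usable:
chance-corrected inter-observer agreement, reader-bias screening, spatial
consistency, and validity against coarser regional reference scores. This
note records the models, conventions and numerical choices the package
makes, and what its synthetic studies can and cannot demonstrate.

## Study design

Each subject's CT stack is reduced to the contiguous slice range from the
pulmonary apex to the lung base and tiled, apex downward, into chunks of
`ceil(chunk_extent / slice_thickness)` slices (17 slices of 0.6 mm for the
default 1-cm extent, i.e. 10.2 mm per chunk). The chunk size is a fixed
integer slice count rather than a physical 10.0-mm window so that every
chunk carries the same amount of image data; a trailing block shorter than
one chunk at the lung base is dropped for the same reason.

Lung zones follow the standard regional convention: upper = apex to
carina, middle = carina to lower pulmonary vein, lower = vein to base. A
chunk belongs to the zone containing its center slice (rounded down for
even-length chunks), with half-open boundaries toward the feet — a chunk
centered exactly on a landmark belongs to the zone below it. All slice
indices are 0-based. Per zone, the chunk whose center is nearest the
midpoint of the zone's slice range becomes the *multi-reader chunk* (ties
toward the smaller chunk index); the remaining chunks are *single-reader
chunks*. Any empty zone is an error: the design requires one mid-zone
chunk per zone per subject.

## Task assignment

Each of the `n_readers` readers receives `quota_multi` multi-reader chunks
(default 75) sampled uniformly without replacement, independently across
readers — so multi-reader chunks are shared and the number of readers per
chunk disperses binomially (mean `n_readers * quota_multi / n_multi`,
about 6.4 and median 6 at the default 26 readers and 306 multi-reader
chunks) — plus a share of the single-reader pool (default quota 100). The
single pool is permuted once and dealt round-robin, which guarantees
exactly-once coverage; when the pool cannot fill every quota (2575 singles
cannot give 26 readers 100 each), shares stay as equal as possible
(spread ≤ 1) and a shortfall warning is logged. The plan is a
deterministic function of the inputs and the seed.

## Synthetic reader studies

No annotation data ship with the package, so every downstream stage is
exercised against a generative model with the qualitative structure the
analyses are meant to detect. It is an ordered-threshold (ordered-probit)
reader model on a latent severity scale:

- **Subjects.** Latent severity of subject *j*, side *s*, chunk *k*:
  `S_j + g_j (1 − k/(K−1)) + w(k)`, with `S_j ~ N(mean_severity,
  severity_sd²)` (defaults −0.5, 1.0), an apical gradient
  `g_j ~ Gamma(2, apical_gradient/2)` (mean 0.8) so disease is worst near
  the apex, and `w` the sum of a random walk shared by both lungs and a
  per-side walk (per-step sd `smoothness_sd/√2` each, default total 0.15),
  so the two sides track each other without being identical. A
  `control_fraction` (default 6/102, the control share of a cohort of
  emphysema subjects plus a small control group) of subjects is
  emphysema-free: their latent
  field is clamped below the first cutpoint. Affected subjects carry one
  true subtype drawn with centrilobular predominance
  (0.55/0.20/0.15/0.05/0.05 over centrilobular, paraseptal, combined,
  panlobular, bullae). Chunk counts are drawn to land in 23–33 per subject
  (mean ≈ 28), matching a mid-fifties screening cohort scanned at 0.6 mm.
- **Readers.** Reader *r* reports the bin of
  `latent + bias_r + N(0, noise_sd_r²)` under cutpoints (0.5, 1.5, 2.5),
  giving the ordinal score 0–3 (none, mild, moderate, severe). Biases are
  `N(0, bias_sd²)` (default 0.3) — some readers systematically over- or
  under-call severity — and noise is jittered around 0.5 per reader. The
  reported type is "none" iff the score is 0, otherwise the subject's true
  subtype, swapped for a uniformly random other subtype with probability
  `type_confusion_prob` (default 0.10). The default cutpoints put most
  mass on scores 0 and 1, as visual scoring of a screening cohort does.
- **Reading times.** One lognormal time per (reader, chunk): median 20 s
  if the reader scored either side positive, else 10 s, `log_sd` 0.5;
  with probability 0.02 the time is inflated above 180 s to emulate a
  pause left running in the annotation tool.
- **Regional reference scores.** A per-(subject, side, region) score is
  derived by binning `0.5·(mean + max)` of the region's chunk latents plus
  `N(0, 0.25²)` noise — a regional reader weighs the worst area more than
  the average — with each region missing with probability 2/612
  (the observed rate of missing reference scores per region).

What passing tests show, and what they do not: the generator reproduces
the qualitative findings the analysis stage must detect (apical
predominance, reader bias, cranio-caudal smoothness, 10 s vs 20 s
timing), so green tests demonstrate that the pipeline *detects structure
that is present* and stays calm when it is absent. They do not certify
real-world agreement levels: actual alphas depend on reader behavior the
model does not attempt to capture (experience, fatigue, subtype-specific
difficulty, correlated errors).

## Krippendorff's alpha

Alpha handles any number of readers, missing entries, and both scales in
play here (nominal subtype labels, ordinal 0–3 scores), which is why it is
the agreement coefficient of choice for this not-fully-crossed design.
One unit is one (chunk, lung side). Units with fewer than two ratings are
excluded; within-unit rating pairs accumulate into a coincidence matrix
with weight `1/(m_u − 1)`, and

```
alpha = 1 − (n − 1) · Σ_{c<k} o_ck δ²_ck / Σ_{c<k} n_c n_k δ²_ck
```

with the identity metric for nominal data and Krippendorff's
cumulative-marginal difference `(Σ_{g=c..k} n_g − (n_c + n_k)/2)²` for
ordinal data. Conventions worth stating:

- Zero expected disagreement (all pairable ratings in one category)
  yields NaN with a warning, not 1.0 — unanimous use of a single category
  says nothing about reliability.
- Confidence intervals are percentile bootstrap over units (chunk-sides),
  default 1000 replicates, deterministic under a seed; undefined
  replicates are dropped and counted. Resampling subjects instead of
  units would widen intervals when chunks within a subject correlate;
  units were chosen as the resampling atom because the unit is also the
  rating atom, and the per-zone tables treat left and right sides as
  separate units throughout.
- The implementation is validated against a brute-force oracle that
  enumerates rating pairs directly, on hundreds of randomized small
  instances, and against invariances (unit/reader permutation, nominal
  relabeling, ordinal scale reversal). Exact invariance under duplicating
  every unit holds only up to the `(n−1)/n` chance correction, which is
  negligible from a few hundred ratings upward; the test asserts
  invariance at 0.01 tolerance on data of that size.

## Downstream analyses

- **Reader bias.** Readers × class contingency tables (scores; types;
  regional reference score of each assigned chunk, the last checking that
  random assignment itself was homogeneous) are tested with the Pearson
  chi-square without continuity correction; all-zero columns and rows are
  dropped before computing degrees of freedom, and expected counts below
  5 trigger a warning.
- **Consensus.** A multi-reader chunk-side collapses to the modal
  emphysema type (ties: higher total score mass, then the fixed order
  none < centrilobular < paraseptal < combined < panlobular < bullae) and
  the *lower* median of the scores carried by that type; modal "none"
  forces score 0. The lower median keeps the consensus on the observed
  ordinal scale for even counts.
- **Consistency.** Per (subject, side), absolute score differences of
  adjacent chunks (consensus scores for multi-reader chunks, the single
  score otherwise), a histogram over 0–3, and the median. Runs are broken
  at gaps in the chunk index so only physically adjacent chunks are
  compared. The outlier rule flags interior chunks differing by at least
  `min_jump` (default 2) from both neighbors in the same direction —
  spikes and dips, not sustained steps — and end chunks differing that
  much from their single neighbor. The rule is intentionally blind to ±1
  excursions, which are ordinary inter-reader variation.
- **Validity.** Each chunk-side maps through its zone to a (subject,
  side, region) reference cell; the 4×4 cross-tab of reference score vs
  final chunk score is reported with row proportions and a chi-square.
  Chunk-sides whose region lacks a reference score are excluded and both
  the region count and the chunk-side count are reported. Perfect
  diagonal agreement is not expected — a region is ~9 cm of lung scored
  as one number, so regions referenced as mild legitimately contain many
  unaffected centimeter chunks.
- **Reading times.** One time per (reader, chunk); times strictly above
  3 min are treated as pauses and excluded. Emphysema status uses the
  annotating reader's own scores (timing is a per-reader behavior, not a
  property of the consensus). Groups are compared with the two-sided
  Wilcoxon rank-sum test in its tie-corrected normal approximation
  (appropriate for large samples with heavily tied integer-second data);
  when all kept times are identical the p-value is 1 by convention, and
  an empty group skips the test with a warning. Reported medians pool all
  readers' chunks rather than averaging per-reader medians.

## Problem sizes and determinism

The default configuration is the full study scale: 102 subjects,
~28 chunks each, 26 readers, 75 + 100 tasks per reader, 1000 bootstrap
replicates — one end-to-end run takes a few seconds on one core, so tests
and examples use this scale directly, with Monte-Carlo checks at 20
replicates and a few smaller cohorts where many replicates are needed.
Every stage takes an explicit seed; the runner derives per-stage seeds
from one master seed via a seed sequence, and identical configs produce
byte-identical output files (each stamped with the config hash).

## Limitations

- The generative model is a deliberately minimal ordered-threshold
  construction; it makes no attempt at image-level realism, reader
  learning or fatigue, subtype-specific difficulty, or correlated errors
  between readers.
- Reader-bias magnitudes are calibrated only to qualitative behavior
  (clearly detectable heterogeneity), not to measured inter-reader
  spreads.
- Alpha here covers nominal and ordinal metrics only; interval/ratio
  difference functions, Cohen's/Fleiss' kappa and intra-observer designs
  are out of scope.
- The outlier flag is a screening rule for visual review, not a
  correction procedure; flagged labels are reported, never altered.
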