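# Methods

## Setting and model

A crowd-grading study presents each of N images to K anonymous workers, who
each cast one binary vote (normal / abnormal). An expert panel has assigned
every image a three-level reference grade — normal, mildly abnormal,
severely abnormal — which is binarized (mild and severe are both abnormal)
for accuracy analysis. The package evaluates the crowd against that
reference with stratified sensitivity/specificity, a strict-majority vote
analysis, and nonparametric ROC statistics, and contains a simulator whose
output has exactly the vote structure these analyses assume.

The simulator's generative model is deliberately minimal:

- **Votes.** A vote on an image of grade *g* is correct with probability
  `expit(logit(p_correct[g]) + a_w)`, where `p_correct[g]` is the
  per-stratum per-vote accuracy (for normal images the per-vote specificity,
  for mild/severe the per-vote sensitivity) and `a_w` is the worker's
  ability offset. Votes are conditionally independent given worker and
  image stratum — image-level difficulty beyond the three strata is not
  modeled.
- **Workers.** Ability offsets are drawn once per study from
  N(0, 1/`heterogeneity_conc`) on the log-odds scale. The default
  concentration is infinite (all offsets zero): a homogeneous crowd whose
  aggregate proportions equal the configured accuracies in expectation,
  which is what calibration to published aggregate tables requires. Finite
  concentrations are opt-in and produce between-worker overdispersion.
  When a stratum accuracy is exactly 0 or 1 the logit is undefined and the
  probability is used as-is, so "perfect" presets stay perfect.
- **Assignment.** Each image's K voters are sampled without replacement
  from a pool of `pool_size` workers with probability proportional to a
  per-worker activity weight, drawn from a gamma distribution whose mean
  and SD equal the configured tasks-per-worker moments. This reproduces the
  heavy-tailed participation seen in real crowds (a few workers do most of
  the work) without attempting exact participation-moment matching. A
  worker can never vote twice on one image; `pool_size >= K` is enforced.
- **Durations.** Per-task durations are log-normal with the configured
  mean/SD (seconds); they are carried through I/O but never analyzed.
- **Seeding.** One integer seed spawns one named substream per concern
  (worker profiles, assignment, responses, durations) via
  `numpy.random.SeedSequence`, so identical inputs give bit-identical
  datasets and adding a concern cannot perturb the others.

Eight calibration presets fix (`design_id`, trial) ∈ {four reward/eligibility
designs} × {two repeat trials} at the operating points of a published
crowdsourced retinal-grading study: per-stratum accuracies from its
sensitivity/specificity table, pool sizes, tasks-per-worker and duration
moments from its participation table, K = 20, reward 0.03–0.05 USD per
task. The study's "proportion correctly identified" rows reflect a stricter,
undefined correctness criterion (involving a feature drop-down that the
crowd also answered); they are stored as preset metadata and never used —
the detection-level sensitivity/specificity rows are the calibration.

## Aggregation rules

- **Strict majority.** An image is majority-correct iff strictly more than
  half its votes match the binarized reference; an exact 50/50 split counts
  as incorrect in both directions. This is the literal reading of a ">50%"
  rule and is monotone: adding a correct vote never revokes a correct call.
- **Pooling and rounding.** Printed percentages are rounded half-up to
  integer percent. Pooled sensitivity over the abnormal strata is the
  count-weighted mean of the stratum sensitivities; pooled majority
  percentages first reconstruct integer image counts per stratum
  (`round_half_up(pct/100 × N)`) because the underlying quantity is a count.
  This rule reproduces the published pooled cells from their printed strata
  in 14 of the 16 checkable cells (7 of 8 overall sensitivities, 7 of 8
  any-abnormality majority percentages); the two exceptions (both in the
  second trial) are
  internally inconsistent in the source at integer precision — consistent
  with the source having pooled unrounded raw proportions — and are
  documented rather than reproduced.
- **Absent strata** are omitted from summaries (never reported as 0/0);
  an image with zero votes is an error for per-image operations.

## ROC statistics

- **AUC** is the tie-corrected Mann-Whitney statistic, computed from
  midranks; it equals the brute-force pairwise count (concordant pairs plus
  half the ties) and is invariant to strictly increasing score transforms.
- **Scoring modes.** `per_classification` treats each vote as one
  binary-scored observation; with empirical sensitivity s and specificity c
  the statistic is exactly (s+c)/2, the single-operating-point rater AUC.
  This mode is the default for reproducing published per-design AUCs, all
  of which match (s+c)/2 within printed rounding. `per_image` scores each
  image by its vote fraction (N observations) and is the mode in which
  aggregating more voters helps; it drives the graders curve.
- **Confidence intervals** are normal approximations clipped to [0, 1],
  with variance from either the Hanley–McNeil exponential approximation
  (Q₁ = A/(2−A), Q₂ = 2A²/(1+A)) or the DeLong structural components.
  DeLong is the default: it is distribution-free and shares machinery with
  the comparison test; Hanley–McNeil is retained as the classic
  Mann-Whitney companion. Degenerate perfect-separation data yields a
  clipped upper bound of exactly 1.
- **Curve comparison** is the DeLong paired z test,
  z = (A₁−A₂)/√(v₁+v₂−2c₁₂), two-sided normal p. Identical score vectors
  return (z, p) = (0, 1) rather than 0/0; a zero-variance difference with
  unequal AUCs raises.
- **AUC vs number of graders.** For each k, votes are subsampled without
  replacement per image, images are re-scored by the subsampled fraction,
  and the per-image AUC is averaged over resamples. At k = K the subsample
  is the data itself, so a single deterministic point with SD 0 is
  recorded. `peak_k` breaks ties toward the smallest k (the cheapest
  design). The location of the peak in the original study (16 of 20
  graders) depends on its unpublished raw votes; only the qualitative
  shape — steep early rise, flat tail — is asserted anywhere.

## What the simulator does and does not establish

Passing tests show that the pipeline's statistics are correct on data with
the assumed structure, and that crowds calibrated to the published
operating points reproduce the published aggregate AUCs and majority
percentages. They cannot show anything about real images: per-image
difficulty variation within a stratum, worker learning, spam, response-time
/ accuracy coupling and queue dynamics are all outside the generative
model, and the simulator's worker pool is exchangeable where a real one is
not. The wide per-image vote ranges published for real data arise here only
from binomial noise (or opt-in worker heterogeneity), not from image
content.

## Problem sizes and tolerances

Stochastic tests run at the study's own scale (100 images × 20 votes =
2,000 classifications) or modest multiples of it: parameter recovery uses
1,200 votes per stratum and a 3-binomial-SE band; the published-AUC
reproduction averages 200 replicate studies and requires agreement within
±0.01; CI coverage uses 300 simulations of n = 2,000 and accepts
[0.92, 0.98]; the binomial-tail and enumeration oracles use exact closed
forms. All simulations are seeded; the hypothesis suites are derandomized.

## Known limitations

- The vote-level CSV schema is this package's own; no public schema exists
  for the source study's raw data.
- Only raw-fraction and strict-majority aggregation are provided — no
  probabilistic label fusion (e.g. EM-style worker-quality models), matching
  the analysis being reproduced.
- The binary-rater identity makes per-classification AUC a deterministic
  function of (sensitivity, specificity); its CI still reflects vote-level
  sampling only, not image-level clustering of votes.
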