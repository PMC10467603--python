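# Methods

`prognosig` implements a three-phase pipeline for building and evaluating
prognostic gene-expression signatures in stage II colorectal cancer:
(1) a genome-wide survival screen across several cohorts, (2) a
recurrence-score system with beam-search refinement of the gene set, and
(3) an evaluation battery (Kaplan–Meier, log-rank, Cox, ROC, risk curves,
covariate-adjusted models).  A synthetic-data generator with planted
prognostic structure makes every stage testable without external
downloads.  This note records the statistical model of each stage, the
parameters that matter, the numerical conventions, and what the synthetic
conditions do and do not demonstrate.

## Survival primitives

**Kaplan–Meier / log-rank / Cox.**  The product-limit estimator,
multi-group Mantel–Cox test and proportional-hazards regression are
delegated to lifelines; ties in the partial likelihood use the Efron
approximation, which is accurate for the heavily tied integer recurrence
scores.  Group-wise observed/expected event counts are computed in-package
from the pooled risk sets.  Test oracles (exact rational product-limit,
explicit O−E/variance loops, brute-force concordance) are independent
re-derivations, not lifelines calls.

**Maximally selected cutpoint.**  Expression markers are dichotomized at
the cut-off maximizing the standardized two-group log-rank statistic
|z| = |O₁−E₁|/√V over the midpoints of consecutive sorted unique values.
Admissible splits must keep at least `minprop` (default 0.1) of the
samples on each side; exact statistic ties resolve to the smallest
cutpoint, making the scan fully deterministic.  This is implemented as a
vectorized pooled-risk-set engine (`_logrank.py`): the risk-set structure
of a fixed (time, event) sample is pre-computed once, after which
thousands of candidate group assignments — cut levels for one gene, or the
score vectors of a whole beam generation — are evaluated with a handful of
array passes.  The batched path runs in single precision with double
precision accumulation; the single-marker path is full double precision.

The p value reported at a selected cut-off is the *naive* log-rank p at
that cut.  Because the cut is chosen to maximize the statistic, this p is
anti-conservative (the classical maximally-selected-statistic optimism);
the screening stage controls errors through cross-cohort replication
instead of per-test calibration, mirroring the pipeline's design.  The
practical consequence — that even outcome-permuted data can show
apparently significant optimized splits — is why the null checks in the
test suite freeze a trained classifier before permuting outcomes.

**ROC.**  AUC equals the Mann–Whitney concordance probability (ties count
½).  The reported operating point maximizes the Youden index
(sensitivity + specificity − 1); the accuracy quoted in reports is
evaluated at that same point.  Relapse labels default to relapse-ever;
relapse-by-horizon is available.

**Risk-of-recurrence curve.**  The probability of relapse within a
120-month horizon is fit by a binomial GLM (logit link) of
event-by-horizon status on the integer recurrence score.  Samples censored
before the horizon without an event are uninformative for horizon status
and are excluded.  Single-valued scores or all/none event sets degenerate
to the observed event fraction and are flagged.

## Screening

For each gene and cohort: optimal cut-off → dichotomize → log-rank.  The
direction is *unfavorable* when the high-expression group has the excess
of events (z > 0), *favorable* otherwise.  A gene earns a verdict when it
is significant (α = 0.05) in at least `min_cohorts` (default 4) cohorts
*and* all significant cohorts agree on direction; otherwise it is
excluded.  No multiple-testing correction is applied across genes — the
replication-plus-consistency rule is the error control.  Under the null,
the chance of j significant cohorts all agreeing in sign falls by 2^(1−j),
which is what keeps the false-verdict rate of the rule low even though the
per-cohort optimized p is inflated.

## Recurrence scoring

Each signature gene contributes a 0/1 point per sample: an unfavorable
gene scores 1 strictly above its cut-off, a favorable gene strictly below;
expression exactly at a cut-off scores 0 under either direction (a
conservative convention, measure-zero for continuous data).  The signature
score is the sum, ranging 0..|genes|; high scores mean high unfavorable
and low favorable expression.  Cut-offs are cohort-specific by default and
can be frozen for applying a trained signature to new samples.  High/low
classification applies the same cutpoint machinery to the integer score.
`RecurrenceScoreClassifier` packages fit (learn cut-offs) / decision
function (scores) / predict (high/low) in scikit-learn style with
survival outcomes as y.

The seven-gene Oncotype DX colon comparator is provided two ways: the
published linear RS_U formula, and the same genes pushed through this
package's 0/1 scoring with directions taken from the signs of the RS_U
coefficients (BGN, FAP, INHBA, GADD45B unfavorable; MYBL2, KI67→MKI67,
MYC favorable).  KI67 is resolved to the official symbol MKI67 through a
small alias table.

## Beam-search refinement

Starting from all 2-gene combinations of the candidate pool, the search
keeps the `beam_width` (default 2000, as in the published search)
lowest-p combinations per size, extends every survivor by every remaining
pool gene, merges duplicates by set identity, and records the per-size
best until `max_k`.  Each combination's score cut-off is re-optimized,
which is cheap because scores are small integers.  The selected size k* is
the significance peak of the trace (smallest k on ties).  Tie-breaks at
the beam boundary use lexicographic gene order, so a fixed input yields a
byte-identical trace.  With an unlimited beam the procedure reduces to
exhaustive subset enumeration, which the tests exploit as an oracle; a
`prune_only_first` flag implements the alternative reading in which only
the 2-gene generation is pruned.

Beam search is a heuristic: no global-optimality guarantee is intended,
and for wide beams the per-size best is monotonically no worse.

## NanoString normalization and QC

Raw counts are normalized in two multiplicative steps, each equalizing
per-sample *geometric* means of a control class against their grand
geometric mean: first the positive-control dilution series (lane and
hybridization effects), then the six housekeeping genes (RNA input);
endogenous genes only are returned.  A +0.5 pseudocount enters a control
block's geometric means only when that block contains zeros, so the clean
case equalizes exactly.  Because the grand geometric mean is
data-dependent, rescaling one sample by c moves the shared reference by
c^(1/n); within-sample ratios are exactly invariant, absolute values to
~0.3% at cohort scale (n = 205).

Genes averaging strictly below 10 counts/sample are removed (the
validation-panel convention).  Outlier samples are flagged when their
relative-log-expression (RLE) median or IQR, or their position in the
first two principal components of the RLE matrix, exceeds 3.5 robust
(MAD) deviations from the cohort; the methods are standard QC practice and
the 3.5 threshold is this package's concretization, since only the
methods, not thresholds, are conventional.

## Synthetic data

`SimConfig` encodes one study: six cohorts of 150 stage II tumors with
~520 genes (10 unfavorable + 10 favorable planted), exponential baseline
relapse hazard 0.004/month, administrative censoring at 120 months, 20%
uniform early dropout, per-cohort batch location/scale effects, a pT4
covariate (prevalence 0.2, log-HR 0.8), and a NanoString block at
validation-cohort scale (205 samples, 52 test + 9 planted-low genes, six
housekeeping, six positive controls, five planted dispersed samples,
negative-binomial counts with size 20 under lognormal lane factors).

Planted genes are equicorrelated (pairwise r = 0.25) through one latent
risk program — emulating the co-expressed unfavorable programs seen in
real tumors — and the relapse hazard acts on the genes' own standardized
expressions with generative coefficients β = effect/(1+(k−1)r).  Two
properties follow: each planted gene's marginal linear-predictor slope per
expression SD equals the configured effect (default 0.8) exactly, and the
summed linear predictor keeps a plausible spread (sd ≈ 1.1–1.5) instead
of the effect·√k explosion an independent-gene model would give.  Putting
the hazard on the genes rather than on the latent factor is deliberate:
it leaves each gene idiosyncratic signal, which is precisely what the
refinement stage must be able to exploit; a factor-level hazard makes
planted genes statistically interchangeable and gene recovery
ill-defined.  Note that the observable single-gene marginal Cox
coefficient is smaller than the configured effect because of
proportional-hazards non-collapsibility (the other planted genes act as
frailty); the generative coefficients are exactly recoverable in a joint
fit.  RFS and OS share a lognormal frailty (sd 0.3) and OS uses an
attenuated (×0.5) linear predictor, so OS effects are directionally
consistent but weaker.

What the generator does *not* emulate: real platform-specific intensity
distributions, gene–gene correlation beyond the single planted program,
informative censoring, competing risks, or the marginal distributions of
any real cohort.  Passing tests therefore demonstrate that the machinery
recovers known structure under a fair proportional-hazards world — not
that the published cohort-specific numbers are reproduced, which would
require the external cohort downloads and the undeposited in-house data.

## Problem sizes and determinism

All randomness flows through numpy `SeedSequence` spawning, so every
cohort, study and count table is byte-reproducible from (config, seed).
The refinement runs in the test and acceptance suites cap the beam trace
at max_k = 20 on the 61-gene pool — the package's chosen desk scale; the
selected-size peak behavior is exercised separately on small pools where
exhaustive enumeration is feasible.  The acceptance script repeats the
screening and refinement studies over 10 generator seeds and reports
averages.

## Known limitations

- The per-cut p values are selection-inflated by design (see above); any
  absolute interpretation of a single screened gene's p is optimistic.
- Cut-offs learned on one cohort do not transfer across platforms without
  re-estimation; the frozen-cutoff mode assumes comparable scales.
- The beam search explores a vanishing fraction of subsets at realistic
  pool sizes; recovered signatures are good, not provably optimal.
- The 61-gene signature of the original development workflow is not fully
  printed in any source available to this package, so only the 15-gene
  and 7-gene Oncotype definitions ship as packaged files.
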