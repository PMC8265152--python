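# Methods

## Model and hypotheses

Survival times are modelled as exponential: subject *i* in the study area has
survival time *T_i* ~ Exp(θ) with θ the mean survival time, censoring time
*L_i*, observed time *t_i* = min(*T_i*, *L_i*) and event indicator *δ_i*
(1 when *T_i* ≤ *L_i*).  A zone *z* is any candidate set of regions produced
by the window construction below.  The scan tests

    H0: θ_in = θ_out for all z        H1: θ_in < θ_out for some z

i.e. it searches one-sidedly for *short*-survival clusters.  With
r_in = Σ_{i∈z} δ_i, t_in = Σ_{i∈z} t_i and study-wide totals R and T, the
zone's log likelihood-ratio under the censored-exponential likelihood is

    llr(z) = r_in·ln(r_in/t_in) + r_out·ln(r_out/t_out) − R·ln(R/T)

when r_in/t_in > r_out/t_out, and 0 otherwise.  Terms with a zero event count
contribute 0 (the 0·ln 0 convention), and the whole computation stays in log
space; the statistic is invariant to rescaling all times by a constant.  When
nothing is censored, δ_i ≡ 1 makes r_in, r_out, R coincide with the subject
counts n_in, n_out, N, which is exactly the no-censoring form of the
statistic — the same code path serves both cases.

The exponential assumption enters only through this likelihood; the ranking
of zones is driven by event counts against observed-time sums, so moderate
misspecification shifts power rather than validity (the permutation null
below is model-free).

## Window construction

Candidate zones follow the usual scan-software geometry.  For every region
taken as a center, and every window shape — an axis ratio a ≥ 1 and an
orientation angle — all regions are sorted by the elliptic distance
sqrt((u/a)² + v²) of their centroids from the center ((u, v) is the
displacement rotated into the ellipse frame; a = 1 is the circle).  Every
prefix of that ordering containing the center and holding between 1 subject
and MSWS × N subjects is a zone; duplicate member sets are kept once, first
occurrence wins.  Distance ties break toward the lower region position in
file order, so zones are reproducible for a given input file.

Defaults: MSWS 0.5 (inclusive bound, in subjects — "population at risk"),
circular mode scans ratio {1}; elliptical mode scans ratios
{1, 1.5, 2, 3, 4, 5} with {1, 4, 6, 9, 12, 15} evenly spaced orientations in
[0, π) respectively, the conventional grid.  Both the ratio set and the
angle counts are configurable.

## Inference

Monte Carlo permutation: each of B replicates shuffles the (t, δ) pairs
across all subjects, holding per-region subject counts fixed — the standard
conditional null for this family of statistics — and records the maximum llr
over all zones.  A candidate's p-value is (1 + #{null maxima ≥ its llr}) /
(B + 1); every candidate, most likely or secondary, is ranked against this
one distribution of the maximum, so a secondary cluster is significant only
on its own strength.  B defaults to 999 for single-dataset analyses
(p-granularity 0.001) and to 199 inside simulation sweeps, where only the
position of p relative to α = 0.05 matters and the 5× saving compounds over
thousands of scans.  All randomness flows from one seed through
`numpy.random.Generator`; per-replicate substreams are derived from
(seed, replicate index), so runs are bit-reproducible and replicates
independent.

Calibration is verified empirically: over 400 cluster-free datasets the
most-likely-cluster rejection rate at α = 0.05 lies inside the exact binomial
95% band (the permutation p-value is uniform on its B+1-point grid up to
ties).

## Reporting and the Gini criterion

Scanning happens once, at the full MSWS; re-scanning at other window sizes
would re-run the hypothesis test and inflate the type-I error.  Reporting
walks the llr ranking greedily: zones above the maximum reported cluster
size (MRCS × N subjects) are skipped, zones overlapping an already-reported
cluster are skipped, and reporting stops at the first non-significant
candidate (p-values are monotone along the ranking because all candidates
share one null distribution).  Reported clusters are therefore pairwise
disjoint and size-bounded, with p-values identical across MRCS choices.

For each MRCS on the candidate grid (3, 4, 5, 6, 8, 10, 12, 15, 20, 25, 30,
35, 40, 45, 50% — the grid used for count-data scans), the reported clusters,
in significance order, give Lorenz points x_k = (Σ_{j≤k} r_in,j)/R and
y_k = (Σ_{j≤k} t_in,j)/T, and the Gini coefficient
Σ_{k=1}^{K+1} (y_k·x_{k−1} − y_{k−1}·x_k) with endpoints (0,0) and (1,1) —
twice the area between the Lorenz polyline and the diagonal.  Short-survival
clusters concentrate events into little observed time, pushing the curve
below the diagonal and the Gini up.  The optimal MRCS is the grid argmax.

Choices made where the procedure was genuinely open:

* only clusters significant at α (default 0.05) enter the Lorenz curve — an
  insignificant candidate should not influence which report is "best";
* "ordered by significance" is realized as llr-descending (Monte Carlo
  p-values tie heavily at 1/(B+1));
* Gini ties break toward the **smallest** MRCS, preferring the more refined
  report;
* when nothing is significant at any grid value the tool reports "no
  clusters" at the largest grid value rather than inventing a selection;
* ranking ties in llr break toward fewer members, then the lower center
  position, keeping reports deterministic.

A structural property worth knowing: splitting one reported cluster into two
disjoint significant pieces never lowers the Gini when the more significant
piece has the shorter mean survival, so the criterion inherently favours
refined reports over merged ones whenever the pieces survive the
significance filter.  This is the mechanism behind its ability to resolve
irregular clusters into parts.

## Synthetic geography and the simulation harness

Real district maps from published scan analyses are rarely distributable, so
the simulation study runs on a synthetic geography: a regular lattice
(default 8×8, unit spacing) with planted true clusters — circular
(k-nearest-centroid around a seed region, k = ⌈fraction × n⌉), elliptical
(same under the elliptic metric) or irregular (an explicit member set).
Scenario defaults mirror a typical published design: 1,000 subjects assigned
to regions uniformly at random; exponential times with mean 5 inside the true
cluster (2 and 7 are the harder/weaker variants) against 10 outside;
censoring rates 10–70%, applied by flagging exactly round(rate × n) uniformly
chosen subjects as censored while keeping the drawn time as the observed
time.  The alternative censoring mechanism — drawing an independent earlier
censoring time — changes both r and Σt and is deliberately not the default;
the simple flagging mechanism matches the fixed-rate design the defaults
emulate.

Per replicate the harness runs the full pipeline (enumerate at MSWS → scan →
one set of Monte Carlo p-values → Gini grid search) and scores detection
against the planted truth: a dataset is *rejected* when it reports at least
one significant cluster; over the S rejected datasets, sensitivity is the
mean share of true-cluster regions detected and PPV the mean share of
detected regions that are true.  Accuracy is aggregated three ways: at the
per-replicate Gini-selected MRCS, at the default 50% MRCS, and per grid value
conditional on that value being selected (the layout of published power
tables).  Accuracy cells condition on per-dataset rejection, as stated in the
output headers.

What the lattice does *not* emulate: heterogeneous district populations,
irregular adjacency, and spatially correlated covariates.  Passing tests
therefore demonstrate the statistic, inference and selection machinery, not
performance on any particular real map.  On the lattice with the default
strong-signal scenario, detection is close to perfect even at the default
MRCS (PPV ≈ 0.92–0.95), so the gap between Gini-selected and default
accuracy is small in the overall aggregate and clearest in the
conditional-on-modal-MRCS comparison (PPV ≈ 0.99 vs ≈ 0.92 at 10%
censoring); weaker signals and irregular truths widen the gap in the
sensitivity direction.

## Problem sizes and numerics

The validation suite and the acceptance script use an 8×8 grid, 1,000
subjects, B = 199 and 100–400 replicates per study — sizes chosen so every
zone statistic is exercised thousands of times while a full run stays in the
tens of seconds on one CPU.  Zone statistics are computed by aggregating
per-region event/time sums with a 0/1 zone-membership matrix product;
permutation replicates reuse the same matrix.  The scalar statistic is
validated against 50-digit arbitrary-precision evaluation to 1e−10, the Gini
against a shoelace polygon-area oracle to 1e−12, and window enumeration and
hierarchical reporting against brute-force oracles.

## Known limitations

* Only short-survival (θ_in < θ_out) clusters are scanned; the long-survival
  direction is symmetric but not implemented.
* No covariate adjustment, space–time scanning, or non-exponential survival
  models.
* No ellipse non-compactness penalty: very eccentric windows compete with
  circles on likelihood alone.
* Coordinates are planar; users with lat/long data should project first.
* The Gini criterion compares *reports*, not hypotheses — it carries no
  significance statement of its own, and with zero significant clusters it
  has nothing to rank.
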