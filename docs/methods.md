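# Methods

This note records the models, conventions and design choices behind
`briefcsid`, in the order the pipeline applies them.

## Keying and missing data

All analysis runs on a canonical binary coding in which 1 always means
the *keyed* direction: a correct answer on a cognitive item, a reported
symptom on an informant item.  Raw codes are assumed ordered toward the
keyed direction; a polytomous item enters the binary engine through a
dichotomization cut *c* (keyed iff response ≥ c).  Missing responses
propagate through keying.

Scale statistics and total scores use complete cases per scale: a
subject missing any cognitive item contributes to neither the cognitive
Mokken run nor the cognitive total (their triage is indeterminate);
a subject missing informant items keeps a cognitive-only triage with an
explicit flag.  This is the simplest policy consistent with a survey in
which slightly fewer informant than cognitive interviews complete.  The
engine nevertheless handles NaN cells pairwise (`use="pairwise"`) for
data too sparse for listwise deletion.

## Mokken scaling engine

**Difficulty** is the proportion of analysed subjects *not* giving the
keyed response, so very easy or very common items have values near 0.
This convention makes published item listings ascend from the item
almost everyone passes to the one most fail, and is stated explicitly
here because the term is used both ways in the literature.

**Guttman errors.**  For a pair with harder item *h* and easier item
*e* (difficulty ordering within the pair's complete cases; ties broken
by ascending column index, the lower-indexed item counting as easier),
an error is the pattern (keyed on *h*, unkeyed on *e*).  Expected
errors under marginal independence are E = n·P(h keyed)·P(e unkeyed)
with the analysed sample's marginals, and H = 1 − F/E at pair, item and
scale level.  The aggregation identities F_total = ½ΣF_i and
E_total = ½ΣE_i hold exactly by construction.  A pair in which either
item is constant is degenerate (E undefined at the margin): it is
flagged, excluded from all aggregates, and surfaces in the pairwise
table rather than crashing the run.

**z statistics.**  The source criteria name no formula, so the package
uses the conditional argument: given the margins of a pair's 2×2 table,
F is hypergeometric with mean E, hence

    z = (E − F) / sd(F),   Var(F) = R·C·(n−R)·(n−C) / (n²(n−1)),

with R the harder item's keyed count and C the easier item's unkeyed
count.  Item and scale z's divide (E − F) sums by the root of summed
pairwise variances (cross-pair covariances ignored).  z is positive
when fewer errors occur than chance predicts.  The statistic is
validated by Monte-Carlo type-I calibration under independence (the
one-sided 5% test rejects at its nominal rate within binomial bounds),
not against any published z values, which are not derivable from the
printed counts alone.

**Monotonicity check.**  Rest-score groups are formed by merging
adjacent rest-score values from the low end until each group reaches
`min_group_size` (default max(50, n/10)).  A decrease of at least
`minvi` (default 0.03) in the proportion keyed between any ordered pair
of groups is a violation; each violation is additionally tested at
α = 0.05 with a pooled two-proportion z test.

**Non-intersection (P-matrix) check.**  With items ordered by
difficulty, each row of the joint-keyed matrix P(++) must be
non-increasing and each row of the joint-unkeyed matrix P(−−)
non-decreasing across columns.  Reversals ≥ `minvi` count as
violations, attributed to the row item, and are tested with a
paired-difference z test using the triple joint probability.

**Crit.**  Violation evidence per item is summarised as

    Crit = 50·(0.30 − H_i)₊ + √#vi + 100·#vi/#ac + 100·maxvi
           + 10·√Σvi + 1000·Σvi/#ac

banded ≤ 40 satisfactory, 40–79 questionable, ≥ 80 violation.  Worth
knowing: a clean 0.2 dip in one response function is reliably
*detected* (violations ≥ minvi) but yields Crit ≈ 30–50 even with
near-deterministic anchor items; Crit ≥ 80 indicates grossly
non-monotone behaviour.  Items that are constant, or leave fewer than
two rest-score groups, are reported `not_assessable` rather than
guessed at.

## Item reduction

Dichotomization is a coordinate-wise search: every polytomous item
starts at its middle level, each item's cut is chosen to maximise that
item's own H_i within the candidate scale with the others held fixed,
and the sweep repeats once.  Ties go to the lower cut (the more
prevalent symptom), making the procedure deterministic.  The objective
is the item's H_i rather than the whole-scale H, mirroring the
item-level selection logic; a full joint search over cut combinations
is exponential and was deliberately avoided.

Selection ranks items by H_i descending and walks the ranking, skipping
an item when (a) its content domain is already covered and an uncovered
domain still offers a strongly scalable item (H_i ≥ 0.5), or (b) its
difficulty lies within ε = 0.02 of an already selected item and a
spaced strong alternative remains.  Skipped items are reconsidered if
the walk ends short of k (default 6).  Every decision is logged, so a
deviation — such as keeping a multi-point recall item that pushes the
score range past k points — is visible rather than silent.

## Scoring and triage

Cognitive 0–9 = six pass/fail items + 0–3 recall count (higher =
better); informant 0–6 = count of keyed symptoms (higher = more
decline); combined = cognitive − informant ∈ [−6, 9], subtraction
because the two scales point in opposite directions.  Screening
cutpoints are stored as half-integer thresholds with an explicit
direction flag (`<6` ≡ positive iff score ≤ 5; `>1` ≡ positive iff
score ≥ 2), which removes the off-by-one ambiguity of mixed `<`/`>`
notations.  The informant default is ≥ 2 with a regional override
(≥ 3) available in configuration.  Triage: cognitive ≤ 4 positive,
≥ 7 negative, 5–6 resolved by the informant (positive iff combined
≤ 4) or indeterminate without one.  The rule is monotone in both
inputs, which the suite verifies by full enumeration.

## ROC validation

Integer scores produce heavy ties, so thresholds sit at half-integers
(midpoints of adjacent observed values) and AUROC uses the rank
statistic with the ½-tie convention; on tie-free data it equals the
trapezoid area under the empirical curve to machine precision.
Confidence intervals are DeLong by default (midrank placements), with
Hanley–McNeil as an option.  The Youden index is
J = sensitivity + specificity − 1.  When a threshold adjacent to the
J-maximiser comes within ΔJ = 0.05, both are reported, ordered
(specificity-favouring, sensitivity-favouring) — the dual-cutpoint
reporting convention.  Stratified analyses compute sensitivity within
case-severity strata and specificity within control-education strata
at a fixed cutpoint; empty strata are flagged not-estimable.

## Synthetic cohort generator

One latent trait θ drives both scales (informant items load on −θ):
the combined subtraction score presumes a shared severity dimension
with opposite polarities.  Controls have θ ~ N(0, 1); cases are shifted
by −2.75 SD in the population design.  In the case-control design mild
cases sit at −2.5 and moderate at −4.0 SD, chosen so the pilot-style
contrast of clinically established cases against screened controls
reproduces combined-scale AUROCs in the mid-0.90s; population-design
severity is labelled by the case-trait median.  Item response functions
are logistic with a common discrimination a = 2.0, which places the
synthetic whole-scale H at ≈ 0.68–0.69 — the strong band the published
scales occupy.  Per-item locations are solved by one-dimensional root
finding (64-node Gauss–Hermite quadrature over the trait mixture,
residual < 1e-6) so each item's marginal difficulty matches its
published target.

The delayed-recall item is three conditionally independent word
recalls sharing one location (count 0–3), entering the Mokken run
keyed at ≥ 2 words — the cut used for its published difficulty of
0.283, which is not otherwise documented.  Informant items are graded
never/sometimes/often through ordered thresholds 1.5 trait-SD apart,
with the keyed threshold calibrated.  Low education (40% of subjects)
shifts every cognitive item location by +1.0 trait SD — a differential
item functioning knob calibrated so the education gap in specificity
matches the published low/high contrast (≈ 89% vs 97% at the `<6`
cognitive cutpoint).  Setting `discrimination=inf` turns every response
function into a step in θ, producing an exactly Guttman matrix
(H = 1) — the limiting case used in tests.

All randomness flows from one integer seed through a Philox generator
with a fixed vectorised draw order, so identical configurations yield
byte-identical cohorts.

**What the generator does not emulate:** site/cluster structure and
survey weights, item-level missingness beyond what a user injects,
informant-specific reporting styles, multidimensional traits, and any
claim to reproduce the published validity point estimates — those
depend on undeposited data.  Passing tests on synthetic cohorts show
the *procedures* behave correctly under the model the analysis assumes
(and detect planted violations of it), not that real data satisfy that
model.

## Problem sizes used in the test suite

Identity and oracle checks run at desk scale (< 1 s).  Monte-Carlo
properties use the sizes at which their tolerances were derived:
difficulty calibration at n = 15 000 (3·SE bands), monotonicity
cleanliness and selection parameter-recovery at n = 5 000 (100 seeds
for recovery, ≥ 95% required), z-calibration with 1000 replicates of
n = 400, stratified orderings over 40 case-control seeds, and the
pilot-band AUROC check over 50 seeds.  The full suite completes in a
few minutes on one CPU.

## Known limitations

* The rest-score grouping rule and the z formula are reasonable
  conventions, not reconstructions of any particular legacy program;
  numerical agreement with other Mokken implementations is expected to
  be qualitative (same violations, same bands), not digit-for-digit.
* The P-matrix check attributes violations to the conditioning (row)
  item; implementations differ on attributing them to all items
  involved.
* DeLong intervals degenerate to zero width under perfect separation;
  the Hanley–McNeil option behaves similarly at AUROC = 1.
* `score_cohort` iterates subjects in Python; it is comfortable at
  survey scale (~10⁴ subjects) but not optimised beyond that.
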