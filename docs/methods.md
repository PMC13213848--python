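# Methods

## Setting and data model

The package evaluates R observers who each assign, to every one of N
subjects, a probability vector over an ordered category set (default: the
seven-way dementia differential CN, AD, bvFTD, SD, PNFA, PSP, DLB). Ground
truth is binary (AD vs CN). The central container is a complete N × R grid
of vectors plus the truth table; incomplete grids are rejected rather than
imputed, because every downstream pairwise statistic assumes paired
observations. Input scale (percent vs fraction) is declared by the caller —
auto-detection exists but only as an explicit opt-in, since silent
misscaling would corrupt every metric. Rows are renormalized to sum exactly
1 after a tolerance check (default 0.5% of total mass, accommodating
vectors recorded at one-decimal percent whose rounded entries do not sum
exactly to 100).

## Tie-tolerant decision rule and partial credit

The predicted label is the argmax of the vector. Two observers can
legitimately record exact ties (humans reporting "50/50"), so the argmax is
tie-tolerant: categories within an additive tolerance (default 1e-9) of the
maximum share the top, and each of the k tied categories receives credit
1/k. A *reported-precision* mode rounds vectors to a stated number of
decimals before comparison, reflecting that recorded scores tie at their
recorded precision while floating-point classifier outputs essentially
never do. Summing credit vectors stratified by truth yields fractional
confusion matrices; binary metrics read the CN/AD diagonal directly, so a
CN/AD tie on a true AD case contributes 0.5 to sensitivity and any mass on
the other five categories counts fully against both binary metrics.

Confidence intervals for the credit proportions use the Wilson score
interval with the fractional success count substituted into the closed
form; a Wald variant is available behind a flag. Weighted F1 averages
per-class F1 over the truth classes (CN, AD), weighted by support, with all
seven predicted columns feeding the precision denominators; a full-category
variant exists but is not the default because truth spans only two classes.

Tie-aware Cohen's κ generalizes the classical statistic to credit vectors:
observed agreement is the mean per-case dot product, expected agreement the
dot product of mean credit profiles. With tie-free vectors it reduces
exactly to classical κ (verified against an independent integer-count
oracle). κ against truth and κ between raters are the same operation with
truth encoded as unit vectors; reports carry both, and degenerate cases
(expected agreement 1) are reported as null with a reason rather than a
number.

## Agreement on the continuous channel

Pearson and Spearman correlations (both always reported, with two-sided
t-approximation p-values) and Levene's F (mean-centered by default;
median-centering gives Brown–Forsythe) are delegated to scipy behind the
module surface. The ICC is the single-measure absolute-agreement form
computed from the two-way ANOVA mean squares,

ICC = (MS_R − MS_E) / (MS_R + (k−1) MS_E + k (MS_C − MS_E)/n),

which can be negative when between-rater disagreement exceeds
between-subject variance; we use the absolute-agreement form throughout
because it is the quantity of interest when two observers are supposed to
output the *same* probability, not merely correlated ones. Bland–Altman
limits are mean ± 1.96 SD of the paired differences (n−1 denominator), with
per-case (mean, difference) pairs exported for plotting.

## Discrimination

ROC analysis uses the continuous AD-probability channel with the convention
"positive iff score ≥ threshold"; tied scores produce diagonal segments.
AUC is computed in the Mann–Whitney form (half-credit for ties) via
mid-ranks, which equals exhaustive pair counting exactly. Bootstrap CIs use
stratified (within-class) resampling with a percentile interval — the
simplest fully reproducible choice; replicates can never lose a class by
construction. Default 2,000 iterations.

DeLong's test compares two correlated AUCs through placement values: the
variance of the AUC difference combines the covariance matrices of the two
observers' placement vectors over positives and negatives. Identical score
vectors give zero variance; the z and p are then reported as null with a
reason. Pairwise comparisons are reported unadjusted (a Holm flag is out of
scope for the default report since the three-way comparison is treated as
exploratory).

The power tool answers "what AUC difference is detectable at target power
for two observers with correlation r?". Analytic mode evaluates the
Hanley–McNeil exponential-approximation variance V(A) at a stated baseline
AUC (default 0.80) and uses Var(Δ) = 2V(1−r), Δ = (z_{1−α/2} + z_power)·√Var.
Simulation mode draws paired binormal observers (score correlation r, true
AUCs baseline ± Δ/2), applies DeLong's test, and bisects on Δ until the
rejection rate hits the target; both modes agree within 0.02 at the default
design (18/20 subjects, r = 0.5, α = 0.05, power 0.80), where the analytic
answer is ≈ 0.21. The variance model is a documented choice: different
textbook variance approximations shift the answer by a few hundredths.

## Calibration and clinical utility

Brier score is the mean squared error of the AD probability against binary
truth (a multiclass Brier is deliberately out of scope, as truth spans two
classes). Calibration curves default to 5 equal-width bins — with studies
of a few dozen subjects quantile bins are unstable — with a quantile
strategy available. Decision curves evaluate net benefit
TP/N − (FP/N)·P_t/(1−P_t) on a 0.01-step grid over [0.05, 0.95] (positivity
"≥ P_t", matching ROC), against treat-all and treat-none references, and
flag whether an observer's net benefit stays positive across the clinically
quoted [0.1, 0.9] range.

## Synthetic study generator

The generator emulates the statistical structure of a two-class,
seven-category reader study. A scalar latent severity s is N(0,1) for CN
and N(d,1) for AD subjects. Observer o perceives
u = λ_o s + √(1−λ_o²) ε, so pairs of observers correlate at λ_o λ_o'; the
AD share is logistic(a_o + b_o u); the residual mass goes to CN except for
a fixed leakage profile over the five other categories; a tie event (per
observer probability τ) replaces the top two values by their mean; finally
the vector is rounded to the recorded precision and renormalized (ties
survive rounding exactly, and exact ties arise *only* from the tie event).
Per-observer random substreams are keyed by a stable hash of the observer
name, so adding an observer never perturbs another's draws.

Because the link is monotone, a tie-free observer's population AUC is
Φ(λd/√2) exactly — the generator's discrimination is verifiable in closed
form, and tests confirm empirical AUC recovery within ±0.01 over 50
replicates of n = 1,000/1,000 (problem sizes chosen as the smallest at which
Monte-Carlo error sits comfortably below the asserted tolerances).

The shipped `paper_shaped` preset encodes the study conditions this package
was designed around: 18 AD / 20 CN subjects; separation d = 1.8125 (a fully
loaded observer sits at AUC ≈ 0.90); two human readers with loadings chosen
for expected AUCs ≈ 0.71 and 0.62, near-zero leakage (< 5% of residual
mass) and tie propensities 0.20/0.25 concentrated on CN/AD ties; and an
automated observer with λ = 1, a well-calibrated link (population Brier
≈ 0.19, mean AD probability in AD cases ≈ 0.42), no exact ties, and 45% of
its residual mass leaked across the differential with DLB the largest
single destination.

What the generator does *not* reproduce: with severity-independent leakage
weights, the normal-class share of the residual almost always exceeds every
single leakage category, so the automated observer's argmax errors fall on
CN/AD rather than occasionally on DLB; reproducing sporadic DLB
top-assignments would require per-category noise, which this single-latent
design intentionally omits. Likewise human reader behaviour is reduced to
one loading, one link and one tie rate — real readers are context-sensitive
in ways no scalar latent captures. Passing tests therefore certify the
*evaluation machinery* and the generator's stated operating
characteristics, not fidelity to any particular clinical cohort.

## Numerical and design choices

- Undefined statistics (zero-variance DeLong, degenerate κ, constant-vector
  correlations, zero-spread Levene) are serialized as null plus a reason
  string, never dropped or forced to a number.
- Reports are canonical JSON (sorted keys, shortest-round-trip floats):
  identical config + seed ⇒ byte-identical output. Wall-clock time is kept
  out of the payload.
- Wilson bounds snap exactly to 0/1 at boundary counts to preserve the
  lower ≤ estimate ≤ upper contract under floating point.
- The bootstrap seed for each rater derives deterministically from the run
  seed and the rater's position, so per-rater CIs are independent but
  reproducible.
- The evaluation CLI (`simulate` / `evaluate` / `compare` / `power`) is a
  thin layer over the library; every flag has a config-file equivalent and
  CLI flags win.

## Known limitations

- ICC is the absolute-agreement single-measure form only; no hierarchical
  or repeated-measures variants.
- Percentile bootstrap (not BCa); with very small n the interval need not
  contain the point estimate, and this is not asserted.
- Power analysis assumes the score-level correlation is a good proxy for
  the AUC-estimator correlation; simulation mode exists precisely to check
  this at the design of interest.
- Decision curves carry no confidence bands, and no recalibration
  (Platt/isotonic) is offered.
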