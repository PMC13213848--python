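# raterbench

Tie-aware evaluation of probabilistic multi-class diagnostic raters.

`raterbench` is built for reader studies in which every observer — an
automated classifier and/or human experts — assigns a *probability vector*
over a fixed set of diagnostic categories to each subject, while ground truth
is binary. The motivating setting is the dementia differential: seven
categories (CN, AD, bvFTD, SD, PNFA, PSP, DLB) with truth restricted to
cognitively normal (CN) vs Alzheimer's disease (AD). The package is aimed at
biostatisticians and imaging researchers who need to compare such observers
head-to-head on a shared probabilistic footing.

## What it computes

**Decision scoring.** The predicted label is the category with the highest
assigned probability. When k categories tie for the top, credit is split
1/k among them: a case scores 1 if the truth is the unique maximum, 1/k if
the truth is among k tied maxima, and 0 otherwise. Tabulating per-case credit
vectors by truth gives *fractional confusion matrices*, from which accuracy,
sensitivity and specificity (Wilson intervals on fractional success counts,
Wald optional), weighted F1 and a tie-aware Cohen's κ

κ = (p_o − p_e) / (1 − p_e),  p_o = (1/N) Σᵢ Σ_c a_ic b_ic,  p_e = Σ_c ā_c b̄_c

are derived (a, b are stacks of credit vectors; truth enters as unit
vectors).

**Agreement.** On the continuous AD-probability channel: Pearson r, Spearman
ρ, single-measure absolute-agreement ICC from the two-way ANOVA mean squares
(negative values permitted), Bland–Altman mean difference with 95% limits of
agreement, and Levene's test for equality of variances.

**Discrimination.** Empirical ROC curves (positive iff score ≥ threshold),
Mann–Whitney AUC with half-credit for ties, stratified percentile-bootstrap
CIs, DeLong's paired test for correlated AUCs, and a power tool for the
minimal detectable AUC difference between two correlated observers
(Hanley–McNeil analytic variance or paired binormal simulation).

**Calibration and utility.** Brier score, binned calibration curves, and
decision-curve analysis: net benefit TP/N − (FP/N)·P_t/(1−P_t) against
treat-all and treat-none strategies.

**Simulation.** A latent-severity generator produces complete synthetic
studies with known operating characteristics: each observer perceives
u = λ·s + √(1−λ²)·ε of the latent class signal s, maps it to an AD
probability through a logistic link, spreads residual mass over the other
categories via a leakage profile, and records occasional exact ties. A
tie-free observer's population AUC is exactly Φ(λd/√2), so generated studies
are verifiable in closed form.

## Worked example

```bash
raterbench simulate --preset paper_shaped --seed 1 --out study/
raterbench evaluate --assessments study/assessments.csv \
    --truth study/truth.csv --seed 1 --out study/report/
raterbench compare --assessments study/assessments.csv --truth study/truth.csv
raterbench power --method analytic
```

The `compare` step prints, for the simulated 18 AD / 20 CN study:

```
model vs radiologist1: AUC 0.936 vs 0.678  delta +0.258  z 3.007  p 0.0026
model vs radiologist2: AUC 0.936 vs 0.654  delta +0.282  z 3.025  p 0.0025
radiologist1 vs radiologist2: AUC 0.678 vs 0.654  delta +0.024  z 0.181  p 0.8562
```

i.e. the automated observer's ranking of AD probability beats both human
readers (DeLong p ≈ 0.003), while the two humans are statistically
indistinguishable. The `power` step prints `detectable AUC difference:
0.2070`: with 18/20 subjects and observer correlation 0.5, only AUC gaps of
about 0.21 or more are detectable at 80% power (α = 0.05). The full
`report.json` adds classification metrics with CIs, pairwise agreement,
calibration and decision-curve blocks, plus CSV exports of every curve.

### File formats

- assessments CSV: header `subject_id,rater_id,CN,AD,BVFTD,SD,PNFA,PSP,DLB`,
  one probability vector per (subject, rater) row; declare `--scale percent`
  or `fraction` (`auto` is an explicit opt-in).
- truth CSV: header `subject_id,truth` with labels CN or AD.
- report: canonical JSON; undefined statistics are null with a reason field.

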