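# Methods

## Setting

`graftdd` analyses a randomized, two-arm kidney-transplant trial in which every
patient undergoes molecular biopsy phenotyping at baseline, week 24 and week 52.
The scientific question is a *difference-in-differences* (ΔΔ) one: did gene
expression or molecular scores change differently over time in the treated arm
(an anti-CD38 antibody depleting NK cells and plasma cells) than in the placebo
arm, which has its own time dynamics?  All inference therefore centers on the
treatment × follow-up interaction, never on simple within-arm changes.

## Gene-set derivation

Four antibody-mediated-rejection (ABMR) gene sets are derived from a reference
biopsy cohort carrying per-sample archetype scores (EABMR = early-stage,
FABMR = fully developed molecular ABMR) and from an NK/HUVEC cell-profile
panel:

* **activity**: top 20 genes by Spearman correlation with the EABMR score.
* **IFNγ-inducible activity**: top 100 EABMR-correlated genes with ρ > 0.2,
  keeping genes whose IFNγ-stimulated HUVEC expression is ≥ log2 5 above both
  NK cells and unstimulated HUVECs.  Prose descriptions of this filter are
  grammatically ambiguous about which HUVEC condition is the numerator; both
  readings are implemented (`numerator=` flag), the default being the
  IFNγ-stimulated condition, i.e. "inducible and not NK-borne".
* **NK-expressed activity**: top 100 EABMR-correlated genes, minus genes whose
  HUVEC expression exceeds the panel's 50th percentile, then the top 20 by NK
  expression.  "Unstimulated and IFNγ-stimulated HUVEC expression > 50th
  percentile" under negation is read as *either condition above its own panel
  median* (conservative against endothelial contamination); a strict-AND mode
  is a flag.  Percentiles are linear-interpolation quantiles over the whole
  panel.
* **endothelial**: top 100 FABMR-correlated genes with unstimulated-HUVEC
  expression ≥ log2 4 above NK cells.

All fold filters compare log2 differences and are inclusive at the boundary;
all sorts break ties lexicographically by gene id, so derivations are exactly
reproducible.  The injury ontology retains only injury-induced ("New") cell
states from a single-nucleus AKI marker table: one set per state for
annotation plus their union for enrichment.

## Scoring

A biopsy's score for a set is the arithmetic mean over member genes of log2
expression minus a per-gene control mean — the log geometric-mean fold versus
control, the convention of pathogenesis-based transcript (PBT) scores.  The
control cohort behind published PBT scores is not distributed with them, so
the control interface is pluggable; without one, genes are centered on the
cohort mean and scores read as deviation from the cohort average.  This choice
shifts every sample's score by a constant per gene and therefore does not
affect any arm × visit inference.

## Score-level inference

**Omnibus PERMANOVA.**  Per score family (ABMR, injury, ...), Euclidean
pseudo-F from the among/within partition of squared distances over the six
arm × visit groups; p = (1 + #{F* ≥ F})/(1 + n_perm).  Labels are permuted
freely by default (10^5 permutations in the pipeline default; the statistic is
cheap, so 10^6 is feasible when wanted).  Free permutation ignores the
repeated-measures structure; a restricted mode that permutes whole patient
blocks is available (`strata=`) and is the appropriate choice when the
grouping factor is constant within patient.

**ART-ANOVA.**  The aligned-rank transform makes factorial ANOVA applicable to
scores with arbitrary marginal distributions: for each effect (arm, visit,
arm × visit) the response is *aligned* — stripped of the estimated cell-mean
contributions of every other effect — then average-ranked, and the ranked
response is tested under the repeated-measures model with a patient random
intercept.  On the balanced complete 2 × n × 3 design this mixed-model F-test
is computed through the exact split-plot decomposition (arm tested against
subjects-within-arms, visit and interaction against the subject × visit
residual), whose denominator degrees of freedom coincide with the
Satterthwaite values there; unbalanced data are rejected rather than
approximated.  The alignment sanity property (non-target effects carry ≈ 0
effect on each aligned column) is checked and logged on every fit.  Null
calibration of the interaction test on the 2 × 10 × 3 design gives a type-I
error of ≈ 0.05 (the acceptance suite verifies membership in [0.03, 0.07]
over 1000 simulations).

**Interaction contrasts.**  Pairwise comparisons inside the interaction use
the aligned-rank-contrast approach: the six arm × visit cells are re-leveled
into one factor and the response ranked (with one factor, alignment removes
only the grand mean, which ranks ignore).  Cell means and their covariance
come from a mixed model on the ranks with a patient random intercept; the 15
cell pairs are t-tested with residual degrees of freedom (n − 6) — an
approximation documented here because Satterthwaite df for arbitrary contrasts
are not available in the fitting backend — and BH-adjusted within the
15-pair family.  The three ΔΔ window contrasts (baseline↔wk24, wk24↔wk52,
baseline↔wk52) are emitted alongside, flagged primary, BH-adjusted within
their family of three.

**Trajectory slopes.**  Injury scores are modeled as score ~ arm × week with a
per-patient random intercept and slope (REML).  Reported are per-arm slopes in
score units per week with 95% CIs, the arm × week Wald p (BH-corrected across
scores), and predicted population trajectories with CI bands.  A singular
random-slope covariance triggers a fall-back to a random-intercept model,
flagged `downgraded` in the output; if that fit is also on the variance
boundary, patient-clustered OLS provides the terminal fallback so slope
estimates and robust CIs are always returned.

## Genome-wide ΔΔ differential expression

Genes are first filtered to the largest interquartile ranges.  Array studies
of this design typically retain a few thousand of ~55k probe sets, but the
cutoff is dataset-specific, so the retained count is configuration — the
pipeline default keeps 1000 of the 2000 synthetic genes, a similar proportion
at desk scale.
Genes differing between arms at baseline (Welch t, p < 0.05; Welch because
arm variances need not be equal) are flagged and
excluded from interpretation outputs but retained in all fits.

Each gene is fitted by OLS on the six arm × visit cell means plus centered
%cortex (the biopsy's cortical fraction, a nuisance covariate for medullary
contamination; centering keeps cell means interpretable at average cortex).
The window contrast is

    ΔΔlogFC = (treated_late − treated_early)/2 − (placebo_late − placebo_early)/2,

the half-scaled reporting convention (each arm's change divided by two, so
the reported value is half the plain difference-in-differences; `scale=1.0`
gives the unscaled one).  The three windows telescope: baseline↔wk52 equals the sum of
the other two, per gene, exactly.

Moderated tests shrink per-gene residual variances toward a common prior
estimated by moment-matching log s² against its theoretical log-chi-square
sampling distribution (trigamma inversion; population-variance moments, which
makes the estimate invariant to duplicated genes).  Posterior variance
s̃² = (d₀s₀² + d·s²)/(d₀ + d), moderated t on d₀ + d df (normal when
d₀ = ∞), BH-FDR, and genes reported by rank of uncorrected p, the pipeline's
reporting basis for top-gene tables.

A calibration caveat: the per-gene model deliberately contains no patient
term.  Patient random effects cancel exactly in the ΔΔ
contrast but inflate the residual variance, so with real between-patient
variation the moderated p-values are *conservative* for this contrast.  The
uniformity calibration is therefore run on the model-matched null
(patient variance zero); under patient effects, tests lose power but do not
overstate significance.

## Enrichment

Cutoff mode: one-sided hypergeometric over-representation of genes with
uncorrected p < 0.05, split by ΔΔ sign, BH within each library.  Rank mode: a
weighted Kolmogorov–Smirnov running sum over the moderated t ranking with a
gene-permutation null, NES = ES / mean(|null ES| same sign), permutation p
with +1 smoothing, leading edge up to the running-sum extremum.  Both modes are
provided because practice varies between cutoff- and rank-based enrichment;
outputs record which mode ran.
Public ontologies (GO, KEGG, Reactome, ...) are consumed only as user-supplied
GMT files — database snapshots are irreproducible by design — and the packaged
default library is the derived injury ontology.

## Synthetic-data generator

The generator encodes the study conditions so every stage is testable without
downloads: 2 arms × 10 patients × 3 complete visits (60 biopsies); per-gene
log2 model = baseline (N(8, 1)) + patient random intercept (sd 0.7 log2) +
shared per-visit drift (sd 0.1, emulating placebo-arm time trends) + planted
arm × visit class effect + arm-specific linear injury trend + %cortex slope +
residual noise (sd 0.5 log2).  Planted effects: −1.0 log2 ΔΔ at week 24 on
both activity classes rebounding by week 52 (treatment suppresses ABMR
activity, which returns after dosing stops), −0.5 log2 on the endothelial
class, injury trends ±0.01 log2/week with opposite sign in the two arms
(falling under treatment, rising under placebo).  %cortex is uniform [40,100]
with a nonzero expression slope for a configurable 10% of null genes.  The
reference cohort draws archetype scores as probit transforms of latent
normals and loads activity/endothelial genes on the corresponding latent
(loading 1, noise sd 1 → population Spearman ≈ 0.69); the cell-profile panel
places each class just beyond its filter with a 1-log2 margin.

What the generator does *not* emulate: correlated noise across genes beyond a
single optional shared factor, probe-level artifacts, batch effects, missing
visits, dropout, or the heavy-tailed variance distribution of real arrays.
Passing recovery tests therefore demonstrates correctness of the estimators
under the declared model, not robustness to those real-data features.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the package's
default validation sizes: 2000-gene universes (300-sample reference cohorts)
for end-to-end runs, 300–800 genes for Monte-Carlo loops, 1000 simulations
for type-I calibration, 100 seeds for slope-sign recovery, 10^4–5×10^4
permutations for PERMANOVA.  Quantiles are linear-interpolation throughout;
fold filters are boundary-inclusive; every sort breaks ties lexicographically;
permutation p-values use +1 smoothing and respect the 1/(n_perm+1) floor; the
trigamma inversion iterates Newton steps to relative 1e-10.  All generators
take explicit integer seeds and are bit-reproducible.

## Known limitations

* Machine-learning classifier scores (e.g. rejection-probability classifiers
  trained on proprietary reference sets) cannot be reproduced; if present they
  are treated as externally supplied score columns.
* The ART contrast t-tests use residual df rather than per-contrast
  Satterthwaite df; on the balanced design the difference is small but the
  p-values for between-arm pairs are mildly liberal.
* Free-permutation PERMANOVA ignores patient blocking; use `strata` for
  grouping factors constant within patient.
* The per-gene model's conservatism under patient random effects (above)
  means genome-wide p-values are lower bounds on significance rather than
  exact under between-patient heterogeneity.
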