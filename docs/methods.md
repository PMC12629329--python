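# Methods

This note records the models, numerical conventions and open design
choices behind `microresilience`, in the spirit of a statistical methods
appendix: what is computed, under which assumptions, and what the
synthetic validation does and does not establish.

## Compositional analysis

Genus count tables are compositional; all between-sample geometry uses
the centred log-ratio (CLR) transform of pseudocounted counts,
`clr(x)_j = ln(x_j + p) − mean_k ln(x_k + p)`, and the Aitchison distance
(Euclidean distance of CLR vectors). Two distinct pipeline paths are kept
deliberately separate:

- **unfiltered counts** for richness, Shannon diversity, CLR, Aitchison
  distances and PCA ordination;
- **15%-prevalence-filtered, CLR-transformed counts** for per-taxon
  statistical modelling (a genus must be detected in ≥ 15% of all
  samples, boundary inclusive).

*Pseudocount.* The default is +1 on counts before the log. The upstream
toolchains in this field do not agree on a zero-replacement convention,
so the pseudocount is a configuration parameter; distance-based
conclusions in the test-suite are checked for stability under
`p ∈ {0.5, 1}`. CLR output is invariant to jointly rescaling counts and
pseudocount, and every CLR row sums to zero within 1e−9.

*Shannon diversity* uses the natural log by default (configurable base);
observed richness counts genera with count > 0. PCA is computed on the
column-centred CLR matrix without unit-variance scaling, the standard
choice for Aitchison-geometry ordination; with identical samples the
explained-variance fractions are defined as 0.

## Resilience

For each subject with a baseline (CID1) sample, every later sample is
scored by its Aitchison distance `d(t)` to that baseline over the *full*
(unfiltered) genus set, and

    R(t) = (dmax − d(t)) / (dmax + d(t)),   dmax = max_t d(t),

with `dmax` taken over the subject's available post-baseline visits only
(the CID1→CID1 distance is trivially zero, and the perturbation maximum
is empirically at CID2). `R ∈ [0, 1]`, equals 0 exactly at the visits
attaining `dmax`, and 1 only on exact compositional return. Subjects
without CID1, and the degenerate case `dmax = 0`, are excluded with a
logged warning; missing intermediate visits simply leave gaps — nothing
is imputed anywhere in the pipeline.

*Median splits* of baseline richness/diversity assign values strictly
above the within-group median to HIGH and everything else (including
exact ties) to LOW — a deterministic rule chosen because the tie
convention is otherwise unidentified.

## Mixed models

Each longitudinal outcome is modelled as

    value ~ arm + time + arm:time (+ covariates),  random intercept ~ subject

with time a categorical factor restricted to the supplementation period
(CID2 = week 0 through CID3 = week 8; the pre-perturbation visit CID1
never enters as a numeric week). Fixed effects and standard errors come
from the REML fit. Because time has several levels, no single Wald
coefficient summarizes the interaction; the reported `p_interaction` is a
likelihood-ratio test of all interaction terms jointly, from ML refits of
the full and reduced models, referred to χ² with (arms−1)×(times−1)
degrees of freedom. Whether the original analyses used this LRT or a
Wald test on some other coding is not identifiable from the source; the
choice here is documented, not asserted as the original.

Metabolic-outcome models additionally take two covariates — the change
of the outcome during the antibiotic week (CID2 − CID1) and baseline
BMI; per-taxon and resilience models take none. Strongly skewed
metabolic outcomes should be ln-transformed before modelling (the
package leaves the transform to the caller, with `|skewness| > 1` as the
suggested operational threshold).

After a significant interaction (α = 0.05), per-visit between-arm
contrasts (2′-FL − placebo at visit t) are Wald z-tests on the
fixed-effect covariance block; they are computed in-package because
statsmodels' contrast helper mishandles the variance parameters appended
to a mixed-model parameter vector. Post-hoc contrasts are a contract
violation when the interaction is not significant.

*Degenerate designs.* On noiseless or otherwise singular data the mixed
model cannot be estimated; `fit_lmm` then falls back to OLS for the
fixed effects — identical to GLS on balanced complete designs, where the
interaction estimate equals the difference-in-differences of cell means —
and flags the result (`method="ols"`, `converged=False`). Non-convergence
of the mixed optimizer is likewise flagged, never silently ignored.

*Calibration.* Under null synthetic cohorts (no arm effect anywhere) the
interaction LRT holds its size: ≈ 0.04 for the two-level (metabolic
CID2/CID3) design and ≈ 0.05–0.07 for the five-level resilience design
at n = 37; the type-I-error acceptance simulation uses the metabolic
design, which is the model family the covariate machinery targets.

## Nonparametric tests and multiplicity

- Wilcoxon signed-rank (paired, two-sided): zero differences dropped
  before ranking (the convention is otherwise unstated); exact p for
  ≤ 25 informative pairs without tied |differences|, else normal
  approximation with continuity correction; ≥ 5 complete pairs required.
- Mann-Whitney U (two-sided): exact for small samples without ties, else
  normal approximation with tie and continuity corrections.
- Benjamini-Hochberg step-up q-values, one family per screen (all taxa
  of one design), q < 0.05 as the significance rule.
- Correlations: Pearson (richness/diversity/metabolic) or Spearman
  (taxon abundances), listwise deletion, ≥ 4 complete pairs, zero
  variance is an error.

Exact small-sample p-values of both rank tests are verified against full
enumeration oracles in the test-suite.

## Metabolic index panel

All formulas are isolated one-per-function so a convention change is a
one-line fix. Inputs are SI; published conventional-unit formulas convert
internally with 1 mU/L = 6.945 pmol/L (this constant, not 6.0, makes the
HOMA-IR of the trial cohort's printed means come out at the printed 1.7)
and 18.016 mg/dL per mmol/L glucose.

| Index | Form used |
|---|---|
| HOMA-IR | G0[mmol/L] · I0[mU/L] / 22.5 |
| HOMA-β | 20 · I0[mU/L] / (G0 − 3.5), G0 > 3.5 |
| Matsuda | 10000 / √(G0·I0·Ḡ·Ī), G in mg/dL, I in mU/L, bars = trapezoidal OGTT means |
| HIRI | AUC_G(0–30)[mg/dL·min] · AUC_I(0–30)[mU/L·min] |
| MISI | (glucose decline rate, OGTT peak→nadir, mmol/L/min) / mean insulin [mU/L] |
| ADIPO-IR | FFA0[mmol/L] · I0[pmol/L] |
| Insulinogenic | (I30 − I0)/(G30 − G0), pmol/L per mmol/L |
| Disposition | insulinogenic · Matsuda |
| Friedewald LDL | TC − TG/2.2 − HDL (mmol/L), TG ≤ 4.5 |

These are the canonical published forms (Matthews HOMA,
Matsuda-DeFronzo, Abdul-Ghani HIRI/MISI, Gastaldelli ADIPO-IR); where a
study supplement specifies a variant (notably MISI's slope convention
and the disposition pairing), the corresponding function is the single
place to reconcile. The MISI slope is a least-squares fit over the grid
points from peak to nadir; it is undefined when glucose peaks at the
final sample. Friedewald LDL is refused above the 4.5 mmol/L
triglyceride validity limit. Domain violations raise rather than return
sentinel values; `index_panel` computes whatever a record's data permit
and leaves the rest `None`.

## Synthetic cohort generator

The generator is the package's ground-truth instrument: 37 subjects in
two arms, 73 genera, six visits, defaults chosen once to match the study
conditions it emulates.

*Community model.* Per-taxon log-mean abundances form a fixed ladder —
the quantiles of N(0, 3.3²) — treated as a population constant; subjects
deviate by N(0, 1) per taxon, visits by N(0, 0.3). Counts are multinomial
on softmax(latent) at log-normal depth (median 20 000, ln-sd 0.3). The
fixed ladder keeps baseline richness stable (≈ 46–49 observed genera)
instead of swinging cohort-to-cohort.

*Perturbation.* The 36 most abundant taxa are depleted by −9 latent ln
units (effectively absent); 22 taxa drawn from the rare tail bloom with
log-fold increases following the expected order statistics of an
Exp(mean 4) profile — one reliably dominant opportunist plus a decaying
tail, lightly jittered and shuffled among the bloomed taxa; 15 taxa are
untouched. Tying depletion to high abundance and blooms to the rare tail
is what produces the observed richness collapse (mean ≈ 48 → ≈ 14
genera at CID2): depleting dominants renormalizes rare taxa *upward*, so
an abundance-agnostic scheme cannot collapse richness. The
dominant-opportunist profile is deterministic in shape because the
collapse is a structural property of the perturbation, not a tail event.
Note that in CLR terms unaffected taxa also shift (renormalization), so
nearly all taxa change significantly in the paired antibiotic screen —
slightly more than the ~80% seen in the real data.

*Recovery.* Each taxon's displacement decays as `exp(−r·week)` with a
subject-specific rate, log-normal around 0.22/week (ln-sd 0.3) — chosen
so recovery is clearly incomplete at week 8 and mean week-2 resilience
sits near 0.07 in the placebo arm. The supplemented arm receives a rate
advantage of 0.08/week during weeks 0–2. In the default *transient*
scenario the accumulated head start washes out over weeks 2–4, after
which both arms share one trajectory — reproducing the observed pattern
of a week-2 difference (mean R ≈ 0.12 vs 0.07) that is gone by week 4;
setting `transient_effect=False` makes the advantage persistent. No
quantitative recovery-rate estimates exist to calibrate against, so
these rates reproduce the qualitative trajectory shape only.

*Randomization and design.* Arms are assigned by Pocock-Simon
minimization on sex, age (<45/≥45 y) and BMI (<30/≥30 kg/m²) with equal
factor weights and seeded coin flips on ties; realized arm sizes are
19/18 or 18/19 depending on the tie-breaks. Visits go missing completely
at random at 3% per sample, mimicking the varying per-visit n of the
emulated trial. Metabolic outcomes are generated independently with a
subject random intercept, a per-week time trend, an arm-by-week effect
(default: an IL-6-like marker with −0.0225 per week, i.e. −0.18 over
eight weeks) and Gaussian noise, at the three clinical investigation
days. Everything is reproducible bit-for-bit from (params, seed).

*What the generator does not emulate.* Taxon-taxon interactions and
cross-feeding, strain dynamics, compositional overdispersion beyond the
multinomial, informative missingness, measurement batch effects, and the
evenness profile of real gut communities (the skewed abundance ladder
that produces the right richness yields a baseline Shannon index near
1.5 rather than the ≈ 2.8 of real cohorts). Passing pipeline tests on
synthetic data therefore demonstrates correctness of the statistical
machinery under the stated model, not robustness to every feature of
real sequencing data.

## Problem sizes used in validation

Monte-Carlo checks run at sizes chosen to make their Bernoulli error
bands meaningful while staying desk-scale: 500 null cohorts for the
type-I error of the interaction LRT (binomial 95% band ≈ ±0.02 around
0.05), 100 transient-scenario cohorts for the two-week vs eight-week
power comparison (paired sign test on per-cohort p-values), 100 random
tables for the CLR/Aitchison brute-force oracle (agreement < 1e−10), and
full enumeration for the exact rank tests (n ≤ 8).

## Known limitations

- Degrees-of-freedom corrections (Kenward-Roger/Satterthwaite) are not
  available for the mixed-model contrasts; per-visit post-hoc tests use
  z-approximations, slightly liberal at n ≈ 37.
- The interaction LRT is mildly anticonservative for many-level time
  factors at this cohort size (≈ 0.06–0.07 empirical size at five
  levels).
- BIOM support covers reading (1.0 JSON and 2.x HDF5 CSR); writing is
  TSV-only.
- The resilience statistic is intentionally the only recovery metric;
  AUC-based or Bray-Curtis-based alternatives are out of scope.
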