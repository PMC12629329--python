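# microresilience

Analysis toolkit for **longitudinal gut-microbiome resilience** after an
antibiotic perturbation, built for two-arm supplementation trials: a
baseline visit (CID1), a post-antibiotic visit after wash-out (CID2,
start of supplementation), supplementary visits at two-week intervals
(SuV1–SuV3) and an end-of-supplementation visit (CID3).

It is aimed at microbiome researchers who have genus-level 16S count
tables plus clinical metadata and want to quantify *how fast* a perturbed
community returns to its own baseline, whether two intervention arms
recover at different speeds, and how recovery relates to host metabolic
physiology.

## What it computes

**Compositional geometry.** Counts are treated as compositions: with a
pseudocount `p`, each sample is centred-log-ratio transformed,
`clr(x)_j = ln(x_j + p) − (1/K) Σ_k ln(x_k + p)`, and the **Aitchison
distance** between two samples is the Euclidean distance between their
CLR vectors. α-diversity (observed genus richness `S_obs`, Shannon
`H = −Σ p_j ln p_j`) and PCA ordination operate on the unfiltered table.

**Resilience.** For each subject, every post-baseline sample gets a
distance `d(t)` to that subject's own CID1 sample; with
`d_max = max_t d(t)`,

```
R(t) = (d_max − d(t)) / (d_max + d(t))
```

so `R = 0` at maximal displacement (right after the antibiotic course)
and `R → 1` as the community returns to baseline.

**Inference.** Per outcome, a linear mixed model
`value ~ arm + time + arm:time (+ covariates)` with a subject random
intercept (REML estimates); the single treatment-by-time interaction
p-value is a likelihood-ratio test (ML refits) over categorical time,
with per-visit Wald contrasts after a significant interaction. Companion
nonparametrics: exact Wilcoxon signed-rank (baseline vs post-antibiotic),
exact Mann-Whitney U (between arms per visit), Benjamini-Hochberg
correction across each per-taxon screen (q < 0.05), and Pearson/Spearman
correlation screens. Per-taxon modelling uses CLR abundances after a 15%
prevalence filter.

**Metabolic indices.** From seven-point OGTT glucose/insulin curves and
fasting biochemistry: HOMA-IR, HOMA-β, Matsuda index, HIRI, MISI,
ADIPO-IR, insulinogenic and disposition indices, and Friedewald LDL
(`LDL = TC − TG/2.2 − HDL`, valid for TG ≤ 4.5 mmol/L). All inputs SI;
conversions (1 mU/L = 6.945 pmol/L insulin; 18.016 mg/dL per mmol/L
glucose) are internal.

**Synthetic cohorts.** A generator produces complete two-arm study
bundles (counts, metadata, metabolic outcomes, ground truth) with a
severe perturbation, arm-specific exponential recovery in latent
log-abundance space, multinomial sequencing noise, covariate-adaptive
minimization randomization and random missingness — so the entire
pipeline is testable against known truth.

## Worked example

```bash
microresilience simulate --seed 42 --out demo
microresilience resilience --counts demo/counts.tsv \
    --metadata demo/metadata.tsv --out demo/resilience.tsv
```

prints

```
wrote synthetic study (216 samples) to demo
wrote resilience trajectories for 34 subjects to demo/resilience.tsv
```

(216 of 37×6 = 222 samples survive random missingness; 34 of 37 subjects
have the CID1 baseline needed for a trajectory). The long table has one
row per subject-visit with `d`, `dmax` and `R`; mean resilience by visit
and arm for this seed:

```
arm          2FL  placebo
timepoint
CID2       0.001    0.010
SUV1       0.119    0.070
SUV2       0.289    0.224
SUV3       0.464    0.401
CID3       0.566    0.515
```

Resilience is pinned near 0 at CID2 (the moment of maximal displacement),
recovers incompletely by week 8, and the supplemented arm is ahead at
week 2 (0.119 vs 0.070) — the transient recovery advantage the generator
encodes. Feeding the same table to `fit_lmm` with time levels
(CID2, SUV1) tests exactly that two-week contrast.

The same study directory works with `diversity`, `taxa-lmm --design
{vanco,arms2wk,lmm2,lmm8}` and `report`; `metabolic` converts an OGTT
long table into the index panel per subject-visit.

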