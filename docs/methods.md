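# Methods

## The bilinear model

`arpan` models a proteogenomic cohort as a bilinear system: centred
expression `Y` (N genes × M samples) is explained by binary promoter
binding-site calls `D` (N × Q), centred protein profiles `P` (M × S) and a
learned TF-by-protein interaction matrix `W` (Q × S),

    Y = D W Pᵀ + E,   W = argmin ‖Y − D W Pᵀ‖²_F + λ‖W‖²_F.

The objective is the direct bilinear ridge; via `vec(DWPᵀ) = (P ⊗ D) vec(W)`
its unique minimizer (for λ > 0, or λ = 0 with nonsingular normal
equations) is `vec(W) = (PᵀP ⊗ DᵀD + λI)⁻¹ vec(DᵀYP)`. The solver never
forms the QS × QS system: it diagonalizes `DᵀD = U_d Λ_d U_dᵀ` and
`PᵀP = U_p Λ_p U_pᵀ` once and divides the rotated cross-product
`U_dᵀ (DᵀYP) U_p` element-wise by `λ_d,i λ_p,j + λ`. This is algebraically
identical to the dense solve (verified to ~1e−13 relative error in the test
suite) and makes refits against new response matrices — cross-validation
folds, permutation nulls — two small matrix products. A singular system at
λ = 0 raises with advice to use a positive penalty.

Two mappings read activities out of a fitted model. TF activities `W Pᵀ`
push each sample's protein profile through the interaction matrix; protein
activities `Yᵀ D W` pull each sample's expression profile back through the
binding sites. Held-out prediction maps a new (training-centred) protein
profile `p` to similarities `s = Yᵀ D W p` with the training samples and
reconstructs the expression profile in the span of the training profiles by
solving `(YᵀY + ε I) a = s`, `ŷ = Y a`, with ε defaulting to
`1e−6 · tr(YᵀY)/M`. The reconstruction transform is a design choice: any
regularized inverse of the training Gram matrix serves; this one is
deterministic, always solvable, and exact in the ε → 0 limit for profiles
inside the span.

## Preprocessing conventions

* Expression is restricted to the k = 5,000 most variable genes (variance
  across samples, ties broken by input order); genes are centred per-row on
  the training samples, protein features per-column. Stored training means
  centre held-out and external data.
* Somatic events are binarized: silent mutations dropped; mutation genes
  kept at driver q < 0.05 and ≥ 10 carriers; copy-number events are calls
  of −2 (homozygous loss) or +2 (high-level amplification) with region
  q < 0.001 and ≥ 10 carriers; amplification and deletion become separate
  columns.
* TFs are dropped when their own gene is expressed in under 40% of samples
  (boundary inclusive). "Expressed" means the raw log value exceeds the
  dataset's floor (its global minimum, i.e. the zero of the pre-log scale);
  the threshold is configurable since expression floors differ between
  quantification pipelines.
* Motif columns are de-duplicated greedily in column order at target-set
  Jaccard ≥ 0.8; greedy-in-order is deterministic and keeps the first of
  any redundant group, and every removal is logged with its retained
  partner. Missing values anywhere are a hard validation error — no
  imputation is attempted.

## Cross-validation and baselines

K-fold (default 10) with a seeded uniform shuffle into near-equal folds.
All training-derived quantities — gene selection, centring means, W — are
recomputed per fold from training samples only. λ defaults to 1.0; when a
grid is supplied it is selected per fold on an inner 80/20 split by mean
held-out Spearman (average-rank ties). Baselines share the identical fold
structure: nearest-neighbour in protein space (Euclidean, ties to the
lowest sample index, logged) and control fits with motif rows and/or
protein rows shuffled within the training set — shuffling preserves each
matrix's row multiset and destroys only the pairing. Constant predicted or
measured profiles make the correlation undefined; they are recorded as
missing and logged, never silently zeroed.

## Activity significance

The empirical null refits the model against expression with permuted sample
labels (whole columns of Y), keeping D and P fixed, and recomputes both
activity mappings per permutation. Shuffling whole profiles preserves
gene–gene covariance and per-profile structure while destroying exactly the
expression–protein pairing under test; a per-gene shuffle is available as
`scheme="per_gene"`. Tail p-values use the smoothed convention
`(1 + #{draws ≥ obs}) / (B + 1)` (ties count toward both tails, so
left + right > 1 and no p is ever 0), two-tailed `min(1, 2·min(left,
right))`. BY (Benjamini–Hochberg–Yekutieli) correction — valid under
arbitrary dependence — runs per sample across regulators, TF and protein
families separately. Flag thresholds follow cohort size: 0.10 above 300
samples, 0.15 from 100 to 300, 0.25 below 100. A flagged cell's direction
is the sign of its smaller tail. Per-regulator prevalence (fraction of
samples flagged) feeds the association filters. The test suite uses 200
permutations by default and 500 in the calibration checks; 5,000 is the
recommended setting for production cohorts (the ensemble builder's
precomputed factorization makes this cheap at RPPA-scale dimensions).

## Alteration association

Each regulator's activity is regressed on the full binary alteration matrix
by ridge (λ = 1.0 default, predictors deliberately left 0/1, outcome
centred, intercept unpenalized). Significance is by permutation: the
outcome is shuffled across samples and refit (the coefficient hat matrix is
precomputed, so all permutations are one matrix product); the nominal p of
a coefficient is the smoothed fraction of null |β| at least as large.
Permutation draws are fresh per regulator from spawned seeds. Tie
comparisons use a 1e−9 relative tolerance so exact rearrangements of the
observed split are not lost to summation roundoff — without it, enumerable
instances converge to half the tied mass. Nominal p-values are BY-corrected
across regulators within each (alteration, family) group; the signed score
is sign(β) × adjusted p, and sign(β) × (−log₁₀ adjusted p) is emitted for
display. Downstream filters: regulator prevalence ≥ 1% of samples,
alteration retained at adjusted p < 0.15 for ≥ 1 regulator.

Pairwise interactions (pairs altered in ≥ 20 samples each, co-altered in
≥ 10) use OLS of activity on intercept + A + B + A·B with the classical
two-sided t-test of the interaction coefficient (the main screen's
permutation machinery is unnecessary here since a single coefficient of a
4-parameter model is tested). A significant (p < 0.05) interaction
coefficient greater than zero and than both main effects is synergistic;
less than zero and than both is antagonistic; anything else is none.

## Cohort screens

Group comparisons are per-regulator two-sided tests (t or Mann–Whitney
rank-sum), mean difference signed group1 − group2, BH-corrected across
regulators (BH rather than BY here, matching the less conservative
correction conventionally used for these secondary screens; configurable).
Rank-set enrichment is a one-sided Mann–Whitney on ranking positions.
Survival screens fit one Cox proportional-hazards model per regulator
(continuous activity + reference-level indicator contrasts of the
categorical covariate, reference = most frequent level; samples with
missing covariate excluded with a logged count); reported are the hazard
coefficient, its Wald p, a log-rank p between the top-40%/bottom-40% risk
groups (risk = the Cox linear predictor), and BH-corrected model p-values.
Activity-versus-expression model families are compared by one-sided paired
Wilcoxon signed-rank (zero differences dropped; all-zero input reports
p = 1 with a warning). Risk stratification takes the top and bottom
⌊0.40·n⌋ by risk with boundary ties broken by sample order. External
transfer restricts W (or D) to shared features, centres the external matrix
by its own means by default (antibody batches differ between cohorts;
training means available by flag) and reports the retention fraction.
Concordance validation computes Harrell's C on negated risks (higher risk →
earlier event) with a seeded permutation test against C = 0.5 — the
permutation route avoids distributional assumptions that the common normal
approximations require.

## The synthetic generator

`make_cohort` draws D ~ Bernoulli(0.10) (all-zero TF columns repaired), a
sparse W* (30% nonzero, N(0,1) entries), standard-normal protein profiles,
and Y = D W* Pᵀ plus Gaussian noise at sd = 0.5 × the empirical signal sd —
the reference noise level for all recovery checks, with the signal sd
measured per draw so the ratio is always well-defined. Ten alterations at
30% frequency; the first three each add +1.0 to one protein feature of
their carriers, so planted effects propagate through the full inference
chain rather than being painted onto activities directly — this is the
causal direction the model assumes (alterations perturb signalling, which
perturbs TF activity). A binary subgroup label shifts two further features.
Survival times are exponential proportional-hazards draws on the first TF's
standardized true activity (log-hazard coefficient 1.0, baseline hazard
0.02/month) with independent exponential censoring whose rate,
`baseline · frac/(1 − frac)`, realizes the configured ~30% censoring within
a few points. `make_null_cohort` keeps all marginals but sets W* ≈ 0 with
unit noise, giving an exact null for calibration. Reference dimensions are
N = 1000, M = 100, Q = 40, S = 25; the fixture suite also emits tiny
(50 × 12) and small (500 × 60) cohorts. The statistical checks in the test
suite and acceptance script run at these reference dimensions (the
association screen uses M = 200 for adequate carrier counts, the survival
checks n = 300 with 200 null regulators).

What the generator does *not* emulate: TCGA marginal distributions, batch
effects, antibody cross-reactivity, motif-matrix noise or the strong
RPPA–mRNA correlation structure of real tumours. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not expected effect sizes on real cohorts — on
real data the motif matrix is noisy and incomplete, and improvements over
randomized controls are far more modest.

## Numerical conventions

Eigenvalues of the factorized solver are clipped at zero; singularity at
λ = 0 is declared when the smallest spectral denominator falls below 1e−12
of the largest. Spearman correlations use the average-rank convention for
ties. Empirical p-values are never 0 or 1-exclusive by the +1 smoothing.
All stochastic procedures take explicit integer seeds; per-regulator
permutation streams come from `SeedSequence.spawn`. Variance-ranking,
motif-deduplication, nearest-neighbour and stratification ties all break
deterministically by input order, and each tie-break is logged.

## Known limitations

* λ is chosen on an inner split only inside cross-validation; the
  single-fit default of 1.0 is a convention, not an optimum.
* The association screen tests alterations jointly but regulators
  marginally; strongly correlated activities yield correlated discoveries,
  which the BY correction absorbs but does not disentangle.
* The Cox screens assume proportional hazards and a correctly specified
  linear activity effect; no diagnostics are run per model.
* Transfer to external cohorts assumes feature names are comparable across
  antibody panels; no cross-panel harmonization is attempted.
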