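# arpan

Affinity-regression modelling of proteogenomic cancer cohorts: linking
upstream (phospho)protein signalling to downstream transcriptional programs,
and asking which somatic alterations perturb that link.

## The problem

A tumour cohort profiled in parallel with RNA-seq (gene expression),
reverse-phase protein arrays (RPPA; (phospho)protein abundance), somatic
mutation calls and discrete copy-number calls carries more information than
any single platform: changes in signalling-protein levels should propagate
through transcription factors (TFs) to their target genes. `arpan` models
this flow explicitly. Given

* `Y` — mean-centred log expression, *N* genes × *M* samples,
* `D` — binary promoter binding-site calls, *N* genes × *Q* TFs,
* `P` — mean-centred protein profiles, *M* samples × *S* antibody features,

it learns the TF-by-protein **interaction matrix** `W` (*Q* × *S*) as the
bilinear ridge minimizer

```
min_W  || Y − D W Pᵀ ||²_F + λ || W ||²_F
```

solved exactly through the Kronecker-product normal equations
`vec(W) = (PᵀP ⊗ DᵀD + λI)⁻¹ vec(DᵀYP)` (the implementation diagonalizes
`DᵀD` and `PᵀP` once, so refits against new responses are two small matrix
products). A fitted model yields two per-sample activity mappings:

* **TF activities** `W Pᵀ` — each TF's regulatory output implied by the
  sample's protein profile;
* **(phospho)protein activities** `Yᵀ D W` — an expression-informed score
  of each protein feature.

Around this core the package provides the full analysis pipeline:
cross-validated held-out expression prediction with nearest-neighbour and
input-randomized baselines; permutation-null calibration of activities
(refit against expression with shuffled sample labels, smoothed empirical
tail p-values, Benjamini–Hochberg–Yekutieli correction with
cohort-size-banded FDR thresholds); ridge + permutation association of
binary somatic alterations with activities, including pairwise
synergy/antagonism interaction tests; differential-activity and Cox
survival screens with 40/40 risk stratification and concordance-index
validation; and a synthetic-cohort generator drawn from the same bilinear
generative model with planted alteration effects and survival hazards, so
every stage is testable without external data.

## Worked example

```python
import numpy as np
from arpan import AffinityRegression, SimulationConfig, make_cohort
from arpan.crossval import cross_validate

bundle, truth = make_cohort(SimulationConfig(seed=1))   # reference synthetic cohort
res = AffinityRegression.from_bundle(bundle).fit(lam=1.0)
print(res.summary())

act = res.tf_activities()
cors = [np.corrcoef(act.values.iloc[:, j], truth.tf_activities.iloc[:, j])[0, 1]
        for j in range(act.values.shape[1])]
print(f"median per-sample correlation with true TF activities: {np.median(cors):.3f}")

print(cross_validate(bundle, folds=10, seed=0).summary())
print(cross_validate(bundle, folds=10, seed=0, model="motif").summary())
```

prints

```
Affinity Regression Results
=============================================
Genes (N):              1000
Samples (M):            100
TFs (Q):                40
Protein features (S):   25
Ridge penalty lambda:   1
||W||_F:                17.8455
In-sample R^2:          0.8003
=============================================
median per-sample correlation with true TF activities: 0.985
CV report [true] metric=spearman seed=0: mean r=0.8098 rmse=3.2937 (100 held-out samples)
CV report [motif] metric=spearman seed=0: mean r=0.3740 rmse=5.9596 (100 held-out samples)
```

The fitted model explains 80% of the centred expression variance in-sample;
the inferred TF activities track the generative ground truth almost
perfectly at this noise level (expression noise sd = 0.5 × signal sd); and
held-out prediction degrades sharply (0.81 → 0.37 mean Spearman) when the
motif matrix rows are shuffled, showing that the binding-site structure —
not just expression covariance — carries the signal.

The same pipeline is scriptable from the shell: `arpan simulate`, `arpan
fit`, `arpan activities`, `arpan crossval`, `arpan null`, `arpan
significance`, `arpan associate`, `arpan interactions`, `arpan compare`,
`arpan survival` all operate on a cohort-bundle directory of TSV files
(`arpan --help` for options).

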