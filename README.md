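# knnbiome

Model-free prediction of microbial community composition from species
presence/absence, with the simulation and diagnostic machinery needed to
evaluate when such prediction works.

## The problem

Interventions on a microbiome — antibiotics, probiotics, fecal
transplants — act on the *species assemblage*: which taxa are present.
After the ecosystem re-equilibrates, the species' *abundances* settle at
a new steady state. Predicting that abundance profile from the intended
assemblage is the practical question, and mechanistic routes (fitting a
population-dynamics model such as generalized Lotka–Volterra to data)
are fragile for communities of hundreds of taxa.

`knnbiome` takes the model-free route. Given a training cohort — an
m × N matrix Θ of relative abundances with binary assemblage view θ —
and a test assemblage φ, it finds the k training samples whose
assemblages are most Jaccard-similar to φ and averages their profiles
species-wise, dividing by p_i (the number of those neighbors that carry
species i, not k):

    Θ̄ᵏ_i = (1/p_i) Σ_{ν∈R} Θ_{ν,i},   Φ_i = Θ̄ᵏ_i if φ_i = 1, else 0,

renormalized to sum 1. The naive *null model* predicts every present
species by its cohort-wide mean, independently of the rest of the
assemblage; the *kNN gain* Δ = err_null − err_kNN(k_min) measures how
much information the joint assemblage carries. Errors are the root
Jensen–Shannon divergence (rJSD) between predicted and true profiles.

The package also provides:

* a **GLV cohort simulator** (`knnbiome.glv`) whose samples are verified
  stable steady states of dx_i/dt = x_i(r_i + Σ_j a_ij x_j), with
  tunable interaction strength σ and "universality" λ (per-sample
  perturbed dynamics);
* **composition metrics** (`knnbiome.metrics`): Jaccard similarity,
  abundance-weighted overlap, and the shared-species renormalized rJSD
  dissimilarity;
* the **dissimilarity–overlap curve** diagnostic (`knnbiome.doc`): the
  OLS slope over the top-20%-overlap sample pairs predicts whether the
  kNN will beat the null model on a given cohort;
* **OTU-table preprocessing** (`knnbiome.preprocessing`): read-count and
  prevalence filters plus first-visit-per-subject selection, so real
  tab-separated or BIOM-1.0 tables flow into the same predictor;
* a **neural-network comparison model** (`knnbiome.neural`) and scripted
  **evaluation protocols** (`knnbiome.experiments`).

## Worked example

```python
import numpy as np
from knnbiome import AssemblageKNN, CohortSpec, generate_cohort

cohort = generate_cohort(CohortSpec(n_species=10, n_samples=120, sigma=0.6, seed=7))
train, test = cohort.subset(np.arange(100)), cohort.subset(np.arange(100, 120))

model = AssemblageKNN(train)
print(model.evaluate(test, ks=[1, 2, 5, 10]).summary())
```

```
kNN evaluation (rJSD prediction error)
==============================================
repetitions: 1   test samples/rep: 20
null model (present-only): 0.1066
k_min = 1   error(k_min) = 0.0406
gain Delta = +0.0660
----------------------------------------------
     k   mean_error         se
     1       0.0406     0.0199
     2       0.0456     0.0144
     5       0.0577     0.0125
    10       0.0813     0.0117
```

Reading: with 100 training steady states of a 10-species pool, the kNN
at its best k predicts held-out profiles with mean rJSD ≈ 0.04, well
below the null model's 0.11 — the assemblage carries real information
about the abundances. The best k is 1 because in a 10-species pool even
the 2nd-nearest assemblage is already quite different.

The same objects work on real data:

```python
from knnbiome import preprocess
from knnbiome.preprocessing import read_counts_tsv

table = read_counts_tsv("stool_counts.tsv", "stool_metadata.tsv")
cohort = preprocess(table)            # <1 read/sample filter, 10% prevalence, first visit
model = AssemblageKNN(cohort)
```

A `knnbiome` console script exposes the same steps
(`simulate`, `predict`, `evaluate`, `doc`, `preprocess`, `experiment`);
run `knnbiome --help`.

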