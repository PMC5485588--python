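# grape-rank

Rank-pair pathway templates for gene expression data: single-sample
pathway deviation scores, nearest-template tissue classification, and
batch-effect quantification — all built on within-sample gene orderings,
so every statistic is invariant to per-sample monotone normalisation.

## Who this is for

Transcriptomics analysts who need pathway-level summaries that survive
platform and batch differences: microarray intensities and RNA-Seq RPKM
can be mixed, because only the *ordering* of genes within each sample is
used.

## The model

For a pathway with genes (g₁, …, g_m), each sample reduces to a bit
vector **B** over the m(m−1)/2 gene pairs, with the bit for (gᵢ, gⱼ),
i < j, equal to 1 iff gᵢ's expression is below gⱼ's (exact ties flip a
fair coin). Averaging **B** over a reference collection gives the
*probability template* **T_P**; rounding it gives the *binary template*
**T_B**, the consensus ordering (entries at exactly 0.5 are assigned by a
coin flip).

Distances from a sample to a template:

* uniform weights: D = (1/|E|) Σ |T_B − B| — the plain reversal
  proportion;
* weighted: D = (1/S) Σ w(T_P) |T_B − B|, with S = Σ w(T_P) and the
  quadratic weight w(x) = (x − 0.5)², which silences gene pairs whose
  ordering is variable in the reference. The constant weight w ≡ 1
  recovers the uniform-weight distance exactly.

Single-sample pathway score: with θ the median and δ₀ the IQR of the
reference samples' own distances, and δ = max(δ₀, w(0.75)/S),

    f(d) = 0               if d ≤ θ
         = (d − θ)/δ       otherwise.

Classification assigns a sample to the class whose template it is
nearest to (weighted, uniform, or a Euclidean pathway-centroid
baseline). Batch effects are quantified by the absolute rate of
differential expression (ARDE: fraction of genes with t-test p < 0.01
between two datasets) versus the relative rate (RRDE: fraction of gene
pairs whose ordering proportions differ by Fisher's exact test),
estimated by subsampling; the hetero-/homo-tissue ratio of a rate is its
signal-to-noise measure, and the differential ordering measure (DOM)
attributes ordering disruption to individual genes.

## Worked example

```python
import numpy as np
from grape import (GeneratorConfig, generate_cohort, generate_gmt,
                   fit_references, score_matrix)

healthy = GeneratorConfig(seed=0, n_genes=60, n_per_class=40,
                          class_orders={"healthy": list(range(60))},
                          flip_noise=0.1)
disease = GeneratorConfig(seed=1, n_genes=60, n_per_class=15,
                          class_orders={"disease": list(range(59, -1, -1))},
                          flip_noise=0.1)
ref_expr, _ = generate_cohort(healthy)
dis_expr, _ = generate_cohort(disease)

pathways = generate_gmt(3, (10, 15), list(ref_expr.index), np.random.default_rng(2))
refs = fit_references(ref_expr, pathways, weight="quadratic",
                      rng=np.random.default_rng(3))
cohort = dis_expr.iloc[:, :2].join(ref_expr.iloc[:, :2])
cohort.columns = ["disease_s0", "disease_s1", "healthy_s0", "healthy_s1"]
print(score_matrix(cohort, refs, rng=np.random.default_rng(4)).round(2))
```

prints

```
         disease_s0  disease_s1  healthy_s0  healthy_s1
pathway
PW0000       285.62      286.07        1.00         0.0
PW0001       217.80      217.80        0.00         0.0
PW0002       216.69      216.69        3.24         0.0
```

Healthy samples score at or near 0 (within reference behaviour); the
disease samples — whose consensus ordering is reversed — sit hundreds of
calibrated spreads away. For `PW0000` the calibration is θ = 0.0000,
δ = 0.0035 over 105 gene pairs: the reference ordering is so stable that
δ is set by the single-reversal floor w(0.75)/S rather than the IQR.

The same machinery is scriptable from the shell:

```bash
grape simulate --config sim.json --seed 9 --out-prefix cohort
grape template --expr cohort.expr.tsv --gmt cohort.gmt --seed 1 --out templates.tsv
grape score    --expr cohort.expr.tsv --ref-expr cohort.expr.tsv \
               --gmt cohort.gmt --seed 7 --out scores.tsv
grape classify --expr cohort.expr.tsv --labels cohort.labels.tsv \
               --gmt cohort.gmt --method grape --seed 5 --out-prefix cv
```

Every output starts with a provenance comment (version, seed,
parameters) that regenerates it exactly.

sklearn users can plug the estimators straight into pipelines:
`GrapeScorer(gene_sets=...)` is a transformer mapping samples × genes to
samples × pathway scores, and `NearestTemplateClassifier(genes=...,
method="grape")` is a classifier over one pathway's genes.

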