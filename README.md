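# gfblup — genomic prediction with biological priors

`gfblup` implements genomic prediction of complex plant traits with linear
mixed models that can exploit prior biological knowledge about groups of
genes. It is aimed at quantitative geneticists and breeders working with
inbred diversity panels (the motivating system is an *Arabidopsis thaliana*
natural-accession panel phenotyped for photosynthetic light-use efficiency
and projected leaf area on an automated imaging platform) who want to ask:
*does telling the model which markers sit in a trait-relevant gene set
improve prediction accuracy?*

## Models

All models act on design-adjusted phenotypes (per-accession BLUEs) ỹ and a
genomic relationship matrix (GRM) **G** = **WW**′/*m* built from centered,
scaled minor-allele counts, *w*ᵢ = (*z*ᵢ − 2*p*ᵢ)/√(2*p*ᵢ(1 − *p*ᵢ)).

* **GBLUP** — one genomic component:
  ỹ = μ + **g** + ε, with **g** ~ N(0, **G**σ²g), ε ~ N(0, **I**σ²e).
* **GFBLUP** — the genetic value is split between a *genomic feature*
  (markers inside the ORFs of a gene set: a GO term with annotations
  up-propagated along `is_a`/`part_of`, a co-expression cluster, or a
  curated list) and the remaining markers:
  ỹ = μ + **f** + **r** + ε, **f** ~ N(0, **G**f σ²f), **r** ~ N(0, **G**r σ²r).
* **Adaptive MultiBLUP** — region kinships **K**₁…**K**_M chosen by jointly
  testing 10-kb half-overlapping windows against the phenotype
  (*p* < 10⁻⁵ to seed, Bonferroni-checked merging), with fallback to the
  all-marker GRM when nothing is significant.

Variance components are estimated by average-information REML (≤100
iterations, tolerance 10⁻⁵, step-halving, EM fallback, boundary handling),
test-set genomic values are predicted conditional on training phenotypes,
and models are compared by repeated 8-fold cross-validation with shared
splits, the likelihood-ratio test against the ½δ₀ + ½χ²₁ boundary mixture,
Wilcoxon–Mann–Whitney tests on accuracy distributions and
Benjamini–Hochberg FDR over the whole feature × timepoint scan. A
synthetic-data generator produces fully homozygous panels with local LD,
gene models, overlapping gene sets, and replicate-level phenotypes with
spatial design effects, so the entire pipeline is testable without any
external download.

## Worked example

```python
import numpy as np
import gfblup as gf
from gfblup.mixedmodel import ModelSpec

# simulate a 250-accession panel; one feature carries 70% of the genetic variance
cfg = gf.SimulationConfig(n_accessions=250, n_markers=2000, n_chromosomes=2,
                          n_genes=300, n_features=5, feature_size_range=(15, 25),
                          seed=1)
geno, genes = gf.simulate_genotypes(cfg)
feats = gf.simulate_feature_sets(genes, cfg, geno)
trait = gf.TraitConfig(h2_target=0.4, feature_id=feats[0].feature_id,
                       hf2_share=0.7, n_causal=50, n_replicates=1,
                       design_effect_sds={}, seed=2)
sim = gf.simulate_trait(geno, feats, trait)
y = sim.phenotypes.sort_values("accession")["value"].to_numpy()

w = gf.center_scale(geno)
g_all = gf.compute_grm(w, geno.accession_ids)
g_f, g_r = gf.partition_grm(geno, feats[0].marker_indices, w=w)

splits = gf.make_cv_splits(250, k=8, repeats=3, seed=1)
cv_gblup = gf.cross_validate(ModelSpec([g_all]), y, splits, "GBLUP", 1)
cv_gfblup = gf.cross_validate(ModelSpec([g_f, g_r]), y, splits, "GFBLUP", 1)
med_f, med_0, gain, p = gf.compare_accuracy(cv_gfblup, cv_gblup)

fit = gf.reml_fit(y, ModelSpec([g_f, g_r]))
print(f"hf2 = {gf.heritabilities(fit)['hf2']:.3f}")
print(f"median r: GFBLUP {med_f:.3f} vs GBLUP {med_0:.3f} "
      f"({gain:+.1f}%, Wilcoxon p = {p:.3f})")
```

Output:

```
hf2 = 0.162
median r: GFBLUP 0.420 vs GBLUP 0.324 (+29.5%, Wilcoxon p = 0.044)
```

`hf2` is the proportion of phenotypic variance attributed to the feature's
markers (σ²f/(σ²f + σ²r + σ²e)); the feature that truly carries most of the
genetic variance raises the cross-validated prediction accuracy (Pearson r
between observed and predicted values in held-out folds) relative to the
all-marker GBLUP benchmark, and the Wilcoxon p-value says that shift is
unlikely under exchangeable accuracies.

A command-line interface mirrors the library
(`gfblup simulate | qc | blue | grm | features | cv | scan`); run
`gfblup --help` for details.

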