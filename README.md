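# assemblage-lda

Microbial **assemblage analysis** for human gut metagenomes. While enterotype
analysis clusters *individuals* by their dominant microbes, assemblage
analysis clusters *taxa* that co-occur across individuals — a mixed-membership
view in which each person carries several assemblages at once, including
non-dominant ones that sample clustering cannot see (e.g. a butyrate-producer
group present across all enterotypes).

The package provides, as a library and a CLI:

- **Variational-Bayes LDA** on sample × genus (or sample × KEGG-ortholog)
  count tables. Each sample i has a mixture θᵢ over K latent assemblages
  (θᵢ ~ Dirichlet(**α**), asymmetric); each assemblage k is a distribution
  φₖ over taxa (φₖ ~ Dirichlet(β), one tied scalar). Each read draws an
  assemblage z ~ Cat(θᵢ) and a taxon ~ Cat(φ_z). Inference is mean-field
  coordinate ascent on the variational lower bound (VLB), with
  empirical-Bayes fixed-point updates of **α** and β each iteration,
  multi-restart selection by best VLB, and posterior-mean estimates
  θ̂ᵢₖ = (nᵢₖ+αₖ)/(nᵢ+Σα), φ̂ₖⱼ = (nₖⱼ+β)/(nₖ+Dβ).
- **Preprocessing**: each sample rescaled to a constant total (default
  10,000) with flooring, then features with all-zero counts dropped.
- **Enterotyping**: PAM (k-medoids) on the Jensen–Shannon divergence between
  genus relative-abundance profiles, best silhouette over random restarts,
  clusters named by their dominant genus.
- **Assemblage statistics**: assemblage prior P(k) = meanᵢ θᵢₖ; per-genus
  posterior P(k|j) = φₖⱼP(k)/ΣₖφₖⱼP(k); Shannon entropies (nats)
  H(i) = −Σₖ θᵢₖ log θᵢₖ and H(j) = −Σₖ P(k|j) log P(k|j); group-averaged
  assemblage distributions.
- **Associations**: Pearson correlation of assemblage proportions with
  functional (KO) relative abundances, Spearman genus–genus correlations,
  Benjamini–Hochberg correction, significance at adjusted p < 0.01.
- **Functional assemblages**: LDA on KO profiles at the same K, matched
  one-to-one to taxonomic assemblages by maximum total θ-column correlation,
  with per-category abundance summaries.
- **Synthetic data**: an LDA forward-process generator whose enterotype
  design emulates the known gut structure — three specialist assemblages
  dominated by one signature genus each (masses 0.71 and 0.66 for the
  Bacteroides- and Prevotella-like ones) plus one generalist assemblage
  spread over shared genera (≤ 0.20 per genus) carried by every group at a
  mean weight of 0.3, with coupled KO profiles in which butyrate-production
  KOs (K00929, K01034, K01035) load on the generalist.

## Worked example

```python
import numpy as np
from assemblage_lda import *
from assemblage_lda.stats import (
    average_by_group, compute_assemblage_stats, entropy_histogram, top_features,
)

config = make_enterotype_design(30, n_samples=120, reads_per_sample=2000, seed=7)
dataset = sample_lda_corpus(config)
norm = drop_empty_features(normalize_to_constant(dataset.counts))
fit = fit_lda(norm, K=4, n_trials=5, base_seed=0, max_iter=400)

for k in range(4):
    print(f"assemblage_{k+1}:", top_features(fit.phi[k], 3, fit.feature_ids))
grouped = average_by_group(fit.theta, dataset.group_labels)
print("groups:", grouped.group_ids)
print(np.round(grouped.mean, 3))
stats = compute_assemblage_stats(fit.theta, fit.phi)
_, _, med = entropy_histogram(stats.sample_entropies, 16, 4)
print("median sample entropy (nats):", round(med, 4))
```

prints

```
assemblage_1: [('genus_014', 0.1042...), ('genus_004', 0.1013...), ('genus_006', 0.0985...)]
assemblage_2: [('Prevotella', 0.6591...), ('genus_028', 0.0716...), ('genus_015', 0.0464...)]
assemblage_3: [('Bacteroides', 0.7044...), ('genus_021', 0.0755...), ('genus_016', 0.0467...)]
assemblage_4: [('Blautia', 0.3930...), ('genus_022', 0.1561...), ('genus_021', 0.1003...)]
groups: ['P', 'R', 'B']
[[0.286 0.645 0.037 0.033]
 [0.301 0.043 0.037 0.62 ]
 [0.321 0.031 0.622 0.027]]
median sample entropy (nats): 0.8501
```

Reading the output: the fit recovers the three specialist assemblages with
their designed dominant-genus masses (Bacteroides ≈ 0.70 vs designed 0.71,
Prevotella ≈ 0.66), and assemblage 1 is the generalist — every group carries
it at ≈ 0.3 while each group loads ≈ 0.62 on its own specialist. The median
per-sample entropy of ≈ 0.85 nats (between 0 and ln 4 ≈ 1.386) says
individuals carry a couple of assemblages, not one and not all four.

The same pipeline is available from the shell:

```bash
assemblage-lda simulate --n-samples 300 --n-features 50 --reads 5000 --seed 0 --out sim/
assemblage-lda preprocess --in sim/counts.tsv --constant 10000 --out norm.tsv
assemblage-lda fit-lda --in norm.tsv --k 4 --trials 10 --seed 0 --out fit/
assemblage-lda enterotype --in norm.tsv --k 3 --trials 10 --seed 0 --out et/
assemblage-lda stats --theta fit/theta.tsv --phi fit/phi.tsv --out stats/
assemblage-lda associate --theta fit/theta.tsv --functions sim/ko_counts.tsv \
    --function-ids K00929,K01034,K01035 --out associations.tsv
assemblage-lda run --config run.yaml   # everything, with a manifest
```

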