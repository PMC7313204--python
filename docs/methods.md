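# Methods

## Model

Counts are modeled by latent Dirichlet allocation. For N samples over D
features (genera, or KEGG orthologs for functional profiles) with K latent
assemblages:

- θᵢ ~ Dirichlet(α), α ∈ ℝ₊ᴷ asymmetric — the assemblage mixture of sample i;
- φₖ ~ Dirichlet(β·1_D), β a single positive scalar tied across features —
  the feature distribution of assemblage k;
- each read of sample i draws z ~ Categorical(θᵢ), then its feature
  ~ Categorical(φ_z).

Reads are exchangeable, so the sufficient data are the count matrix rows.
Before fitting, every sample is rescaled to a common total C (default
10,000; entry ⌊cᵢⱼ/Σⱼcᵢⱼ · C⌋ computed in exact integer arithmetic) so that
deeply sequenced samples do not dominate the corpus, and features whose
rescaled counts are zero everywhere are dropped. Fits are insensitive to the
choice of C (checked at C = 10,000 vs 100,000 in the test suite).

## Variational inference

Mean-field variational Bayes with q(z) q(θ) q(φ). Responsibilities are
stored per (sample, feature) pair and weighted by the pair's count —
mathematically identical to per-read storage and necessary at thousands of
reads per sample. One outer iteration is:

1. **E-step.** r(i,j,k) ∝ exp ψ(nᵢₖ+αₖ) · exp ψ(nₖⱼ+β) / exp ψ(nₖ+Dβ),
   normalized over k, where n are the count-weighted responsibility sums
   from the previous iteration; then the sums are recomputed. This is the
   exact coordinate-ascent update of q(z) given Dirichlet posteriors
   q(θᵢ) = Dir(nᵢ·+α) and q(φₖ) = Dir(nₖ·+β).
2. **Hyperparameter update.** Empirical-Bayes re-estimation of α
   (component-wise) and β (tied scalar) by Minka-style fixed-point
   iteration on the expected sufficient statistics E[log θ], E[log φ]
   (inner cap 100 iterations, tolerance 1e-8). Each inner step is an MM
   update of the corresponding VLB terms, so the bound cannot decrease.
3. **VLB evaluation.** The evidence lower bound of the token-sequence log
   marginal likelihood; it is a valid bound for *any* variational state,
   which the tests exploit by checking it against exhaustive-enumeration
   log marginals on tiny corpora.

Iteration stops when |ΔVLB| < tol (default 1e-6, absolute; a relative mode
is available via `tol_mode`) or after `max_iter` iterations (default 1,000,
a numerical safety bound — on near-degenerate corpora, e.g. two samples, the
empirical-Bayes α estimate diverges slowly and the VLB keeps drifting
upward, so a cap is required). The fit runs `n_trials` restarts (default 10)
from random starts — one symmetric Dirichlet(1) responsibility draw per
*sample*, shared across its features, which makes the entire fit exactly
equivariant under feature-column permutations — and keeps the restart with
the highest final VLB (ties to the lowest seed). Point estimates are
posterior means; assemblage indices are arbitrary under the model, so
reported assemblages are ordered by descending mean θ column and all
recovery tests match labels explicitly by maximum-correlation assignment.

Defaults: initial α = 0.1 (all components), initial β = 0.05, tol = 1e-6,
10 restarts, K chosen by the analyst (the pipeline fits K = 2, 3, 4, 5 and
reports K = 4 by default).

## Enterotyping

PAM (k-medoids) on the pairwise Jensen–Shannon divergence between genus
relative-abundance profiles, JSD(p,q) = ½KL(p‖m) + ½KL(q‖m), m = (p+q)/2,
natural log, with the 0·log 0 = 0 convention (no pseudo-counts; m is
positive wherever either argument is). Each trial starts from k distinct
random medoids and alternates nearest-medoid assignment (ties to the lower
cluster index) with medoid minimization until the medoid set is stable; an
emptied cluster is re-seeded to the non-medoid sample farthest from every
current medoid. Ten trials by default; the trial with the highest silhouette
coefficient wins (silhouette uses the precomputed JSD matrix; singleton
clusters score 0). Clusters are named by their most abundant genus.

## Assemblage statistics

P(k) is the average of θᵢₖ over samples; P(k|j) = φₖⱼP(k)/ΣₖφₖⱼP(k).
Entropies are Shannon entropies in **nats** (0·log 0 = 0), bounded by ln K.
Low H(j) marks assemblage-specific genera, high H(j) genera shared across
assemblages; H(i) near 0 marks single-assemblage individuals.
Group-averaged assemblage distributions report per-group means and
population standard deviations (divide by n) of the θ columns.

## Associations

Assemblage-function association uses Pearson correlation between θ columns
and per-sample *relative* KO abundances (functional counts are normalized
per sample, matching the compositional treatment of taxa), two-sided
p-values from the t distribution with N−2 degrees of freedom (an exact
permutation mode is available for small N), and Benjamini–Hochberg step-up
adjustment over the whole K × F family; significance at adjusted p < 0.01.
Genus–genus checks use Spearman correlation with average ranks for ties.
Zero-variance columns are reported as missing and excluded from the BH
family with a warning.

## Functional assemblages

LDA is fitted to the KO count table at the same K. Functional assemblages
are matched one-to-one to taxonomic assemblages by the permutation
maximizing the summed Pearson correlation between θ columns across samples,
solved exactly as a linear assignment problem; this matching rule is this
package's construction. KO-level φ rows are aggregated into functional-
category abundances through a KO→category map in which each KO belongs to
exactly one category (multi-category hierarchies must be flattened
upstream); unmapped KOs pool into an "unmapped" category.

## Synthetic data generator

The generator is the LDA forward process itself, which is the appropriate
testbed because the inference target is exactly this model. The enterotype
design (K = 4) emulates the qualitative gut structure:

- **Specialists** (assemblages 1–3): dominant mass on one signature genus
  each — 0.71 (Bacteroides-like) and 0.66 (Prevotella-like) by default; the
  third uses 0.40, our choice, large enough that dominant-genus cluster
  naming is unambiguous against the generalist cap below. Signature genera
  are the first three feature indices by convention. The remaining mass is
  spread by a fixed low-concentration Dirichlet(0.5) draw over the genera
  from index 9 on.
- **Generalist** (assemblage 4): mass spread over a 12-genus block (indices
  3–14) as a jittered uniform; the construction bounds every entry by
  1.3/(0.7·12) ≈ 0.155 < 0.20. Block genera 3–8 are exclusive to the
  generalist (anchor genera); genera 9–14 are shared with the specialists'
  spread and therefore acquire mixed P(k|j) — together these produce the
  two-peak feature-entropy structure (assemblage-specific vs shared genera).
- **Groups**: each sample belongs to one of three groups (B/P/R) whose θ
  prior is Dirichlet with concentration 50 (our choice for realistically
  tight within-enterotype dispersion; nothing in the emulated structure
  pins it) around means of 0.62 on the group's specialist, 0.04 on the
  other two, and a **mean** of 0.3 on the generalist.

The generalist weight is realized as a two-component mixture per group: 80%
of samples are generalist-rich (weight 0.365) and 20% generalist-poor
(weight 0.04), keeping the group mean at exactly 0.3. This dispersion is
essential, not cosmetic: if every sample carried the same generalist weight,
the decomposition would be non-identifiable — replacing a specialist row by
a blend φₛ ← (φₛ + c·φ_g)/(1+c) with θ adjusted per sample reproduces every
sample's read distribution *exactly*, so the likelihood is flat along that
ridge and only the priors pick a point on it (empirically the fitted
generalist weight then lands around 0.21 rather than 0.3). Generalist-poor
samples make the blend infeasible (θ would go negative), pinning the true
decomposition; they also mirror the person-to-person variability of
generalist abundance seen in real cohorts.

Functional profiles are drawn from the *same* θ with per-assemblage KO
loadings: designated butyrate KOs carry 0.30 total mass in the generalist
and 0.02 elsewhere (15× ratio), and the remaining mass is an independent
Dirichlet draw per assemblage, so functional LDA can recover and match the
assemblages. Counts rows always sum exactly to the configured read depth,
and everything is deterministic given the seed.

What the generator does **not** emulate: sequencing error, zero-inflation
beyond multinomial sampling, phylogenetic correlation among genera, overlap
between signature genera, or real-cohort effect sizes. Passing tests
therefore demonstrate correctness of the algorithms under the model's own
assumptions and the stated qualitative structure — not reproduction of any
real cohort's numbers (Table-style probabilities, real median entropies, or
per-country patterns), which require external data out of scope here.

## Numerical choices and test scales

- Digamma-based updates act on strictly positive arguments by construction;
  hyperparameters are floored at 1e-10 (with a warning) if a fixed point
  ever steps non-positive.
- ψ⁻¹ uses Minka's initialization plus five Newton steps.
- Equal-VLB restarts and equal-silhouette trials resolve to the lowest
  seed; argmin/argmax ties resolve to the first (lowest) index everywhere.
- BH adjustment is the step-up minimum, capped at 1; it is order-invariant
  and monotone.
- Test problem sizes are chosen to make the statistical checks decisive yet
  quick: recovery uses N = 300, D = 50, 5,000 reads/sample, 10 restarts
  (total-variation error on φ ≲ 0.01 in practice against a 0.10 bound);
  bound checks enumerate 2×2 corpora with ≤ 4 reads/sample; normalization
  invariance uses N = 150, D = 40 with 3 restarts; the bound-validity check
  runs 80 iterations per tiny corpus (the bound holds at every iterate, and
  the empirical-Bayes α diverges on such degenerate corpora, so running
  longer only drifts the hyperparameters).

## Known limitations

- Variational bounds, not exact posteriors; posterior means inherit the
  mean-field factorization bias.
- Empirical-Bayes α can diverge on corpora with very few samples; the
  iteration cap bounds the damage but such fits should not be interpreted.
- Model selection for K is left to the analyst (best-VLB per K is reported;
  interpretability decides).
- PAM is a local optimizer; restarts mitigate but do not guarantee global
  optima on hard instances.
- The KO→category map must be single-category per KO.
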