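# Methods

`kronfuse` predicts whether a cancer cell line is *sensitive* or *resistant*
to a compound by fusing heterogeneous similarity views of both sides of the
(cell, drug) pair and learning the relationship with a class-weighted SVM on
a Kronecker-product pairwise kernel.

## Model

Each cell line is described by up to three genomic views, each drug by up to
three chemical/therapeutic views, and each view is reduced to a similarity
matrix over its entity set:

| matrix | entities | construction |
|---|---|---|
| S_Mut | cells | weighted cosine over binary oncogene-mutation profiles |
| S_CN  | cells | Gaussian kernel on gene-level copy-number profiles |
| S_GE  | cells | absolute Pearson correlation of expression profiles |
| S_Chem | drugs | Gaussian kernel on molecular-descriptor vectors |
| S_Target | drugs | max normalized Smith–Waterman over target-protein sets |
| S_ATC | drugs | hierarchy-aware similarity over ATC code sets |

Fusion is the element-wise maximum, `Comb_c = max(S_Mut, S_CN, S_GE)` and
`Comb_d = max(S_Chem, S_Target, S_ATC)`: two entities are treated as similar
if *any* single view says they are. Each pair of matrices defines the
pairwise kernel

    K((c, d), (c', d')) = S_cell(c, c') * S_drug(d, d')

so two (cell, drug) pairs are similar only when cell and drug are
simultaneously similar. The kernel is kept factorized; Gram blocks are
products of sub-blocks of the two factors and the full Kronecker matrix is
never materialized.

Continuous responses (IC50 by default) are categorized into +1 (sensitive,
value ≤ 0.5 on the truncated [0, 8] scale), −1 (resistant, value ≥ 7.5) and
0 (unknown); unmeasured pairs are kept distinct from unknown. A soft-margin
SVM with the precomputed pair Gram is trained on labeled pairs, with class
weights n_total / (2 · n_class) to counter the typical ~3:1 excess of
resistant associations.

### Mutation weights

The per-gene weight is w_k = exp(−f_k / (h·σ_f)), with f_k the gene's
mutation rate across cells, σ_f the standard deviation of the rates
(replaced by 1 when the rates are constant) and h = 10. This is a monotone
inverse-frequency weighting: ubiquitously mutated genes contribute less to
cosine similarity than rare, informative ones. A `uniform` scheme (plain
cosine) is available as an escape hatch.

### Gaussian bandwidth

Wherever a Gaussian kernel is used (copy number, descriptors,
response-profile similarity) the default bandwidth is the self-tuning rule
γ = 1 / mean‖x − x′‖² over all distinct pairs, so exp(−γd²) has mean
argument −1; a fixed γ may be supplied. Copy-number and descriptor features
are z-scored per feature first (descriptor scales are wildly heterogeneous);
expression is not, since Pearson correlation is already scale-free. Missing
feature values are mean-imputed per feature before distances; Pearson uses
pairwise-complete features.

### ATC similarity

Codes are parsed into the 5-level WHO hierarchy. The distance between two
codes is the shortest path in the tree, with codes whose level-1 letters
differ connected through a virtual root (+2 edges). Every observed prefix
gets an inverse-frequency weight normalized to max 1, so rare (specific)
prefixes weigh more. A code pair scores ρ^d · ω(deepest shared prefix) with
ρ = 0.25; a drug pair takes the maximum over its code sets, normalized by
the geometric mean of the two self-scores so identical code sets score
exactly 1. The algebraic form (geometric-mean self-normalization, maximum
aggregation over code sets mirroring the target-set maximum) is this
package's design; it uses exactly the stated ingredients — tree distance,
inverse-frequency weights, ρ — rewards sharing of specific codes, and keeps
cross-branch similarities positive but tiny.

### Alignment scoring

Target-protein similarity is SW(a,b)/√(SW(a,a)·SW(b,b)) with local
alignment under BLOSUM62, affine gaps 11/1 (the modern default);
`AlignmentConfig.matlab()` (BLOSUM50, linear gap 8) mimics older toolbox
defaults. Drugs sharing a target protein score 1 without alignment.

### PSD repair

Max-combination and |PCC| can break positive semidefiniteness, so each
kernel factor is repaired once before learning: eigenvalues are clipped at
zero, the matrix reconstructed, and the diagonal rescaled to 1. The
Kronecker product of PSD factors is PSD, so the pair Gram is then safe for
the solver. `psd_mode="none"` disables this.

## Evaluation protocol

Outer 10-fold stratified cross-validation over labeled pairs (options:
leave-cell-out / leave-drug-out group folds for the "new cell / new drug"
settings). The penalty C is chosen by 3-fold inner-CV AUC inside training
data only; ties break toward smaller C. AUC is trapezoidal (equals the
normalized Mann–Whitney statistic); AUPR is step-wise average precision,
which avoids the optimism of trapezoidal PR interpolation.

Decision values from different folds are on different scales — the margin
and intercept shrink with C — so pooling raw values across folds can
understate AUC badly at small C even when every per-fold AUC is high. Test
scores are therefore standardized within each fold before pooling; this is
monotone within a fold, leaving per-fold metrics untouched, and makes the
pooled ranking scale-free. Raw signed values are retained for sign-threshold
class predictions (recall, etc.).

Tissue-stratified metrics recompute AUC/AUPR on the pooled out-of-fold
scores of pairs whose cell carries each tissue label. The feature–response
correlation analysis builds a Gaussian similarity over response profiles
(per-shared-position mean squared distance, so profiles with different
missingness are comparable), correlates its upper triangle with each
feature-similarity matrix, bins pairs into feature-similarity tertiles and
Welch-tests adjacent bins.

## Synthetic data

The generator emulates the shape of a drug-screening release: 120 cells ×
20 drugs by default, 4 latent clusters per side, visible noisily in every
view (25 binary mutation genes with cluster signatures, 200 copy-number and
300 expression features as cluster means + unit Gaussian noise, 50
descriptors likewise; per drug-cluster one ancestor protein of length 300
with 5% per-drug point mutations; one level-4 ATC prefix per cluster with
distinct leaves). Sensitivity is block-structured: P(sensitive) is 0.9 on
the anti-diagonal cell-cluster × drug-cluster blocks and 0.1 elsewhere, so
neither side alone separates the classes. IC50-like values sit near 0.2
(sensitive) / 7.8 (resistant) with sd 0.15, truncated to [0, 8]; 20% of
entries are shifted into the uninformative middle band. All draws come from
child generators of one seed, so the cell-side draw is invariant to the drug
count. Tissues are assigned independently of clusters.

What the generator does *not* emulate: dose–response curve shape, realistic
descriptor physics or correlated measurement error; passing tests therefore
demonstrate correct mechanics and recoverable planted structure, not
real-data performance.

**A note on the attainable AUC.** Because labels are Bernoulli draws given
the cluster blocks, the best possible ranking is the two-level block
posterior; with blocks 0.9/0.1 and a quarter of pairs in high blocks, the
pooled AUC of an oracle is ≈ 0.857 and AUPR ≈ 0.77. The fused kernel
reaches this ceiling (≈ 0.856 at the default seed), i.e. the model recovers
essentially all recoverable structure; higher absolute numbers would require
more deterministic blocks, not a better model.

## Problem sizes and numerics

Default experiment sizes (120 × 20 bundle, ~1,850 labeled pairs; the
imbalance study at 80 × 16 with one weak sensitive block p = 0.7 over
background 0.03, ≈ 14:1 class ratio) keep the full evaluation — grid
search, 16-combination ablation, tissue stratification — around a minute on
one CPU. SVC tolerance is 1e-3; decision values are reproducible to 1e-6
across runs with a fixed seed, and serialized models reproduce them
bit-identically. Degenerate inputs are handled by convention rather than
NaN: all-zero mutation profiles and codeless/targetless drugs get 0
off-diagonal similarity (flagged unavailable), zero-variance expression
rows get 0, and pairs sharing no available source after union alignment get
0 with a warning.

## Known limitations

- The exact published forms of the mutation-weight and ATC-code formulas,
  and the Gaussian bandwidths used on real screening data, are not
  recoverable; the defaults here are committed, documented choices exposed
  in configuration.
- Amax/ActArea categorization cuts are dataset-dependent; only quantile
  mode and explicit thresholds are offered, no built-in cuts.
- No multiple-kernel learning: fusion weights are not optimized, by design
  (the maximum rule is the model).
- Unknown-pair ranking quality is assessed against planted truth only.
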