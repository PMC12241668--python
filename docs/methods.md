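# Methods

## Scope and model

`lactoscore` quantifies the activity of a gene signature (canonically a
curated set of lactylation-related genes) in every cell of a count matrix,
stratifies cells by that activity, and identifies genes associated with the
high-activity state. The central modeling assumption is that a cell's
signature activity is monotone in the within-cell expression ranks of the
signature genes; four of the five scorers are therefore pure rank
statistics, invariant under any strictly increasing transformation of a
cell's expression vector, and the fifth (the module score) controls for
expression level by bin-matched background subtraction.

## Scorers

All scorers receive dense average ranks by descending expression (rank 1 =
highest; ties get the average of the ranks they span, which makes every
scorer deterministic — implementations that break ties randomly trade
reproducibility for nothing we need here).

- **Recovery-curve area** (AUCell-style). H(x) counts signature genes at
  rank ≤ x; the score is Σ_{x=1..k} H(x) normalized by its maximum
  Σ_{x=1..k} min(x, n_s), with k = ⌈0.05·N⌉ by default. It is 1 exactly
  when the signature occupies the top n_s ranks and 0 when no signature
  gene is within the top k. With tied (fractional) ranks a gene counts from
  the next integer rank upward.
- **Rank-U statistic** (UCell-style). Signature ranks are capped at
  r_max + 1 (default r_max = 1500), U = Σ capped − n_s(n_s+1)/2, and the
  score 1 − U/(n_s·r_max) is clipped to [0,1]. The cap bounds the penalty a
  single undetected gene can impose in sparse cells.
- **Normalized mean rank** (singscore-style). The signature's mean
  ascending rank, linearly rescaled between its theoretical minimum (set at
  the bottom ranks) and maximum (set at the top).
- **ssGSEA**. Walking genes from most to least expressed, signature genes
  add (N − r + 1)^α normalized by the signature's total weight (α = 0.25)
  and others subtract 1/(N − n_s); the score integrates the running sum
  over all N steps. No cross-cell normalization is applied — the consensus
  stage's min-max rescaling absorbs scale.
- **Module score**. Genes are placed in 24 equal-count bins of mean
  expression; each signature gene draws 100 control genes from its bin
  (without replacement when possible, seeded), and the score is mean
  signature expression minus mean control expression per cell.

Defaults (5% rank cutoff, r_max 1500, α 0.25, 24 bins / 100 controls)
follow the scorers' canonical descriptions; all are exposed in
`ScoringParams`. Signature members are matched to the matrix by exact,
case-sensitive string comparison; the matched fraction is reported and a
fraction below 0.5 raises a prominent warning, since silent case-folding
corrupts gene-symbol spaces.

## Consensus and state assignment

Each scorer's per-cell vector is min-max normalized to [0,1] (a constant
vector maps to 0.5 with a warning); the consensus is the unweighted mean
over non-missing methods (a median option is exposed — the fusion rule is a
genuinely open choice, and the mean is the least structured one). States
come from the consensus distribution's quartiles with strict inequalities:
LLS below the 25th percentile, LHS above the 75th, LDTS between. The
quantile convention is fixed as order statistics — q25 is the
(⌊n/4⌋+1)-th smallest value, q75 the ⌈3n/4⌉-th — so that with all-distinct
scores exactly ⌊n/4⌋ cells fall below q25 and n − ⌈3n/4⌉ above q75 (n/4
each when 4 | n), on every platform. Boundary ties land in LDTS; fewer than
8 scored cells is an error (quartiles are meaningless); an all-tied
consensus yields 100% LDTS with a warning. Spatial spots run through the
identical machinery, joined back to their coordinates.

## QC and preprocessing

Genes detected in fewer than 5 cells are removed; cells must have 200–7000
detected genes (inclusive) and at most 20% mitochondrial counts (strictly
above is removed; "MT-" prefix). The gene filter precedes the cell filters,
and the pair is iterated to a fixpoint so the operation is idempotent —
removing cells can push genes back under the prevalence threshold, and a
single pass would leave the output dependent on how often you ran it.
Normalization is per-cell scaling to 10,000 counts followed by ln(1+x).
HVGs are the top 2000 genes by binned standardized dispersion in the
classic Seurat-v1 sense: variance/mean computed on the de-logged scale,
z-scored within 20 equal-count bins of mean expression (on the log scale
the variance of highly expressed genes is compressed and genuinely variable
genes sink), ties broken lexicographically. PCA standardizes genes and
fixes each component's sign so its largest-magnitude loading is positive;
clustering is Leiden on a 15-NN graph of the 20-PC embedding at resolution
0.8, delegated to igraph/leidenalg, with labels renumbered by descending
cluster size. Cluster markers are positive-only: Wilcoxon rank-sum
group-vs-rest with p < 0.01 and log2FC > 0.25, where log2FC is the
pseudocounted ratio of de-logged means.

## Differential expression and ORA

The LHS-vs-LLS contrast uses the two-sided Wilcoxon rank-sum test per gene
— exact enumeration when both groups have ≤ 10 tie-free observations,
otherwise the tie-corrected normal approximation — with BH adjustment over
all tested genes. The filter applies the raw p (< 0.01) and |log2FC| >
0.25 in both directions; adjusted p is reported alongside, since protocols
in this area commonly filter on raw p while readers want the FDR.
Over-representation is the upper-tail hypergeometric test of the
query/set overlap within an explicit background (default: all genes
surviving QC), BH-adjusted across sets.

## Co-expression modules

Counts are aggregated into metacells — greedy k-nearest-neighbor pooling
(k = 25) in the PCA embedding, each cell used at most once, yielding
⌊n/k⌋ metacells — to de-sparsify correlation estimates. The network is
unsigned: a_ij = |pearson|^β with the soft power chosen as the smallest
β ∈ 1..20 whose scale-free fit R² ≥ 0.8 (sign-corrected: a positive slope
of log p(k) vs log k disqualifies), falling back to the argmax with a
warning; β = 12 is the parameter default when a caller fixes it directly.
The topological overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij)
is clustered by average linkage on 1 − TOM with a static cut at 0.995 of
the tallest merge; clusters under 30 genes pool into "grey". A static cut
replaces the dynamic hybrid tree cut deliberately: it preserves the
pipeline's semantics with a small, fully testable core, and the cut height
is exposed. Module labels follow the standard color sequence by descending
size. Eigengenes are the first principal component of the module's
standardized expression, sign-fixed to correlate positively with the
module's mean expression; kME is the signed Pearson correlation of every
gene with every eigengene (signed, so hub ranking respects direction), and
hubs are the top 25 members by kME. Module-state association is a
Kruskal-Wallis test of each eigengene across the three states,
BH-adjusted; "LHS-associated" modules are significant ones whose mean
eigengene peaks in LHS.

## Feature selection

The cohort carries both a binary label and (time, event) survival data:
univariate Cox uses the survival outcome and the other four classify the
label — the only reading under which all five algorithms apply to one
cohort. LASSO is L1-logistic on standardized expression with λ chosen at
the minimum cross-validated deviance, the per-repeat λ averaged in log
space over repeated 10-fold CV (10 repeats at library default, 3 in the
demo pipeline to keep its wall time in minutes). The Cox solver is a
one-covariate Newton-Raphson on the Breslow partial likelihood, iterated to
gradient < 1e-8, with Wald p-values; it is validated against lifelines in
the tests and used only as implemented here in the pipeline. Random-forest
importance is Breiman's out-of-bag permutation importance computed on a
hand-rolled bootstrap ensemble of CART trees (500 by default): each tree's
OOB accuracy drop is evaluated only for features the tree actually splits
on (others contribute an exact zero). Boruta appends an independently
shuffled shadow copy of every feature each iteration, scores a hit when a
real feature's importance exceeds the best shadow, and decides
confirm/reject by a two-sided binomial test of hits against 0.5 with
Bonferroni correction over the undecided features (α = 0.01, ≥ 5
iterations before testing, 100 max); its internal ensemble uses 150 trees
per iteration — importance enters Boruta only through the
exceeds-best-shadow indicator, which is far less noise-sensitive than the
importance values themselves. XGBoost ranks features by total gain and
selects those above the mean gain (a top-k rule is exposed). The hub list
is the strict intersection of the five selections; all pairwise and
leave-one-out intersections are emitted for diagnosis.

## Synthetic data

The generators define the study conditions; they are deliberately simple
and fully seeded (one global seed feeds named substreams, so adding an
output never perturbs an existing one).

- **Single-cell counts**: negative binomial with var = m + φm² (φ = 0.5),
  log-normal gene baselines, mild log-normal library-size variation, 4
  cell types over-expressing disjoint 30-gene marker blocks 4-fold, 10
  "MT-" genes filling a per-cell mitochondrial share drawn uniform from
  (0.02, 0.15), and a planted 25% of cells multiplying the 50-gene
  signature by fold 4. Signature baselines draw from a moderate-expression
  distribution (log-normal, median 1 count) — signature genes of a
  metabolic program are not rare transcripts, and a fold planted on a
  near-zero mean would be censored by dropout rather than present in the
  data.
- **Modular expression**: x = √ρ·z_module + √(1−ρ)·ε per module (Gaussian,
  shifted into positive range), giving within-module Pearson r ≈ ρ and ≈ 0
  elsewhere.
- **Cohort**: standard-normal expression; label log-odds and survival
  log-hazard are both `effect_size` × the sum of the informative genes
  (default 3 genes at 1.5 SD, n = 500); censoring is an independent
  exponential whose rate targets the configured expected censoring
  fraction.
- **Spatial**: a √n × √n spot grid whose central square (≈ 25% of spots)
  over-expresses the signature by the configured fold.

What the generators do **not** emulate: dropout beyond NB sampling,
doublets, ambient RNA, batch effects, gene-length/GC biases, realistic
gene-gene correlation outside the planted blocks, or non-proportional
hazards. Passing tests therefore demonstrate correctness of the algorithms
and recoverability of planted signal under idealized noise — not
performance on real tissue.

## Numerical choices and problem sizes

Ties: average ranks everywhere. Degenerate inputs: constant score vectors
normalize to 0.5; all-tied consensus → all LDTS; zero-matched signatures
propagate missing scores; zero-variance genes are skipped in
standardization (unit divisor). Quantiles: the order-statistic convention
above, chosen for exact reproducibility. The demo pipeline runs 2000 cells
× 3000 genes, builds the network on the top 1000 HVGs, and uses 3 LASSO CV
repeats; these sizes keep a full end-to-end run at minutes on a single
core while leaving every recovery property measurable. The acceptance
script uses the same sizes.

## Known limitations

The consensus fusion rule (mean) and the choice of which modules feed the
candidate pool are heuristics exposed as parameters, not derived from a
model. The scale-free criterion can be indecisive on small metacell counts
(the fallback picks the best-fitting power and warns). The static tree cut
will merge adjacent modules that a dynamic cut would split. Cluster-level
annotation of cell types is intentionally out of scope — marker dictionaries
are user input.
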