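# lactoscore

Consensus gene-set activity scoring and lactylation-state analysis for
single-cell, spatial and bulk transcriptomics.

Lactate accumulation in tumors drives lactylation, a post-translational
modification increasingly implicated in glioblastoma biology. Because no
single-cell assay measures lactylation directly, its activity is proxied by
the transcriptional activity of a curated lactylation-related gene set.
`lactoscore` implements the full discovery pipeline around that idea, for
researchers who want to stratify cells by the activity of any signature and
find the genes that track it:

1. **Five independent per-cell scorers** of a signature *S* in a cell with
   gene ranks *r* (rank 1 = highest expression, average ranks for ties):
   - *AUCell-style recovery-curve area*: with H(x) = |{g ∈ S : r_g ≤ x}| and
     k = ⌈0.05·N⌉, score = Σ_{x=1..k} H(x) / Σ_{x=1..k} min(x, |S|).
   - *UCell-style U statistic*: U = Σ_{g∈S} min(r_g, r_max+1) − |S|(|S|+1)/2,
     score = 1 − U/(|S|·r_max), r_max = 1500.
   - *singscore-style mean rank*: the signature's mean ascending rank,
     rescaled to [0,1] over its achievable range.
   - *ssGSEA*: integrated rank-weighted running sum over the full ranking
     (weights (N−r+1)^α, α = 0.25).
   - *Module score*: mean signature expression minus the mean of
     expression-bin-matched control genes (24 bins, 100 controls/gene).
2. **Consensus and states**: each scorer is min-max normalized to [0,1]; the
   per-cell consensus is their mean. Cells below the consensus 25th
   percentile form the low lactylation state (LLS), above the 75th the high
   state (LHS), and the interquartile middle the dynamic transition state
   (LDTS). The same machinery applies unchanged to spatial spots.
3. **State-associated genes**: Wilcoxon rank-sum DE between LHS and LLS
   (p < 0.01, |log2FC| > 0.25), intersected with the gene content of
   co-expression modules whose eigengenes peak in LHS. Modules come from a
   WGCNA-style core: metacell aggregation, soft-thresholded |r|^β adjacency
   (scale-free fit), topological overlap, average-linkage tree cut,
   eigengenes and kME hubs.
4. **Hub genes**: five feature-selection algorithms on a labeled survival
   cohort restricted to the candidates — LASSO-logistic (CV-minimum λ),
   univariate Cox (p < 0.05), random forest (top 20 by out-of-bag
   permutation importance), Boruta (shadow-feature binomial test) and
   XGBoost (mean-gain rule) — intersected into the final hub list.

Every stage is exercisable on synthetic data with planted ground truth
(negative-binomial counts with cell types, mitochondrial genes and a planted
high-activity subpopulation; block-correlated modules; cohorts with planted
prognostic genes; spot grids with a planted region), so the whole pipeline
is testable without any download.

## Worked example

The `analysis/` scripts run the whole study on synthetic data. With the
shipped defaults (2000 cells × 3000 genes, 50-gene signature at fold 4 in a
planted 25% of cells):

```bash
python analysis/01_simulate_data.py
python analysis/02_qc_cluster.py
python analysis/03_score_states.py
python analysis/04_state_de.py
python analysis/05_coexpression_modules.py
python analysis/06_feature_selection.py
python analysis/07_spatial.py
```

prints, among other things:

```
QC: 2000 -> 1994 cells, 3000 -> 3000 genes
2000 HVGs, 20 PCs, 8 Leiden clusters at resolution 0.8
state composition: {'LDTS': 998, 'LLS': 498, 'LHS': 498}
planted-cell recall in LHS: 1.000
114 DEGs pass p<0.01 & |log2FC|>0.25 (52 up in LHS)
planted signature recovered as LHS-up: 100.0%
4 modules: {'turquoise': 138, 'blue': 100, 'brown': 59, 'yellow': 50}
LHS-associated modules: ['turquoise']
40 up-DEGs overlap LHS modules (40 of the planted signature)
five-way intersection: ['LACT0028', 'LACT0001', 'LACT0016']
intersection equals the planted informative genes: True
Jaccard(LHS spots, planted region) = 1.000
```

Read: the quartile rule puts exactly a quarter of cells in each extreme
state; the planted high-lactylation cells are fully recovered as LHS; the
LHS-vs-LLS contrast plus module overlap narrows 3000 genes to 40
candidates, and the five-algorithm intersection returns exactly the three
genes planted as informative in the cohort. The same consensus machinery
recovers the planted spatial region perfectly at fold 4.

The one-call equivalent is `lactoscore.pipeline.demo(seed)`, which runs
simulation through hub-gene selection into a single run directory with a
JSON manifest.

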