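# stressgwas

Stress-resistance phenomics scoring and mixed-model GWAS for microbial
strain collections.

Screening a collection of *Saccharomyces cerevisiae* strains across a panel
of stress conditions — each applied at several increasing inhibitory levels
— produces thousands of growth curves. `stressgwas` turns those curves into
two complementary resistance traits per strain and condition, ranks the
strains, associates the rankings with genetic variants under a mixed model
that controls for relatedness, decomposes the evidence by variant source,
and validates candidate gene lists on a protein-interaction network.
A synthetic-data module generates every input with known ground truth, so
the entire analysis runs and is testable offline.

## The method

**Growth parameters.** Five parameters are extracted from each curve:
lag time λ, maximum specific growth rate μmax (max slope of
ln(signal − blank) over a sliding regression window), amplitude A,
half-amplitude time t½, and area under the curve. Non-growing wells get
defined worst-case sentinels so every ranking is total.

**Performance and robustness.** At each inhibitory level, parameters are
oriented (time-like ones inverted) and min-max scaled across strains;
*performance* is the weighted sum Σₖ wₖ·x̃ₖ, averaged over levels.
*Robustness* measures retention: for each parameter the ratio of its value
at level ℓ ≥ 1 to its value at the least inhibitory level, clamped to
[0, 1] and averaged. Strains are ranked per condition and score type
(rank 1 = best, average ties), with decile ranking values 1–10.
Rank-variability analysis re-ranks under Dirichlet(1,…,1) weight samples;
parameter-influence (PI) scores record the rank change when one parameter
is up-weighted, normalized so the global extreme is ±1.

**Mixed-model GWAS.** Rankings are the phenotype (rank-based inverse-normal
transform by default). The model y = Xb + g + e with g ~ N(0, σ²g K) uses a
VanRaden genomic-relationship K; REML estimates of δ = σ²e/σ²g come from
the spectral one-dimensional form of the restricted likelihood (EMMA-style:
one eigendecomposition, then a grid search with local refinement). Markers
are tested by generalized least squares reusing the null variance
components (P3D/EMMAX default, exact per-marker re-estimation optional).
SNP/indel markers are restricted to core-genome regions with minor-allele
frequency > 5%, chained into LD blocks (r² ≥ 0.8 against the block
representative) and tested via the representative. CNV gain and loss
markers are binary presence vectors over the atomic segments induced by
event breakpoints. Significance cutoffs come from the departure of the
observed p-values from uniform QQ quantiles; gene p-values are the minimum
over units overlapping the gene plus its strand-aware 800 bp upstream
region.

**Downstream.** Per gene category and ranking, the 0.75 quantiles of
−log10 p per source (SNP/gain/loss) are normalized into barycentric
contribution coordinates. GWAS gene lists are mapped onto a
protein-interaction network: maximal cliques enriched for the list
(hypergeometric + Benjamini-Hochberg) are unioned into modules and
compared against equally sized random gene lists with a paired Wilcoxon
signed-rank test. Cohort comparisons use Wilcoxon rank-sum /
Kruskal-Wallis tests with BH FDR control, binning related strains (e.g. a
shared bioethanol lineage) to one pseudo-observation first.

## Worked example

```python
from stressgwas import synthio, growthio, resistance

strains = synthio.gen_strains(12, seed=7)
curves, truth = synthio.gen_growth_curves(
    strains, n_conditions=3, levels_per_condition=5,
    n_replicates=2, noise_sd=0.01, seed=7)
table = growthio.extract_table(growthio.curves_from_frame(curves), blank=0.075)
rankings = resistance.ranking_table(table)
print(resistance.top_frequency(rankings, k=3).head(5))
```

```
strain
S007    3
S011    2
S009    2
S006    2
S008    2
```

Strain S007 appears three times in the top 3 across the six rankings
(3 conditions × {performance, robustness}) — the summary used to order
strains by overall resistance. A single condition's robustness ranking
looks like:

```
strain    score  rank  ranking_value condition score_type
  S005 0.827765   1.0              1       C01 robustness
  S009 0.815398   2.0              2       C01 robustness
  S004 0.746871   3.0              3       C01 robustness
  S011 0.721260   4.0              4       C01 robustness
```

where `score` is the weighted mean retention in [0, 1], `rank` 1 is the
most robust strain, and `ranking_value` is the decile bin (values > 6 mark
poorly resistant strains).

The full pipeline (simulation through cohort statistics) runs from one
config:

```bash
stressgwas all --seed 1 --outdir run1          # or: python -m stressgwas
```

writing plain-text TSV/JSON artifacts (`rankings.tsv`, `association.tsv`,
`gene_pvalues.tsv`, `contributions.tsv`, `modules.tsv`, …), each stamped
with the configuration hash.

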