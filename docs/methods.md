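# Methods

This note documents the models, defaults and design choices behind
`stressgwas`, in the order the pipeline runs.

## Synthetic study conditions

The generators emulate a screen of a yeast strain collection: 36 strains
split 17 industrial / 13 environmental / 4 laboratory / 2 clinical
(largest-remainder allocation for other n, always covering all four
categories), 13 stress conditions, 4–7 inhibitory levels per condition
(drawn uniformly unless fixed), 2 replicate wells, monitored over a ~66 h
grid (default 0.5 h steps). Bioethanol strains are placed in Brazil and
share a `bin_group`, providing the related-lineage structure that cohort
tests collapse to a single pseudo-observation.

**Growth curves.** Each strain carries baseline parameters drawn once:
μ0 ~ U(0.25, 0.55) h⁻¹, λ0 ~ U(2, 6) h, A0 ~ U(0.8, 1.2) signal units,
instrument baseline ~ U(0.05, 0.10), inoculum y0 = 0.005·A0. These ranges
are typical of yeast microcultivation readouts. The trajectory is a
*lagged logistic*: flat at baseline + y0 until λ, then
y(t) = baseline + A / (1 + (A/y0 − 1)·e^(−μ(t−λ))). A pure logistic
parameterized by its midpoint has its maximal ln-slope at the start of
observation, so a tangent-based lag estimate is identically ~0 and a
planted lag could never be recovered; the lagged form keeps a closed-form
curve in the logistic family while making λ a well-defined, recoverable
quantity. Dose response is Hill-type per strain × condition:
retention f(d) = 1/(1 + (d/IC50)^h) with IC50 ~ U(1.5, L+1) in level units
and h ~ U(1.5, 3); μ and A scale by f, λ by 1/f. Wells whose amplitude
falls below the blank threshold (default 0.1) or whose lag exceeds the
observation window are flat ("no growth"), reproducing level-dependent
grower counts. Gaussian noise (default sd 0.01) is added and clipped at 0.

**Genotypes.** Balding–Nichols structure: ancestral frequency
p ~ U(0.1, 0.9), population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with
F = 0.2 over 3 populations by default; diploid dosages Binomial(2, p_pop).
The phenotype adds planted per-dosage marker effects, a polygenic term
MVN(0, σ²g·K) with K the realized genomic-relationship matrix (returned as
ground truth), and iid noise. Between-population allele-frequency
divergence follows the closed-form beta moments and is verified against
them in tests.

**CNV segments** are placed with a U-shaped Beta(0.5, 0.5) position bias
(subtelomeric-like), 3–40 kb long, with a configurable number of events
shared verbatim across random strain subsets so that overlap structure
exists for marker construction. **Genes** are non-overlapping spans with
strand, ORF class (verified/uncharacterized/dubious) and TF-superfamily
labels. **Networks** are Erdős–Rényi backgrounds with planted fully
connected cliques and STRING-like edge confidences; the foreground list
contains a stated fraction of each clique plus random background nodes.
**Metabolomes** are log-normal abundances (79 metabolites by default) with
group-level shifts for chosen strain subcategories and an intra/extra
compartment coupling (default −0.6) on centered log-abundances.

What the generators deliberately do not emulate: real genome sequences or
linkage maps, read-level noise, plate-position effects, metabolite
chemistry, or condition-specific pleiotropy. Passing tests therefore show
correctness of the algorithms and calibration under the stated statistical
structure, not performance on any particular real dataset.

## Growth-parameter extraction

Curves are median-smoothed (window 3; endpoints shrink the window).
μmax is the maximum slope of ln(signal − blank) over a sliding 5-point
least-squares window — 5 points balance noise suppression against slope
bias on ~15-min grids. λ is the Zwietering tangent construction: the
tangent at the μmax window intersected with the initial (baseline) level.
t½ is the first upward crossing of A/2 with linear interpolation; AUC is
the trapezoid of the blank-subtracted signal. `grew` is A ≥ min_amplitude
(default 0.1); non-growers get worst-case sentinels (λ = t½ = end of
observation, μmax = A = AUC = 0) rather than missing values so rankings
stay total. Replicates aggregate by per-field median with MAD dispersion;
grew is a majority vote with ties counting as grown. On noise-free curves
the extractor recovers μ and A within 2% and λ, t½ within 5% over a grid
of generator settings.

The identity of the five parameters is a configuration-level choice: the
scoring layer operates on any five-vector, so substituting a different
parameter set changes no code.

## Scoring and ranking

Min-max scaling within level (not z-scores) keeps scores in [0, 1] and is
robust at small n; a degenerate range among growers maps to 0.5, or 1.0
when non-growers are present at the level (the growers still dominate).
Robustness uses retention ratios against the least inhibitory level,
directly operationalizing "maintains its parameters as levels increase";
time-like parameters invert the ratio. Level integration is an unweighted
mean over usable levels (configurable weights provided). A consequence
worth knowing: a strain that collapses at high levels loses integrated
performance too, so "high performance / low robustness" patterns require
dominance at the levels where the strain grows.

Decile ranking values are ceil(10·rank/n); with 36 strains, values > 6
correspond to the bottom ~40% of the table. PI scores use baseline rank
minus bumped rank (default bump 0.25 before renormalization), so positive
means moving up the table; normalization divides by the global maximum
absolute raw score over all parameters and conditions.

## Mixed model

REML maximizes the restricted likelihood over δ = σ²e/σ²g in its spectral
form: with S the fixed-effect projector, the top n−q eigenpairs of
S(K + I)S give eigenvalues λᵢ + 1 and rotated residuals η, and
ℓ_R(δ) = ½[(n−q)(log((n−q)/2π) − 1 − log Σηᵢ²/(λᵢ+δ)) − Σlog(λᵢ+δ)].
The maximizer comes from a 100-point grid on log₁₀δ ∈ [−5, 5] plus bounded
refinement. For K = I the likelihood is flat in δ (only the total variance
is identified); this is reported with a warning. The spectral form matches
explicit-inverse evaluation to 1e−6 in tests.

Marker tests whiten with the Cholesky factor of K + δ̂I and run OLS on the
whitened design (Wald t, df = n − q − 1). P3D-style reuse of the null
components is the default: at strain-collection scale exact per-marker
re-estimation is affordable (and provided), but P3D matches common EMMA
practice and keeps scans O(markers). Rank phenotypes get a rank-based
inverse-normal transform by default ((r − 0.5)/n quantiles); raw-rank mode
is retained.

The QQ-departure cutoff walks the sorted p-values from the most
significant and keeps the longest prefix with
−log₁₀p_obs ≥ −log₁₀p_exp + ε (default ε = 0.5 decades, configurable);
the threshold is the largest p in the prefix, with a 0 sentinel when the
prefix is empty. Gene p-values take the minimum over overlapping units —
deliberately without multiplicity correction, since contiguous genes in a
significant block are expected "passengers" and the network-module stage
is the designated de-noiser.

## CNV markers and gene events

Loss markers pool loss (0 < copy < ploidy) and deletion (copy 0) events;
gain markers are separate. The genome is cut at the union of event
breakpoints; atomic segments carry presence vectors; adjacent segments
with identical vectors merge; constant vectors and markers with minor
class frequency < 0.05 are dropped. This equals a per-base brute-force
computation on randomized toy genomes (tested on 200 instances). Gene
assignment: full coverage confers the event; partial overlap confers
loss/deletion (a copy is truncated) but never gain (the extra copy is
incomplete); deletion > loss > gain when events conflict; same-event
segments are merged per strain before the coverage test.

## LD blocks and kinship

Blocks chain markers greedily left-to-right: a marker joins if it is
within 20 kb of the block's last member and has r² ≥ 0.8 with the current
representative (the highest-MAF member so far, ties leftmost). The exact
published blocking rule for the emulated study is not available; the
parameters are exposed in config. Kinship is the VanRaden GRM
(center by 2p̄, scale by 2Σp(1−p)), normalized to unit mean diagonal, with
tiny negative eigenvalues clipped. Note that sample-frequency centering
biases off-diagonals by −1/(n−1); the identity limit under independent
markers holds as both markers and strains grow.

## Modules and nulls

Module discovery enumerates maximal cliques exactly (networkx) — at
desk-scale networks exactness is feasible and is declared the reference
behavior; a seed-controlled sampling fallback exists for very large
graphs. Enrichment is hypergeometric against the score-filtered network's
node set (not the genome — this choice changes p-values and is stated
explicitly), BH-corrected across cliques; modules are connected components
of the union of significant cliques, so module nodes equal clique nodes
here (no connector insertion). The randomized null draws equally sized
node lists; each module statistic is compared real-vs-each-null with a
one-sided Wilcoxon signed-rank over the paired differences. With the
default 5 random lists the exact one-sided floor is 1/32, so strong claims
(p < 0.01) require ~20 or more lists; all-zero difference vectors report
p = 1, making the test conservative when nothing is discovered.

## Cohort statistics

Rank-sum tests use the exact null for small tie-free samples and the
tie-corrected normal approximation otherwise; Kruskal-Wallis is
tie-corrected with an all-tied guard (H = 0, p = 1). Correlation matrices
use Bonferroni by default (BH available) — the two adjustments are kept
distinct because families of pairwise correlations and families of group
tests have different sizes. Binned pseudo-observations use the member
median (mean optional). Metabolite group scores are mean signed z-scores
of log abundances within a pathway/class per strain, with a sign flag for
extracellular production-vs-consumption orientation.

## Numerical choices and degenerate inputs

Ratios guard denominators at 1e−12; p-values are floored at the smallest
positive float; −log₁₀0 is capped with a warning. All-blank curves,
all-non-growing levels, constant markers, empty CNV marker sets, empty
module sets and constant correlation features are handled as defined
results (sentinels, skips with counts, or NaN reported as missing), never
exceptions.

## Problem sizes used in validation

Acceptance-level checks run at: 5×5 noise-free (μ, A) recovery grids;
20-seed planted-ordering scoring checks (8 strains × 4 levels); a 5,000-
marker structured-null calibration at 120 strains with a 100-seed power
study (300 markers, 100 strains, 2-SD effect); 200 randomized ≤10 kb CNV
genomes; 100-node networks with a planted 8-clique and 20 random null
lists; and a full default-scale pipeline run (36 strains × 13 conditions).
These sizes were chosen to make every check a from-scratch computation a
workstation completes in well under a minute each.

## Known limitations

Rank phenotypes bound the information available to the mixed model; with
36-strain cohorts power exists only for large effects, mirroring the
screening setting. The QQ-departure rule is a heuristic threshold, not an
error-rate guarantee. Contribution coordinates depend on the chosen
quantile (default 0.75) and on whether normalization happens within or
across rankings (parameterized). The module null pairs real-vs-null per
statistic; other pairings are defensible and configurable.
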