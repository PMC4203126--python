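# Methods

This note records the models, parameter choices and numerical conventions
behind `embryoarray`, and what the synthetic planted-truth tests do and do
not demonstrate about real array data.

## Study design and the synthetic generator

The package targets the factorial design of a two-genotype somatic
embryogenesis time course: genotypes {WT, vtc2} × four stages
(bent-cotyledon zygotic embryo, D7I, D14I, mature somatic embryo) × two
biological replicates = 16 arrays, each transcript measured by a probe set
of 11 PM/MM pairs. All of this is configurable (`StudyDesign`); the
defaults are the conditions above, with a default transcriptome size of
22,810 probe sets (the ATH1-scale array) and 500–2,000 genes in tests and
the acceptance run, which exercise identical code at desk scale.

The generator's intensity model is deliberately the simplest one with the
right shape for array data:

- On the log2 scale, `log2 PM = μ_g(cell) + φ_i + ρ_a + ε`, where
  `μ_g(cell)` is the planted per-cell mean, `φ_i` a per-probe affinity
  shared across arrays (Gaussian, SD 0.7, median-centered exactly so
  that noise-free median polish returns `μ` itself), `ρ_a ~ N(0, 0.15)` a
  replicate effect, and `ε ~ N(0, 0.2)` probe-level noise. PM is therefore
  lognormal (multiplicative noise); gene-level fixtures use additive
  Gaussian noise on log2 values (SD 0.25) directly.
- MM = 0.3 × PM (times lognormal noise) for expressed transcripts;
  MM ≈ PM for planted-absent transcripts. This is what makes the
  discrimination scores informative or not, mirroring how absent
  transcripts behave on real arrays without modelling probe sequence.
- Planted baselines are Uniform(6, 10) log2 (absent: Uniform(2, 4));
  differential genes get a ±3 log2 shift in the mutant at one stage
  (the generator rejects planted effects below 1 log2 unit); pattern
  genes follow prototype profiles with Uniform(1, 2) amplitudes.

Dominant-pattern prototypes are placed by repulsion on the centered unit
sphere until all pairwise Pearson correlations fall below 0.5. The bound
is one-sided: strongly anticorrelated profiles are distinct patterns
(mirror-image regulation), and a two-sided bound is in fact infeasible for
nine patterns over four cells (Welch bound). For the end-to-end recovery
configuration the planted patterns are genotype-symmetric (the same stage
profile in both genotypes), which keeps the planted differential sets
exactly separable from pattern genes — pattern genes then have fold change
exactly 1 in every genotype contrast. The 13- and 9-pattern recovery
checks instead use free prototypes over the full 8- or 4-cell space, as
those pattern counts require.

Promoters are 1,000 bp of uniform-composition random sequence
(configurable); background promoters are rejection-sampled to contain no
match to any motif in the table, and planted sites are exact consensus
realizations, so zero-noise motif recovery is deterministic. Background GO
terms are stratified-proportionally sampled across the planted gene
groups: their overlap with any pattern's gene set sits at its expectation
by construction, making them non-enriched deterministically rather than
merely on average. What the generator does **not** emulate: probe-sequence
affinity (GC effects), spatial artifacts, correlated gene-gene noise,
non-uniform base composition, GO-term overlap structure, or PWM-strength
binding sites. Passing the planted-truth suite therefore shows the
pipeline implements its definitions correctly and is calibrated under
clean noise models — not that it is robust to every artifact of real
hybridization data.

## Preprocessing

RMA-style summarization is quantile normalization of PM across arrays
followed by per-probe-set median polish of log2(PM) (tolerance 1e-10, max
100 sweeps; per-sample value = overall + column effect). The
normal-exponential background-correction step of full RMA is omitted: at
gene level the analyses here act on ranks, fold changes of moderately-to-
highly expressed genes, and standardized profiles, none of which need a
background deconvolution on synthetic data; the omission is a documented
deviation from the full algorithm. Quantile normalization averages rank
means over ties so tied values stay tied; strict idempotence holds on
tie-free data.

Replicate QC reports Pearson r between the replicates of each genotype ×
stage cell (zero-variance replicates are flagged undefined rather than
propagating NaN). Sample clustering is average linkage on 1 − Pearson
distance over genes, with supports from a gene-resampling bootstrap
(ordinary bootstrap proportions; the multiscale "approximately unbiased"
correction is out of scope). Distance and linkage are conventional
defaults and configurable, since the upstream procedure does not pin them
down. Trees serialize to Newick with supports as internal-node labels.

## Detection calls

The detection analogue follows the classic scheme: discrimination scores
`R_i = (PM_i − MM_i)/(PM_i + MM_i)`, a one-sided Wilcoxon signed-rank test
of `median(R) > τ`, and thresholds τ = 0.015, α1 = 0.04, α2 = 0.06 (the
published defaults). The p-value is exact — the signed-rank null is
enumerated by a generating-polynomial convolution over doubled midranks —
for up to 25 informative pairs, with a tie-corrected, continuity-corrected
normal approximation beyond. Zeros are dropped (rank-0 convention); ties
get midranks. This is an analogue of the commercial implementation, not a
bit-exact clone of it; it is the test the scheme describes. Consensus
detection requires a P call in both replicates of a tissue.

## Differential testing

The two-class unpaired SAM statistic is used per stage (the screening
F-like multiclass variant is provided as `multiclass_sam_statistic`).
`s₀` defaults to the median of the gene-wise standard errors — with two
replicates per group the full percentile search is not meaningfully
estimable and the median is a standard simplification. With 2 + 2 arrays
the permutation null is all six balanced relabelings (including the
identity); FDR at a |d| threshold is the median null exceedance count over
the observed count, capped at 1, and a gene's q is the minimum FDR over
thresholds at or below its own |d| (monotone non-decreasing down the |d|
ranking). Because the null is tiny, q estimates are coarse (multiples of
1/6 granularity at the top); Benjamini–Hochberg on pooled permutation
p-values is reported alongside (`q_BH`) as the secondary estimator, and
either can drive selection. Genes with zero within-group variance and
s₀ = 0 get an infinite d, are flagged, and are excluded from the
permutation null. Fold change is computed on log2 means (a geometric-mean
ratio), reported signed, and the selection gate is `q < 0.05` with linear
`|FC| ≥ 2`, the fold bound inclusive.

## Dominant patterns

The expression filter removes genes whose mean linear value (2^log2
averaged over the replicates of each cell) is ≤ 30 in every cell; a
relative 1e-12 guard absorbs log/exp round-trip error at the boundary.
Clustering operates on replicate-averaged, per-gene z-standardized
profiles over the 8 (or, for a one-genotype run, 4) cells — 
standardization is an inference, made because Pearson-distance clustering
of unstandardized log2 levels would be dominated by baseline expression.

FANNY minimizes the Kaufman–Rousseeuw objective
`Σ_v (Σ_{ij} u_iv² u_jv² d_ij) / (2 Σ_j u_jv²)` with `d = 1 − r`. The
iteration is the classic inverse-gradient membership update with a
halving damper that guarantees a non-increasing objective; convergence is
a relative objective change below 1e-8 (max 500 iterations).
Initialization is deterministic given the seed: k seed objects by
farthest-point traversal, memberships inversely proportional to the
dissimilarity to each seed, plus a 5% seeded Dirichlet perturbation.
Plain random initialization was observed to strand the iteration in poor
local minima on well-separated data; the farthest-point start lands it in
the structured basin while the perturbation breaks symmetry on
structure-free data.

The membership threshold m = 0.44 is read as a core filter: a gene is
core for a cluster iff its membership is ≥ m and that cluster is its
argmax (ties to the lowest index). Alternative readings — m as the FANNY
membership exponent, or as a post-hoc assignment cutoff — are noted but
not implemented; the core reading is the one under which the published
workflow (cores → prototypes → merge → correlation-gated assignment) is
coherent. Prototypes are core means; merging is greedy
highest-correlation-first while r ≥ 0.90 (size-weighted prototype means,
provenance recorded). The merge threshold is genuinely unspecified
upstream ("significant similarity"); 0.90 is the default, it is exposed
in the config, and `merge_sensitivity_sweep` reports pattern counts
across thresholds. Final assignment sends each filtered gene to its
best-correlated merged prototype iff r ≥ 0.85; constant profiles are
flagged "undefined correlation" and left unassigned. All tie-breaks are
lowest-index and deterministic.

## Enrichment and modules

Over-representation is the upper-tail hypergeometric probability
P(X ≥ k) for k carriers in a set of n against K carriers among N
background genes, evaluated through the log-space-stable survival
function. The enriched flag uses raw p < 0.001 with no multiplicity
correction — that is the upstream rule, kept for fidelity — while
BH-adjusted values are always reported next to it. The background is all
genes on the (synthetic) array. Motif matching is exact IUPAC consensus
on both strands (a reverse-complement match counts at its forward-strand
position; a palindromic motif counts once per strand, twice per site; `N`
in a sequence never matches); PWM scoring is out of scope.

Module graphs contain one diamond node per motif enriched in the analyzed
gene set, octagon TF nodes for mapped TFs that are themselves members of
the set (genome-wide TF inclusion is available via
`require_tf_in_set=False`, since whether the upstream tool required the
TF to be co-regulated is not documented), circle gene nodes for set
members with ≥ 1 promoter match, and GO-term annotation nodes attached to
their member genes — annotation as nodes keeps the graph expressible in
SIF, and grouping is recoverable from the attribute file. Enriched motifs
with no mapped TF are kept and flagged orphan. Export is deterministic
(sorted nodes and edges), so rebuilding a module from the same inputs is
byte-identical, and the SIF round-trips to the same edge multiset.

## qPCR

2^−ΔΔCt with replicate Ct values averaged before differencing; the
replicate scatter of the target gene is combined across the two
conditions by the range method into fold bounds at ΔΔCt ∓ SD, reported
but not further propagated. Efficiency-corrected quantification is out of
scope.

## Pipeline and reproducibility

Stages run in a fixed order, each reading only upstream artifacts; all
floats are written with `%.17g` and read back with round-trip parsing, so
re-running a downstream stage alone reproduces its files byte-identically.
Every stage's randomness derives from the single config seed plus a fixed
per-stage offset. The manifest records the config, per-stage counts and
SHA-256 hashes of every output file. Config defaults equal the procedure's
stated thresholds (filter 30, K = 15, m = 0.44, assignment r = 0.85,
q < 0.05, |FC| ≥ 2, enrichment p < 0.001); `validate_config` range-checks
all of them and rejects unknown keys.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: 500 genes ×
16 arrays end-to-end, 520 genes for the 13-pattern recovery, 1,000 genes ×
50 null datasets for differential calibration, and 200 random gene sets
against 30 terms for enrichment calibration. These sizes give stable
statistics while keeping the whole suite fast; the code paths are
identical at full array scale, which only multiplies the gene dimension.

## Known limitations

- No CEL parsing and no background correction: input is a probe-level
  intensity table, and absolute expression values are not comparable to a
  full RMA pipeline's (ranks and contrasts are).
- The detection test is an analogue of the commercial call algorithm, not
  a reimplementation validated against it.
- q-values from a 6-relabeling null are coarse by construction.
- Bootstrap supports are plain proportions, which are known to be biased
  relative to multiscale-corrected values.
- Enrichment treats GO terms as flat gene sets (no ancestor propagation),
  and motif presence is binary consensus matching.
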