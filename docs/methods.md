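# Methods

This note documents the models and procedures implemented in `ommatidia`,
the parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## The synthetic retina generator

The generator (`simdata`) emulates droplet scRNA-seq of the adult fly eye.
It is first-class, tested code: its planted structure is the ground truth
against which every downstream stage is scored.

**Cell types and proportions.** Types are drawn multinomially. Default
proportions follow the anatomically expected per-ommatidium composition
(R1–6 30%, R7 5%, R8 5%, cone 20%, primary pigment 10%, secondary/tertiary
pigment 20%, of a 90% total because bristle cells are not counted),
renormalized and scaled by 0.97 to leave room for a 3% non-eye contaminant
(brain neurons and glia) so the QC removal stage has real work to do.

**Subtypes.** Within R7/R8 a cell is pale with probability
`pale_prob = 0.30`, otherwise yellow; a yellow R7 is dorsal-third
(co-expressing Rh3 and Rh4) with probability `dorsal3_frac = 0.15`; any
inner photoreceptor is reassigned to the dorsal-rim class (Rh3 + hth, no
other opsin) with probability `dra_frac = 0.02`. The DRA draw is
independent of the pale draw, so the pale fraction among non-DRA R8s is
exactly `pale_prob`. No census of dorsal-third or DRA capture rates
exists; those two defaults are small-but-detectable placeholders and are
exposed in the configuration.

**Counts.** Per-gene baseline means are log-normal (median e⁻¹);
negative-binomial counts arise as gamma–Poisson mixtures with per-gene
dispersion drawn from a gamma prior (shape 2, scale 1.5, floor 0.5) — the
standard overdispersion model for UMI counts — and a log-normal per-cell
size factor (σ = 0.3). Opsins follow the exclusivity table exactly in the
clean counts: ninaE only in R1–6 at mean 400 (the highest-mean gene, as in
real eye data), the R7/R8 opsins at mean 150 in their subtype (75 + 75 in
dorsal-third R7s). Panel genes (sens, pros, ct, Crys, w, Pdh,
santa-maria, wrapper, hth, Skeletor, fne, moody, repo) are planted in
their canonical types; sens and pros are deliberately weak (mean 1.0),
matching their weak expression in real R8/R7 clusters — this is what
leaves the opsins as the dominant axis separating inner-photoreceptor
subtypes, the central phenomenon the ablation experiment measures.

Three planted programs carry cell-type identity beyond the named genes:

- 20 exclusive markers per type for R1–6, cone, both pigment classes and
  the non-eye class, with baseline ≈ LogNormal(ln 0.07, 0.15) multiplied
  by `marker_fold = 8` in the home type. The baseline window is chosen so
  a fold-8 marker clears both screening gates: detection ≥ 0.25 at home
  and < 0.10 elsewhere (Class 1 at τ = 0.10).
- 20 *shared* inner-photoreceptor markers planted in both R7 and R8
  (recorded as `marker_of = "R7/8"`), mirroring the biology in which R7
  and R8 are transcriptionally close and share a marker repertoire; these
  are what `find_shared_pair_markers` should recover, and their presence
  (with no strong R7- or R8-exclusive program besides opsins and
  pros/sens) is what lets R7 and R8 mix once all four inner opsins are
  ablated.
- a 15-gene high-expression photoreceptor program (phototransduction and
  structural genes, mean ≈ 15) shared by R1–8, mirroring the many
  photoreceptor-generic (Class 3) markers of real data; it keeps R1–6
  separable from pigment/cone after ninaE ablation.

**Noise.** The ambient soup profile is the clean dataset-wide expression
profile (hence ninaE-dominated). Per cell, ρ ~ Beta(mean 0.05,
concentration 50); a Binomial(N, ρ) subset of the cell's molecules is
*replaced* by multinomial soup draws, so library sizes are conserved and ρ
is interpretable as the contaminated fraction. Mitochondrial counts are
added to hit a Beta-distributed target fraction (mean 0.08). One percent
of cells become doublets by adding a random partner's profile. Library
sizes are binomially thinned per timepoint by `depth_decline = (1, 1,
0.6)`, reproducing the depth decline of aged samples in the third
timepoint.

**What the generator does not emulate.** Gene–gene correlation beyond
shared type programs; bristle cells; spatial structure; empty droplets
(the soup is estimated from the expression profile, not from empty
barcodes); cell-type capture biases (so the pipeline's pale:yellow ratio
should match 30:70, unlike real captures where pale R8s are depleted).
Tests passing on this generator show the machinery is correct and
calibrated, not that real data meet its assumptions.

## QC

"Between 200 and 3500 genes" is implemented inclusively; "mitochondrial
percentage < 20%" strictly — following the wording of the thresholds the
analysis mirrors (the four published threshold sets are shipped in
`iocore.PUBLISHED_THRESHOLDS`). Non-eye removal operates at cluster
level: a cluster is dropped when fne, moody or repo is detected in ≥ 50%
of its cells; the 0.5 operationalizes a by-eye FeaturePlot call and is
configurable.

## Ambient correction

The soup profile is s_g = column sums / grand total. The contamination
fraction of cluster k is estimated from forbidden genes F_k — genes the
cluster's annotated cell type cannot transcribe (opsin exclusivity):

ρ̂_k = Σ_{c∈k} Σ_{g∈F_k} x_cg / (Σ_{c∈k} N_c · Σ_{g∈F_k} s_g),

clipped to [0, 0.5]; clusters whose forbidden genes carry no soup mass are
flagged unusable rather than silently zero. The forbidden map is derived
from the cluster annotation (R1–6 forbids Rh3–6; a pale R8 cluster forbids
ninaE, Rh3, Rh4 and Rh6; pigment and cone clusters forbid all five
opsins; dorsal-third and DRA clusters exempt the opsins they genuinely
express).

Correction is performed at cluster level: for each (cluster, gene) the
expected soup E = ρ̂_k · N_k · s_g is stochastically rounded (seeded, so
integral without systematic bias), capped at the observed total, and the
removed counts are allocated to the cluster's cells by a multivariate
hypergeometric draw weighted by each cell's observed counts. A per-cell
independent subtraction was considered and rejected: for a gene whose
per-cell soup expectation is ≈ 0.2 counts, independent rounding removes
almost nothing from the cells that actually carry the soup counts, while
cluster-level removal takes out essentially all of the forbidden signal
(second-pass removal is under 10% of the first). Entries never increase
and never go negative.

## Clustering

Expression is log CP10K: y = ln(1 + 10⁴ x / N). Highly variable genes are
ranked by standardized variance: per-gene standardized counts
(x − m)/sd_trend with sd_trend from a degree-2 polynomial fit of log10
variance on log10 mean, clipped at √n_cells, then ranked by the variance
of the clipped values. The √n clip matters: clipping counts at
mean + 3·sd_trend instead would cap rare strong markers (the opsins) at
the trend and push them to the bottom of the ranking.

PCA (default 50 components) is computed on NB Pearson residuals of the
HVG counts, (x − μ̂)/√(μ̂ + μ̂²/θ) with μ̂ = N_c s_g and fixed θ = 10
(overdispersion 0.1), clipped at √n. The residuals are deliberately *not*
rescaled to unit variance: genes with strong bimodal structure — above
all the opsins — then dominate the leading components, as they do under
an SCTransform-style workflow. A classic per-gene z-score (clip ±10) is
available via `pca_scale="zscore"`, but it equalizes every gene's weight,
which provably buries single-gene subtype structure below the
random-matrix noise floor of the retained components: under z-scoring the
baseline pale/yellow mixing index drops from ≈ 0.98 to ≈ 0.2 and the
subtype clusters never separate. Component signs are fixed (largest
loading positive) for reproducibility.

The SNN graph uses k = 20 Euclidean nearest neighbours in PC space,
neighbour sets including the cell itself, Jaccard edge weights, and edges
pruned at ≤ 1/15 — the defaults of the workflow family this pipeline
mirrors. Communities come from Leiden (RB-configuration modularity,
resolution 0.8, seeded; the resolution the original analysis used is not
recorded, so the family default is exposed in the configuration). UMAP is
seeded and used for reporting only; no statistic depends on it.

Annotation scores each cluster against marker panels (R8: Rh5/Rh6/sens;
R7: Rh3/Rh4/pros; R1–6: ninaE; cone: ct/Crys; primary pigment:
wrapper/Pdh; secondary/tertiary pigment: santa-maria/w/Pdh) as the mean
of cluster-mean expression z-scored across clusters; ties yield
"ambiguous", never a silent pick. R7/R8 subtype is pale or yellow by the
dominant opsin; dorsal-third and DRA flags use detection fractions
(≥ 0.5 on the co-expressed genes, < 0.1 on the excluded opsins).

## Marker screen

One-vs-rest Wilcoxon rank-sum on log CP10K with the tie-corrected normal
approximation, or full enumeration (midranks, two-sided by distance from
the null mean of U) when both groups have ≤ 10 cells — the enumeration is
verified against brute force for all group sizes up to 8. Gates follow
the FindAllMarkers convention: positive only, detection ≥ 0.25 in either
group, log2((mean CP10K + 1) ratio) ≥ 0.25; the pseudocount-1 fold change
is the Seurat-family convention. Bonferroni is applied within each
cluster's tested set (the convention of the workflow mirrored here); BH
is used only for gene-set over-representation.

"Expressed in a cluster" means detection fraction ≥ τ = 0.10, an
operationalization of a by-eye FeaturePlot call; τ is exposed and swept
in tests. "Ubiquitous" means expressed in *all* evaluated clusters.
Candidates not expressed in their own home cluster are flagged
`not_expressed` as an anomaly rather than dropped silently.

## Ablation experiment

Counts for a gene set are deleted, the full normalize → HVG → PCA → SNN →
Leiden stack is re-run with identical parameters and seed (HVGs are
re-selected after removal), and reference labels are transferred by
barcode, never re-inferred. Two statistics quantify what UMAP plots show
qualitatively, both computed in PC space rather than the 2-D embedding to
avoid embedding artifacts:

- mixing index M for a class pair (A, B): restrict to A ∪ B, take each
  cell's fraction of same-label k = 20 nearest neighbours, average to
  S_obs, and normalize against random mixing, M = (S_obs − S_null)/(1 −
  S_null) with S_null = p_A² + p_B². M is symmetric in the pair,
  rotation-invariant, and requires both classes to have ≥ k + 1 cells
  (smaller pairs are reported as undefined, not zero).
- adjusted Rand index between reference labels and de-novo communities,
  restricted to pigment and cone cells, testing that untouched types keep
  their structure.

## Male/female comparison

Batch integration is a deliberate simplification of Harmony: batches are
first translated to a common global centroid (which removes a constant
offset exactly), then k-means joint clustering and within-cluster
centroid alignment iterate until the largest translation is below 10⁻³
(at most 10 iterations; batches with < 10 cells in a cluster are left
untouched). This is sufficient for offset-style batch effects, which is
all the sex comparison requires; it makes no claim to Harmony's behaviour
on composition-confounded batches.

The sex screen calls candidates at Bonferroni-adjusted p < 0.05 per
cluster and assigns one of three verdicts: `sex_specific` (detected in
≥ 25% of one sex and ≤ 5% of the other — "expressed in most cells of one
sex but hardly the other"), `fold_different` (mean CP10K + 1 ratio ≥ 2 or
≤ ½; "average expression" is not further specified upstream, so mean
CP10K was chosen and recorded), else `pattern_equivalent`. On null data
(no planted sex differences) the screen returns zero sex-specific calls.

Timepoint mixing is the Shannon entropy of a cluster's timepoint
composition normalized by the entropy of the global composition, plus a
chi-square goodness-of-fit p per cluster. The pale:yellow ratio test is
the exact two-sided binomial (minimum-likelihood method) with a 95%
Clopper–Pearson interval, checked against direct pmf summation.

## Numerical and degenerate-input choices

- All randomness flows through numpy Generators seeded per stage by
  stable hashing (CRC32 of the stage name mixed with the base seed), so
  re-running one stage never perturbs another.
- All-zero cells normalize to all-zero rows (with a warning); all-zero
  matrices are rejected where a soup profile is required.
- Empty datasets (0 cells) round-trip through the writers with valid
  headers.
- HVG ties break by gene index; annotation argmax ties yield "ambiguous".
- ρ̂ is clipped at 0.5 to prevent pathological over-correction; the clip
  warns.
- Gene-count and mito thresholds: inclusive vs strict as stated above.

## Problem sizes used in the shipped validation

The default validation dataset is 5,000 cells × 2,000 genes (the scale at
which all recovery statistics are quoted: type ARI ≥ 0.9, planted Class-1
recovery ≥ 90%, the ablation mixing-index contrasts); generator-fidelity
checks use 50,000–120,000 sampled label vectors; null calibrations use
ten 600-cell replicates. These sizes keep the whole suite to a few
minutes on one CPU while leaving all statistics comfortably clear of
their thresholds.

## Known limitations

- The soup is estimated from the dataset-wide profile rather than empty
  droplets; on tissue where the contamination is not expression-
  proportional this biases ρ̂.
- Cluster-level soup removal assumes the cluster annotation (and its
  forbidden sets) is broadly correct; a mis-annotated cluster can be
  over- or under-corrected (the 0.5 clip bounds the damage).
- The centroid batch correction cannot disentangle batch from composition
  when a cell type exists in only one batch (those clusters are skipped
  by the min-cells rule).
- The three-class specificity screen inherits τ's arbitrariness; values
  of τ between 0.05 and 0.25 reorder borderline Class 2/3 calls (swept in
  the test suite).
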