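# ommatidia

Single-cell RNA-seq analysis of the adult *Drosophila* eye, packaged as a
tested, reusable pipeline and driven by a synthetic ommatidial-retina count
generator so that every stage can be exercised — and scored against ground
truth — without any external data.

The adult fly retina is a crystalline tissue: each ommatidium contains
eight photoreceptors (R1–R8), four cone cells and a fixed complement of
pigment cells. Inner photoreceptors come in stochastic subtypes defined by
mutually exclusive Rhodopsin expression — pale (Rh3 in R7, Rh5 in R8) and
yellow (Rh4 in R7, Rh6 in R8) at roughly a 30:70 ratio, with dorsal-third
yellow R7s co-expressing Rh3 and Rh4 and the dorsal rim area expressing Rh3
plus *hth* only. R1–6 express *ninaE*, the most abundant transcript in the
eye and therefore the dominant component of the ambient-RNA "soup" that
contaminates every droplet. This package implements the full analysis such
data calls for:

- **simdata** — a negative-binomial generator planting cell types in
  anatomically expected proportions, opsin exclusivity, marker programs,
  ninaE-dominated ambient contamination (fraction ρ per cell),
  mitochondrial reads, doublets and a per-timepoint depth decline.
- **qc** — per-cell metrics; keep cells with gene counts inclusively
  within [gene_min, gene_max] and mitochondrial fraction strictly below
  mito_max; remove non-eye clusters (*fne*, *moody*, *repo*).
- **ambient** — cluster-aware soup correction: soup profile s_g from
  dataset-wide expression; per-cluster contamination from "forbidden"
  genes the cell type cannot transcribe,
  ρ̂_k = Σ x_forbidden / (Σ N_c · Σ s_g); expected soup removed per
  (cluster, gene), never driving a count negative.
- **cluster** — log CP10K, highly variable genes by standardized variance
  against a mean–variance trend, PCA on NB Pearson residuals (50 dims),
  shared-nearest-neighbour graph (Jaccard weights, pruned at 1/15), Leiden
  communities, seeded UMAP for reporting, and marker-panel annotation
  (panel-mean z-scores across clusters; opsin ratios assign pale/yellow).
- **markers** — one-vs-rest Wilcoxon rank-sum (exact enumeration for small
  groups), Seurat-style gates (only.pos, min.pct = 0.25, log2 fold change
  ≥ 0.25 on mean CP10K + 1), Bonferroni adjustment, cross-dataset
  intersection, a three-class specificity screen (Class 1 = expressed only
  in the home cluster at detection ≥ τ = 0.10; Class 2 = one other;
  Class 3 = several but not all), R7/R8-shared markers, and hypergeometric
  over-representation with BH q-values.
- **ablation** — the Rhodopsin-removal experiment made quantitative:
  delete gene sets ({Rh3,Rh4}, {Rh5,Rh6}, {Rh3–6}, {ninaE}, all five),
  recluster with identical parameters, transfer reference labels, and
  measure the kNN mixing index M (1 = separated, 0 = random mixing) per
  subtype pair plus the adjusted Rand index over untouched pigment/cone
  cells.
- **compare** — male/female merging with iterative centroid batch
  correction, a sex-specific screen with a three-way verdict
  (sex-specific / ≥2-fold level difference / pattern-equivalent),
  timepoint-mixing entropy, aging depth trends, and exact binomial tests
  of pale:yellow ratios with Clopper–Pearson intervals.
- **census** — published cell-type census tables used as worked examples
  for percentage and merged-total arithmetic.

## Worked example

```python
import ommatidia as om

sim = om.SimConfig(n_cells=3000, seed=3)
cfg = om.PipelineConfig(seed=3, run_ablation=False, run_embedding=False)
report = om.run_full_pipeline(sim, cfg)

qc = report["qc"]
print(f"cells kept: {qc['n_after_noneye_removal']} / {qc['n_input_cells']}")
print(f"median UMI per cell: {qc['median_counts']:.0f}")
print(f"top ambient (soup) gene: {report['ambient']['top_soup_gene']}")
rho = report["ambient"]["rho_by_cluster"]
print(f"contamination rho by cluster: {[round(v, 3) for v in rho.values()]}")
print(f"communities: {report['clusters']['n_communities']}")
print(f"cells per annotated type: {report['clusters']['type_counts']}")
r8 = report["compare"]["ratio_tests"]["R8"]
print(f"R8 pale fraction: {r8['pale_fraction']:.3f} "
      f"(exact binomial p vs 0.30: {r8['p_value']:.3f})")
```

prints

```
cells kept: 2898 / 3000
median UMI per cell: 1290
top ambient (soup) gene: ninaE
contamination rho by cluster: [0.109, 0.052, 0.06, 0.098, 0.046, 0.052, 0.047, 0.078]
communities: 8
cells per annotated type: {'R1-6': 952, 'pigment23': 665, 'cone': 633, 'pigment1': 320, 'R7': 175, 'R8': 153}
R8 pale fraction: 0.281 (exact binomial p vs 0.30: 0.660)
```

Reading: 97% of droplets survive QC and non-eye removal; the soup is
ninaE-dominated as expected for eye tissue; the estimated per-cluster
contamination fractions scatter around the planted mean of 0.05 (the two
higher values belong to small clusters); Leiden finds one community per
major type plus pale/yellow splits; and the pale fraction among annotated
R8s is statistically compatible with the expected 30%.

The same run is available from a shell:

```sh
ommatidia all --outdir out --seed 3          # writes out/report.json
ommatidia simulate --outdir out --seed 3     # dataset only (10x-style mtx)
```

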