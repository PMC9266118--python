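# Methods

## Scope and data model

`limbtraj` reconstructs a cell-type atlas of the limbal stem/progenitor
niche from two UMI count matrices — one per condition (`unwounded`,
`wounded`) — and designates putative limbal stem cells (LSCs), limbal
progenitor cells (LPCs), conjunctival progenitors and non-epithelial
populations. All cluster-level quantities (marker means, score thresholds,
stage means in the maturation screen) are expressed in **counts-per-10k**
units: the arithmetic mean over member cells of `1e4 * count / cell_total`,
i.e. the back-transformed (`expm1`) value of the log-normalized matrix.
This is the scale on which average marker expression values and the
differentiation-score ranges are conventionally printed, and the scale the
simulator's configured weights target.

## Quality control and normalization

A cell passes QC iff `total_counts >= min_counts` (default 500) and
`detected_genes >= min_genes` (default 200) and `apoptotic_fraction <=
max_apoptotic` (default 0.10), where the apoptotic fraction is the share of
the cell's counts on a configurable apoptotic gene panel (genes missing
from the matrix contribute zero). The three criteria mirror standard
droplet-data screening — low reads, few genes, apoptotic/stressed cells —
but the numeric thresholds are package defaults, config-exposed, since no
canonical values exist. "Low reads" is interpreted as low *UMI* counts.
Genes detected in fewer than 3 cells are dropped before clustering
(config-exposed). Normalization is library-size scaling to 10⁴ followed by
`log1p` (natural log), recorded in the matrix metadata rather than assumed
downstream; zeros map to zeros and each cell's value order is preserved.

## Clustering

Cells are embedded by PCA (`n_pcs = 10`) of the z-scored top-500
variable genes (ranked by dispersion = variance/mean of log expression).
Two partitioners are provided:

* `kmeans` (default): k-means for k in 2..20 with the partition chosen by
  mean silhouette (subsampled to 2000 cells above that size, seeded). The
  cluster count is therefore emergent, and results are reproducible across
  platforms because no graph heuristics are involved.
* `leiden`: community detection (RBConfiguration, seeded) on the kNN graph
  (k = 20) of the embedding, with a `resolution` parameter.

Silhouette-selected k-means was made the default after it recovered the
planted partition exactly at full study size, whereas modularity-based
community detection requires a resolution choice that is dataset-dependent.
Clusters are renamed by decreasing size (`EC1`, `EC2`, …, per condition);
names are presentation-level only and every downstream rule is
name-agnostic.

Characteristic markers per cluster are one-vs-rest two-sided Wilcoxon
rank-sum tests across genes with Benjamini–Hochberg correction within each
cluster; reported markers satisfy adjusted p ≤ α (default 0.05) and
log fold change ≥ `min_lfc` (default 0.25, natural log of linear-scale
means with pseudocount 0.01), ranked by fold change (ties: adjusted p, then
gene symbol).

## Joint dendrogram, cherries, branches

Cluster centroids from *both* conditions enter one agglomerative tree.
Distance is 1 − Pearson correlation of `log1p` centroid profiles over the
union of each condition's top-500 variable genes; linkage is average
(UPGMA); both are config-exposed (euclidean/complete available). The
agglomeration is implemented directly because reproducibility requires an
explicit tie rule — equal-height merges resolve toward the
lexicographically smallest pair of node labels, and children are ordered by
smallest descendant leaf — making serialized trees byte-stable. Problem
sizes are tens of leaves, so the O(n³) loop is irrelevant. Trees serialize
to Newick (leaf labels `<cluster>|<condition>`, branch lengths = height
differences); parsing goes through Bio.Phylo.

A **cherry** is an internal node whose two children are both leaves. Each
cherry whose two epithelial leaves come from opposite conditions becomes
one *shared* cell type; every remaining epithelial leaf — including both
members of a same-condition cherry, since the pairing rule is conditional
on opposite conditions — becomes its own condition-specific type. This
gives the identity `#types = #epithelial leaves − #cross-condition
cherries`, which holds for arbitrary trees and is property-tested on 1000
random trees.

Branches are obtained by restricting the tree to the epithelial leaves
(suppressing unary nodes, keeping merge heights) and splitting root-down at
the k − 1 highest merges (k = 3 by default; ties resolve toward the
smallest leaf label). k is an explicit parameter, never inferred, because
branch count is a modelling choice.

## Differentiation scores and designation

Corneal score from the cell-count-weighted mean Krt12 of a type's member
clusters: 1 if < 0.9, 2 if 5.5–20, 3 if > 180. Conjunctival score from mean
Krt13: 1 if < 0.8, 2 if > 9. These ranges reflect the natural segregation
of the markers into separated expression bands; values falling in the gaps
between bands are assigned to the nearest band on the multiplicative scale
(geometric-midpoint boundaries ≈ 2.22 and 60.0 for Krt12, ≈ 2.68 for
Krt13), since expression effects are fold-change-like. A `strict` mode
raises on gap values instead. Scoring is total and monotone on [0, ∞).

Designation proceeds per epithelial cell type:

* A branch *shows a differentiation trajectory* iff it contains at least
  one **shared** type that is undifferentiated on *both* axes (corneal
  score 1 **and** conjunctival score 1) and at least one type with corneal
  score ≥ 2. Requiring the conjunctival axis too is deliberate: a branch
  anchored only by a conjunctival progenitor is a conjunctival lineage, not
  the corneal differentiation trajectory.
* Within trajectory branches: shared, doubly undifferentiated types whose
  progenitor-panel mean (Krt14/Krt15) is at or above the median over all
  undifferentiated types are putative LSCs. Using ≥ (rather than >) keeps
  the rule meaningful when the number of undifferentiated types is odd and
  an LSC sits exactly at the median. Among putative LSCs, a relative drop
  of the epithelial percentage from unwounded to wounded of at least δ
  (default 0.25) designates **putative_active_LSC**, otherwise
  **putative_quiescent_LSC**. A two-proportion z-test (α = 0.05) is
  available as an alternative decrease rule. Corneal-score-≥2 types in
  trajectory branches are **putative_LPC**.
* Outside trajectory branches: conjunctival-score-2 types are
  **putative_CjPC**; corneal-score-2/3 types are
  **putative_differentiating_LPC**; doubly undifferentiated types with
  progenitor mean strictly between the most differentiated non-trajectory
  types and the LSC minimum are **unknown_origin_SPC** (stem/progenitor
  cells of unknown origin). Types matching no rule are `unclassified`.
* The proliferative flag (mean proliferation-panel z-score ≥ 1 across
  clusters, per-gene z over all cluster profiles, zero-variance genes
  contributing z = 0) is attached independently and never drives a label.
* Epithelial percentages are computed over epithelial clusters only and
  sum to 1 per condition by construction. LSC candidacy is restricted to
  shared types: a type absent after wounding cannot be distinguished from
  an exhausted or artefactual population, so it is treated as the general
  rule rather than a case-specific exception.
* The hematopoietic panel (Cd34/Cd44/Cd14/Cd19) is reported descriptively
  and never used as a decision criterion.

Non-epithelial clusters (no cytokeratin-panel gene with mean ≥ 1.0; the max
over the panel is used so one strongly expressed keratin suffices) are
typed by argmax over stromal/T-cell/macrophage panel z-scores, with
`unresolved` returned when the margin over the runner-up is < 0.5.

## Maturation screen

Only unwounded clusters enter (wound-healing expression can be transient
and stage-specific). Stage means are cell-count-weighted over member
clusters (an unweighted mode exists). A gene passes iff mean rises by
≥ `min_ratio` (default 2.0) per step across LSC → LPC → differentiating
LPC, with pseudocount 0.01 added to every mean; the fold difference is
computed between the trajectory endpoints, (diffLPC + pc)/(LSC + pc), an
explicit modelling choice over max/min. Passing genes are ranked by fold
descending (ties by symbol) and the top N (default 10) marked selected.

## The simulator

Each cluster is an expression program: a vector of per-10k weights over the
gene universe (≈ 1950 genes by default: marker panels, characteristic
markers, branch signatures, apoptotic panel, planted maturation genes, and
1800 background genes that absorb the remaining budget so every cluster's
weights sum to 10⁴ — hence a configured weight *is* the expected
counts-per-10k mean). A cell draws a log-normal library size (mean 5000,
σ = 0.25) and Gamma-Poisson (negative binomial, Var = μ + μ²/θ, θ = 10)
counts per gene. The default composition plants the full study:

* 3136 unwounded cells in 11 clusters and 4967 wounded cells in 12, of
  which 8 per condition are epithelial (85% of cells) and the rest stromal
  / T cell / macrophage (typed by Col1a1/Col1a2/Dcn/Cd34, Trdc/Cd3g/Trbc1,
  Cxcl2/Ccl4/Cd14 panels; the wounded sample carries a second, Cd34-high
  stromal subtype).
* Corneal stages realize the printed Krt12 score bands via stage weights
  0.3 / 12 / 250; conjunctival stages use Krt13 weights 0.2 / 15.
  Progenitor level (Krt14/Krt15 weight) is 60 for the two LSC types, 50
  for trajectory LPCs, 20 for the unknown-origin types and 5 for the
  differentiated Branch-2 types, matching the described ordering.
* Epithelial shares: the putative quiescent LSC pair at 18% → 22% and the
  active pair at 20% → 11% of epithelial cells; remaining shares chosen
  once as a plausible spread (6–16%).
* Cross-condition pairs carry identical programs up to their reported
  marker values (Edn2 29 → 13, Adm 3.9 → 1.0 for the quiescent pair; Fmo2
  8.9 → 6.8 for the active pair); every type additionally carries a small
  exclusive synthetic marker set, and each of the three branches a
  12-gene signature, so that types are separable and branches cohesive —
  the qualitative structure any clusterable atlas must have.
* Planted maturation genes: the Krt12 ladder itself plus 9 synthetic genes
  (`Mat01..Mat09`) on a geometric ladder 0.2 × 20^(stage−1); the screen's
  expected top-10 is exactly this 10-gene set, with Krt12 first.
* 5% of cells per condition are emitted QC-failing by one of three
  mechanisms (4% library, 80-gene restriction, 25% apoptotic mass),
  recorded in the ground truth. The apoptotic panel (`Apop01..Apop20`) is
  a synthetic stand-in — no canonical apoptotic gene list is assumed.
* Proliferative clusters (one homeostatic LPC, one wound progenitor) raise
  Mki67/Mcm2–7 weights 25 vs baseline 2.

The ground truth records cell→cluster labels, QC-fail cells, pairings,
branch labels, lineages, proliferative flags and the expected designation
per cluster. Identical config + seed ⇒ byte-identical MTX output.

**What the simulator does not model:** doublets, ambient RNA, batch
effects beyond condition, GFP-label intensity, cell-cycle structure within
clusters, or gene–gene correlation beyond the cluster programs. Passing
tests therefore demonstrate that the inference chain recovers the planted
structure under negative-binomial noise at realistic depth — not that it
is robust to the full messiness of real droplet data.

## Problem sizes and numerical choices

Full-scale runs (3136 + 4967 cells) are used for the single-seed recovery
checks and the acceptance script; the 20-seed end-to-end designation check
runs at 0.4× cell counts with composition, effect sizes and structure
unchanged — at that size the smallest cluster (≈ 60 cells) occasionally
merges into its branch neighbour, which leaves the LSC designations
untouched and is part of what the check demonstrates. Simulator mean
recovery is asserted within 20% relative error with an absolute floor of
0.2 counts-per-10k, since sub-unit means at a few hundred cells have
sampling error of the same order as the relative band. Zero-distance
profile ties and equal-height merges resolve lexicographically;
zero-variance genes z-score to 0; correlation against a constant profile
is treated as 1 (distance 0). Seeds propagate explicitly: the simulation
seed fixes the data, the clustering seed fixes PCA/k-means/Leiden, and the
pipeline reuses one seed for both.

## Known limitations

* The score-band thresholds are taken as given; on data normalized to a
  different scale they must be re-derived from the observed segregation.
* Cherry pairing can only pair clusters one-to-one; a cell type that
  splits into two clusters in one condition will appear as one shared type
  plus one condition-specific type.
* Branch count k is user-chosen; the trajectory-branch definition assumes
  corneal maturation is the dominant axis.
* The designation rules are deterministic thresholds, not a probabilistic
  model; δ = 0.25 encodes "a clear relative decrease" and should be
  revisited for designs with very different sampling depths (or replaced
  by the z-test rule).
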