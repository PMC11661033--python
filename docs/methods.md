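# Methods

This note documents the generative model, the analysis procedures, the
defaults and the reasoning behind the genuinely open design choices. It
states no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## The synthetic data generator

### What it emulates

The generator reproduces the structure of a human right-atrial-appendage
scRNA-seq cohort contrasting sinus rhythm (SR) with atrial fibrillation
(AF): two conditions × 3 biological samples each; eight major cell types at
pooled proportions of 44% FB, 27.3% immune (split here 60:40 into myeloid and
lymphoid — the split is not reported anywhere and is a package choice), 14.6%
EC, 8.1% SMC, 3.2% aCM, 1.5% epicardial, 1.2% neuronal; 23 subclusters (FB1–6,
SMC1–2, EC1–3 with reported marker genes; aCM1–2, My1–4, Ly1–4, Epi1, Neu1
with atlas-standard placeholder markers, since subcluster counts and markers
for those compartments are not enumerated — both the split and the panel are
overridable in `SynthConfig`). The reported percentages sum to 99.9%; the
packaged profile renormalises them so each condition's fractions sum to 1.

### Composition

Per-sample subcluster counts are a single multinomial draw of
`cells_per_sample` cells. Within each major type the pooled fraction is
split uniformly across its subclusters (per-subcluster fractions are never
reported numerically). Condition differences are encoded as a zero-sum
shift vector `d`: SR uses `f − d/2`, AF uses `f + d/2`, so the pooled SR+AF
expectation equals the pooled target exactly — the natural construction when
only pooled proportions are reported. The default `d` raises FB3 strongly
(+4 percentage points, the dominant reported change), FB1/FB5 and the
myeloid subclusters mildly, and lowers FB2/FB4/FB6, aCM, EC and epicardial
fractions; magnitudes are package choices since none are reported.

### Counts

Counts are gamma-Poisson: `K ~ NB(mu, alpha)` with `Var = mu + alpha·mu²`
and a single shared dispersion `alpha = 0.5` (mid-range for UMI data).
`mu_cg = L_c · w_g · bump(g, s, d)` where:

- `L_c ~ LogNormal(log 2000, 0.3)` is the cell's library-size factor;
- `w_g` are sum-normalised baseline weights: lognormal(0, 1) for pure
  background genes, and a common unit weight for panel, program and planted
  genes (markers of real atlases are reliably detected; a fixed baseline
  also makes the generator's mean ratios exact, which the moment-level
  tests exploit);
- `bump` multiplies the cell's own subcluster markers *and* its major type's
  markers by `marker_fold_change = 8`, its subcluster and lineage program
  genes by `program_fold_change = 4`, and — in AF cells of a targeted
  subcluster — each planted gene by `2^log2FC`.

**Program genes.** Real cardiac lineages differ in the expression of
hundreds of genes, not just the handful of printed markers. A slice of the
configured background budget is therefore assigned to expression programs:
40 genes per major type (`LIN-*`) and 25 per subcluster (`PRG-*`), both at
fold 4. This serves two purposes. First, recoverability: with only 2–5
marker genes per type, the separation of a 1.2% cell type contributes a
signal eigenvalue below the PCA noise bulk, and no clustering method can
isolate it — the programs provide the realistic lineage-scale signal that
makes recovery reliable without being degenerate. Second, the one-vs-rest
DEG universe then contains ~1,000 cluster-specific genes rather than only
the panel, which is what the expression-pattern stage is meant to partition
(the emulated study's analog has 1,791). Matrix dimensions remain
`markers + extra + n_background_genes`.

**Planted condition effects.** The default `condition_de` encodes the
reported FB3 AF signature — *COL3A1* (+2 log2), *ELN* (+1.5), *SPARC*,
*TPM1*, *ACTA2* (+1) up; *MT2A* (−1.5), *MT1X* (−1) down — plus *TXNDC5* and
*POSTN* (+1) in EC1. Fold sizes are package choices; the genes and
directions are the reported ones.

### Determinism

Every random consumer derives its own stream from
`(seed, tag)` — e.g. `counts|SR2|FB3` — so the full output is a pure
function of the config, block order never matters, and stages can be rerun
in isolation. Fixing the seed fixes the output byte stream; changing it
changes counts but not dimensions or label sets.

### What the generator does not model

No doublets, ambient RNA, batch/donor effects, UMI saturation, spliced
layers, or gene–gene correlation beyond the block structure above. Cells
within a subcluster are exchangeable. Passing tests therefore demonstrate
that the pipeline's logic is correct under the declared model — planted
effects of the stated size are recovered at the stated error rates — not
that it is robust to the full noise structure of real tissue.

## Quality control and normalization

Cells are kept with 200–6,000 detected genes and mitochondrial fraction
≤ 0.2 (`MT-` symbol prefix); genes need detection in ≥ 3 retained cells. No
thresholds are reported for the emulated study, so these are the
conventional defaults, fully configurable. An upstream instrument-based
aggregate filter in the emulated workflow has no in-silico counterpart.
Normalization scales each cell to 10,000 counts and applies log1p (natural
log). A matrix emptied by QC, or a zero-total cell reaching normalization,
is an explicit error.

## Annotation

Clustering is PCA (30 components, seeded randomized solver) followed by
seeded k-means — transparent and deterministic; graph-based clustering was
considered and rejected as a default because k-means with a fixed seed and
`n_init=10` reproduces bit-identically across platforms. Two deliberate
choices:

- **Over-partitioning.** The major stage uses `k = 30` clusters, not 8.
  With k equal to the number of types, k-means spends clusters splitting the
  44% FB compartment and merges the 1–2% epicardial/neuronal types, which
  can never be undone by labelling. Over-clustering followed by per-cluster
  marker scoring is the standard remedy and costs nothing: clusters mapping
  to the same type are merged by the label.
- **Marker scores across clusters.** `score(cluster, type)` is the mean over
  the type's present markers of the cluster-mean expression z-scored
  *across clusters* (not cells), keeping scores comparable between abundant
  and rare types. Ties break to the declared panel order and are flagged.

Subclustering reruns the same procedure within each major type with k equal
to the type's sub-panel size, then names clusters by sub-panel score — via a
one-to-one Hungarian assignment when cluster and panel counts match (so two
clusters cannot claim the same name), argmax otherwise.

## Differential expression

One-vs-rest Wilcoxon rank-sum per cluster on log-normalized values — the de
facto scRNA-seq standard; the Student's t-test is reserved for sample-level
composition comparisons. The scalar test uses the exact distribution for
pooled n ≤ 12 without ties, otherwise the normal approximation with midrank
tie correction and continuity correction; the table-level routines use a
vectorised implementation of the same asymptotic test (ranks and tie terms
computed once per gene, reused across clusters). Fold changes are
expression-space: `log2((expm1(mean log) + 1) / (expm1(mean log) + 1))`,
pseudocount 1. BH adjustment is applied within each contrast's gene vector.
Default catalogue filters: q < 0.05, log2FC > 0.25, upregulated only — no
thresholds are reported; these are conventional and configurable. The union
of marker genes across clusters is the pipeline's DEG universe; whether the
emulated study's 1,791 DEGs were one-vs-rest markers, condition DEGs or both
is not stated, and the one-vs-rest reading is used here.

## Expression patterns

Each DEG's profile is its mean expression per cluster, z-scored within the
gene across clusters (zero-variance genes become zero rows, never NaN).
Profiles are partitioned by seeded k-means into K = 14 patterns — matching
the emulated study's count; how its patterns were actually derived
(hierarchical, manual, other) is unknowable from the text, and k-means on
z-scored cluster means is this package's principal interpretive decision.
Pattern ids are ordered by the cluster index of the centroid argmax for
stable reporting; a pattern's signature is the ordered set of clusters with
centroid z above `signature_threshold = 1`. Empty patterns trigger bounded
reseeded restarts, then an error.

## Gene-set enrichment

The observed statistic is the overlap between a gene set and a pattern's
genes within a background universe; the null redraws same-size sets
uniformly without replacement and the empirical p-value uses the add-one
correction `p = (1 + #{null ≥ obs}) / (n_perm + 1)`, so p is never 0 — the
floor is `1/(n_perm+1)` (a reported permutation "P = 0" is represented this
way here). Whether the emulated analysis permuted gene labels, set
membership or pattern assignment is unstated; all three are equivalent under
exchangeability, which is why the exact hypergeometric tail is the
cross-check (and the acceptance anchor). Defaults: background = the
pattern-assigned DEG universe (the most conservative reading of "random
data"; all detected genes can be passed instead), `n_perm = 10,000`, no
multiplicity correction across patterns (raw permutation p-values are the
convention being emulated; a BH pass can be applied to the output table).
Symbol matching is case-folded exact match; no alias resolution.

## Composition comparisons

Per-sample counts and fractions at either level, then a two-sided unpaired
Student's t-test (pooled variance; Welch optional) on per-sample fractions
between SR and AF, starred `*` p<0.05 / `**` p<0.01. No compositional
(CLR/logit) transform by default — raw proportions are the convention being
emulated. With n = 3 per condition the test is a coarse instrument; group
means are always reported alongside, and degenerate zero-variance inputs are
flagged rather than silently assigned a p-value.

## Pipeline and problem sizes

`run_all` executes simulate → QC → annotate → DE → patterns → enrich →
composition from one config, derives per-stage seeds by hashing the stage
name with the global seed, writes every intermediate as TSV/MTX/JSON, and
emits a manifest (versions, seeds, input hashes, per-stage counts).
Reruns with an identical config are byte-identical.

Problem sizes used in the shipped checks, chosen to exercise every claim at
meaningful statistical resolution: the shared test fixture runs 6 × 1,500 =
9,000 cells (every subcluster ≥ ~100 cells); the study-scale checks and
`scripts/acceptance.py` run 6 × 11,667 ≈ 70,000 cells, the emulated cohort's
scale, where 3 binomial SE on the FB fraction is ±0.56 percentage points.

## Known limitations

- Gene symbols are matched exactly (case-folded); no HGNC alias resolution.
- The generator's exchangeable-within-subcluster cells make clustering
  easier than on real data at equal signal size; recovery rates here bound
  the pipeline's behaviour under the model, not under real noise.
- Immune subcluster structure (My1–4/Ly1–4 split and markers) is a
  documented guess pending any enumeration in the emulated literature.
- The composition t-test inherits the n=3 sample size of the emulated
  design; its power statements are anecdotal at that n.
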