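# Methods

`citepipe` re-implements, as a tested pipeline, a CITE-seq analysis of
CD4+ T cells in coronary artery disease (CAD) and diabetes (DM): antibody
background thresholding, major-type gating, surface-marker clustering,
cluster-composition testing, filtered differential expression, iterated
random-forest gene importance, and Gensini-based CAD classification.  The
real cohort data are not required: a synthetic generator emulates the
multiplexed study design with known ground truth, so every stage has a
recoverable target.

## Data model

Three UMI count matrices (antibody tags, transcripts, sample tags) share a
cell-barcode index; the barcode is the join key across modalities and cells
missing from any modality are dropped with a logged count.  Matrices are
held cells x features and exchanged on disk as Matrix Market (1-based
entries, rows = cells, with `barcodes.tsv`/`features.tsv` sidecars) or
dense CSV; the two dialects load to value-identical objects.  Configuration
is one flat dataclass tree serialized to YAML or JSON; unknown keys are an
error so typos fail fast rather than silently reverting to defaults.

## Synthetic study generator

The generator emulates the study conditions: 8 subjects by default (the
full sex x CAD x DM crossing), 1,500 cells per subject, hash-tagged four
subjects per plate; 49 antibodies; 200 targeted genes; 5% doublets.

* **Cell populations.** Six latent clusters spanning major lineages
  (B, monocytes, CD8 T, and three CD4 T memory subsets: central memory,
  effector memory, CCR2+ effector memory).  Per-subject cluster proportions
  start from base proportions (0.15/0.15/0.15/0.25/0.20/0.10), receive
  N(0, 0.2) logit noise (subject-level biological variability), and planted
  effects multiply one cluster's softmax weight by the odds ratio — which
  scales that cluster's odds against the rest *exactly* by the planted
  factor.  The default design depletes the CCR2+ Em cluster in CAD+
  subjects at odds ratio 0.5.
* **Antibodies.** Each antibody has a negative and a positive normal
  component on a latent log2 scale with per-cluster positivity; counts are
  negative binomial (variance mu + phi mu^2, phi = 0.5) around 2**latent.
  Background sits at mean 1.0 (about 2 UMIs); phenotype markers' positive
  component at 6.0 (about 64 UMIs); the six gating lineage markers at 9.0
  (about 500 UMIs), reflecting how bright abundant lineage antigens are in
  real panels.  Filler antibodies get random per-cluster positivity
  (probability 0.4), drawn once with a fixed design-construction seed.
* **Genes.** NB counts (phi = 0.2) around 2**(base + cluster shift +
  condition shift).  Each cluster has eight marker genes shifted +2 log2;
  planted condition effects add the stated log2 fold change for subjects in
  the condition: TCF7 up in both CAD+ and DM+, GNAI2 in CAD+, LAIR2 in
  DM+, IFITM3 in females, IL32 in DM- — all at log2FC 1.0, planted at a
  base depth of 2.5 log2 (about 6 UMIs).
* **Tags.** The subject's own tag is Poisson(60); others Poisson(1).
* **Doublets.** A doublet sums the counts of two freshly drawn singlets
  from *distinct* subjects on the same plate, so it carries two high tags;
  cross-lineage pairs (different major types) are the "biological doublet"
  subset.  Same-subject doublets are not generated — they would carry a
  single high tag, contradicting the generator's two-high-tags contract;
  undetectable-by-tag doublets enter the pipeline instead through the
  external expression-doublet flag channel.
* A cheap path (`simulate_cluster_counts`) draws only the subject x
  cluster membership counts from the same proportion model, for
  composition analyses that do not need count matrices.

Everything is driven by one `numpy` Generator seeded from a single integer;
identical seeds give bit-identical outputs.

What the generator does **not** emulate: ambient RNA, plate batch effects
(off by default; an additive plate shift is available for robustness
experiments), TCR clonality, trajectory structure, and empty droplets.
Passing tests therefore show that the algorithms recover known structure
under clean multiplexed noise, not that they are robust to every artifact
of real data.

## Demultiplexing

The tag-calling rule is deliberately simple and auditable: a cell is
*undetermined* if no tag reaches `min_count` (default 10); a *multiplet* if
a second tag reaches `min_count` and the top/second ratio is below
`dominance_ratio` (default 3), or if two tags both reach
`min_count * dominance_ratio` (two genuinely high tags); otherwise a
*singlet* assigned to the dominant tag's subject.  The three clauses as
first drafted did not cover every count pattern (e.g. top 50 / second 12 at
the defaults satisfies none); the implemented rule is total, agrees with
all stated cases, and preserves the monotonicity property that raising
`min_count` can never turn an undetermined cell into a singlet.

Three doublet categories are tracked separately: tag multiplets (above);
expression doublets, imported from an external per-barcode CSV (the
detection algorithm is out of scope, only the flag is carried); and
cross-lineage "biological" doublets — CD4 T cells positive for myeloid
markers (CD33, CD14 by default), flagged per cell or, by default, per
cluster when more than 50% of a cluster's members are marker-positive
(mirroring the removal of an entire contaminated cluster).

## ADT normalization and thresholding

Antibody counts are CLR-normalized per cell on the log2 scale (pseudocount
1, config-exposed; a per-antibody-across-cells margin is a one-line change
on the transposed matrix).  Per antibody and cell-type context, a
two-component univariate normal mixture is fitted by EM: five
initializations with component means at spread quantile pairs
(25/75, 10/90, 5/95, 30/70, 15/85), sds at half the pooled sd, relative
log-likelihood tolerance 1e-6, 500-iteration cap, best likelihood kept,
components ordered by mean.  The positivity threshold is the posterior-0.5
crossing between the component means (the Bayes boundary between the two
fitted normals, solved in closed form from the quadratic in x); if no
crossing lies between the means the midpoint is used with a warning.  A
mean + k sd negative-reference rule (default k = 3) is provided for markers
thresholded from a known-negative cell type.

Two guards formalize what an analyst does when inspecting ridgeline
distributions before trusting a deconvolution:

* a fit is only accepted when the components describe two real populations
  — means at least 2 pooled sds apart and both weights at least 0.02;
  otherwise the antibody is reported as `failed` with no threshold
  (background-only markers legitimately fail);
* within a cell type that is entirely negative for a marker (e.g. CD33 on
  CD4 T cells), a mixture can only split the zero-count spike from the
  nonzero background, so the pipeline takes decision thresholds from the
  all-cells context, where the positive population of another lineage
  anchors the positive component; within-type fits are still computed and
  reported.

Gating is ordered first-match-wins over thresholded markers: B (CD19+),
monocytes (CD14+ or CD16+), CD8 T (CD3+CD8+), CD4 T (CD3+CD4+ and
CD8-CD19-CD14-CD16-), everything else `Other`.  The order resolves
contradictory marker combinations deterministically and every cell receives
exactly one type.

## Clustering and phenotype naming

Gated CD4 T cells are clustered on CLR antibody space with the gating
lineage markers excluded: centering, PCA to 20 components (full SVD, fixed
sign convention), a k = 30 nearest-neighbor graph (undirected union of
directed kNN edges), and Louvain community detection (igraph multilevel) at
resolution 0.15 with the random seed fixed at 42.  Labels are renumbered
1..K by decreasing size, ties broken by lowest member index, so identical
input and seed give identical labels and permuting cells changes labels
only up to renumbering.  An externally corrected embedding can be passed
in place of the internal PCA (batch integration itself is out of scope).
The 2-D embedding defaults to the first two PCs — deterministic and free —
with UMAP available by config; it is for plots only and carries no contract
beyond determinism.

Clusters are named by rules over marker-positive fractions (positive =
fraction strictly above 0.5): Em CCR2+ before the plain memory rules, then
Cm (CD45RA-CD197+), Em (CD45RA-CD197-), Emra (CD45RA+CD197-), Naive
(CD45RA+CD197+); unmatched clusters are `Unlabeled-k`.

## Composition analysis

Within the parent type, each subject's cluster proportion p is expressed
as natural-log odds ln(p'/(1-p')) with Haldane smoothing
p' = (x + 0.5)/(n + 1), keeping clusters absent from a subject finite.
Groups are compared per cluster by a two-sided rank-sum test on subject
log-odds — consistent with the use of Mann-Whitney tests for continuous
clinical variables — with Benjamini-Hochberg adjustment across clusters
reported alongside the raw p-values.

## Rank-sum testing

One statistical engine serves composition and DE.  When both groups have at
most 8 observations the two-sided p-value is exact: all C(n1+n2, n1)
assignments of the pooled midranks are enumerated and
p = 2 min(P(W <= w), P(W >= w)) capped at 1 — tie-safe, and equal to the
classical exact distribution when there are no ties.  Larger groups use
scipy's tie-corrected normal approximation with continuity correction,
vectorized across genes.  Constant columns get p = 1 by convention and are
flagged.

## Differential expression

Transcripts are normalized per cell to log2(1 + CPM).  The normalization
sentence this follows is ambiguous between per-cell and per-gene scaling; a
literal per-gene mode is retained for fidelity experiments, but per-cell is
the default because per-gene scaling makes cross-gene fold-change
comparisons degenerate.  Per gene: rank-sum p as above; avg_log2FC =
log2((mean(2^v - 1) + eps)/(mean(2^v - 1) + eps)) with eps = 1e-9; pct.1
and pct.2 are the expressing-cell fractions.  Cluster markers keep
adj p < 0.05, avg_log2FC > 0 and pct.1/pct.2 > 2.5 (a zero pct.2 counts as
an infinite ratio so the filter stays total); the condition-overlap set
intersects genes upregulated in both contrasts at adj p < 0.05 with
pct.1 > 0.2.

## Random-forest importance

For a two-condition contrast, each of 15 iterations draws 1,000 cells per
condition (with replacement only when a condition is smaller, with a
warning), trains a 500-tree random forest (scikit-learn defaults otherwise;
class balance is guaranteed by the equal subsample, so no class weighting),
and min-max scales the impurity importances to 0-100.  Genes are ranked by
the mean scaled importance across iterations (median available by config).
Per-iteration sub-seeds derive deterministically from the master seed via
`SeedSequence([master, iteration])`.  Stratum rankings are compared by
Spearman correlation over the union of either stratum's top-50 genes;
genes outside the top-50 in one stratum keep their actual rank there.

A caution established while validating the procedure: min-max scaling
stretches the importance range of *whatever* the forest saw, so under a
label-shuffled null the typical gene still scores ~30 and the luckiest of
200 genes averages in the mid-40s across 15 iterations — approaching 50
when the cell pool is small enough that a gene's accidental correlation
with the shuffled labels persists across subsamples.  High scaled
importance alone is therefore not evidence; the separation that matters is
a planted/real signal pinning 100 in every iteration while everything else
collapses toward zero.

## Gensini scoring

Percent stenosis maps to a base score through the conventional breakpoint
table {>=25%: 1, >=50%: 2, >=75%: 4, >=90%: 8, >=99%: 16, 100%: 32}
(config-replaceable), multiplied by the segment's location weight in
[0.5, 5] and summed over lesions.  No collateral adjustment.  Scores above
30 classify CAD+, below 6 CAD-; the boundaries themselves are
indeterminate because both stated inequalities are strict, and subjects in
[6, 30] are labeled indeterminate rather than silently excluded.

## Orchestration and determinism

`run_all` executes simulate -> demux -> CLR/threshold -> gate -> cluster ->
biological-doublet removal -> phenotype naming -> composition -> DE (CAD
and DM) -> overlap -> importance under one config and one master seed.
Stage sub-seeds derive from SHA-256 of (master, stage name), truncated
below 2^31.  The manifest records the config snapshot, per-stage cell
counts (asserted non-increasing through filters), SHA-256 checksums of
every written table, and the headline results; identical (config, seed)
reproduce identical checksums.

## Problem sizes used in validation

The validation suite runs the full pipeline at the default design (12,000
cells) and individual stages at 20,000 cells; composition power uses 100
replicates of the membership sampler at 16 subjects (8 per CAD group);
DE calibration uses 500 null NB genes at 100 cells per group; the
importance checks use a 40,000-cell pool with 1,000 cells per condition,
15 iterations and 300 trees (trees reduced from the 500-tree default to
keep repeated null fits cheap; tree count does not change the null
behavior measurably).  Analysis drivers run a 4,800-cell version of the
same design.

## Known limitations

* The tag-calling rule is a simple contract, not a reimplementation of any
  vendor algorithm; real hashing data with ambient tag soup may need the
  two parameters retuned.
* Expression-doublet detection is intentionally external; the pipeline only
  consumes a per-barcode flag.
* The mixture model assumes two normal components on the CLR scale;
  trimodal markers or heavy zero-inflation within a context are reported as
  failures rather than force-fitted.
* Composition testing treats subjects as exchangeable within groups; no
  mixed-effects or Dirichlet-multinomial structure.
* With 4 subjects per group (the default 8-subject design) the exact
  rank-sum test's smallest attainable two-sided p is 2/70 ~ 0.029, so only
  complete separation can reach significance; the 16-subject design is the
  appropriate scale for power statements.
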