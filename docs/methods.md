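# Methods

## Scope and data model

The package operates on sparse gene × cell integer count matrices with
per-cell metadata (maturation stage among E16.5–P20, capture technology
`cell` or `nucleus`). In memory the container is an AnnData (cells ×
genes); on disk the 10x-style MatrixMarket triplet dialect
(`matrix.mtx` in strict `integer general` coordinate format with
1-based, genes × cells indices; headerless `features.tsv` and
`barcodes.tsv`; TSV metadata). Writers are bit-faithful round-trip
partners of the readers; the MTX writer is implemented directly rather
than through `scipy.io.mmwrite` because the latter auto-detects
symmetry and picks the field from the dtype, both of which would break
the fixed dialect. Result tables are TSV with a `#`-prefixed provenance
line (tool version, seed, parameters).

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions
under which every downstream claim is checked.

**Count model.** For cell `c` of type `t` and gene `g`,

    count ~ NB(mean = s_c · μ_g · m_{g,t} · G_g(p_c), dispersion φ_g)

thinned per molecule by a binomial with keep probability `q`. The NB is
mean/dispersion parameterized (variance `μ + φμ²`) and sampled as a
gamma–Poisson mixture; binomial thinning keeps the family closed (a
thinned NB is NB with mean `qμ`), which is why thinning rather than
whole-entry zeroing is used — zeroing entire entries would, among other
artifacts, randomly assign a fifth of all cells to the weakest anchor
bin regardless of position. `s_c` is a mean-one log-normal library
factor (default log-sd 0.3). Baseline means `μ_g` are log-normal around
1.0 (log-sd 0.5); dispersion defaults to 0.5 with per-gene overrides.

**Cell types.** A registry of 37 specifications (name, ensemble, marker
genes with fold multipliers, proportion, per-technology capture bias)
drives both simulation and annotation. Marker multipliers default to
8×. Capture biases encode the known technology asymmetries: outer hair
cells are absent from the single-cell preparation (bias 0), the basal
stria layer is nearly absent (0.05) and the intermediate stria inflated
(3×) there, whereas nuclei are captured near-uniformly. Registry marker
sets are constructed so that no type's marker set is a subset of
another's; this is what makes cluster-level marker scoring able to
separate every pair of types.

**Background divergence.** Real cell types differ in hundreds of genes,
not only in their nameable markers. Unnamed background genes therefore
receive per-(gene, type) mean-one log-normal multipliers (log-sd 0.8).
Without this, no clustering method can separate 37 populations that
differ in 2–3 genes each against shot noise — a property of the data,
not of the algorithm. Fixtures that need exchangeable null genes (null
calibrations) set this to 0.

**Tonotopic gradient.** Tympanic border cells carry a latent position
`p ~ Uniform(0, 1)` (0 = base, 1 = apex; continuous because the four
subregions are a post-hoc binning, so continuity is the least-committal
choice). A base-high gradient gene with base/apex ratio `r` has its
mean multiplied by `r^(−p)` (apex-high: `r^(p−1)`) — log-linear in
position, the simplest monotone shape consistent with a gradual
gradient. The TBC screening fixture models the anchor *Emilin2* as a
highly expressed (16× baseline), low-dispersion (φ = 0.1) gene with a
conspicuous 16-fold gradient: with the φ = 0.5 dispersion floor of
ordinary genes, per-cell expression noise caps the correlation between
observed anchor expression and `p`, and a weak anchor would attenuate
every screened gene's between-bin contrast below the 1.3 fold gate.
Screened genes default to baseline mean 12 (the screen's detection
filter restricts it to robustly expressed genes) and dispersion 0.5.

**What the generator does not emulate:** ambient RNA, doublets, batch
chemistry, cell-cycle structure, mean-dependent dropout curves, or
read-level noise. Passing tests therefore demonstrate correctness of
the statistical machinery under a clean NB world, not robustness to
every artifact of real droplet data.

## Normalization, QC, clustering, annotation

Normalization is depth scaling to 10,000 followed by `log1p` — the
dominant convention for 10x data; all-zero cells pass through with a
warning. QC removes cells below a detected-gene threshold first, then
genes below a cell-support threshold (the order matters and is fixed).

Clustering is PCA (50 components) → kNN graph (15 neighbours) → Leiden
at resolution 2.0, deliberately over-partitioned, followed by two
correction passes:

* a **cluster-validity merge**: the closest pair of clusters (centroid
  distance in PCA space) is merged unless at least 5 genes separate
  them at rank-sum BH q < 0.01 with an absolute mean difference > 0.5
  on the log scale, iterated to fixed point. The gene-count floor
  guards against double-dipping — a handful of "significant" genes can
  always be manufactured by grouping outlier cells. The cost is that
  populations genuinely differing in fewer than 5 genes cannot be kept
  apart.
* a **nearest-centroid refinement** (≤ 3 reassignment iterations),
  which cleans up single boundary cells the graph partition leaves in
  the wrong community.

A fixed-k KMeans path is available as an alternative. All paths are
deterministic under a fixed seed.

Cell-type assignment is cluster-level: per cluster, each registry type
scores the mean over its markers of the cluster's mean expression
scaled per gene to [0, 1] across clusters; the cluster takes the argmax
type only if the margin over the runner-up is ≥ 0.1 (which leaves exact
ties `nonassigned`); the ensemble label is inherited from the registry.
Marker ranking is a two-sided Wilcoxon rank-sum one-vs-rest per gene:
exact (full enumeration over midrank assignments) when both groups have
≤ 10 cells, otherwise the tie-corrected normal approximation without
continuity correction; BH within each group; enriched genes (positive
log2 fold-change of de-logged means with a 1e-9 pseudocount) rank ahead
of depleted ones, then by q ascending and fold descending — a marker is
by convention over-expressed in its group.

Fibrocytes are sub-clustered (KMeans, k = 5) and each sub-cluster is
called high/low on *Slc12a2*, *Gjb2*, *Car2* (scaled across
sub-clusters, high above 0.5); the 8-combination → 5-subtype mapping
ships as an editable YAML (`data/fibrocyte_map.yaml`) because the exact
combinations are a judgment call; unmapped combinations become
`fibrocyte-unresolved`.

## Tonotopy screen

Binning sorts cells by anchor expression descending with stable ties
(input order), so runs are reproducible even with tied counts; zero
anchor expression falls apex-most. When the cell count is not divisible
by the bin count, larger bins sit on the base side (N = 10 → 3, 3, 2,
2). Kruskal–Wallis is delegated to `scipy.stats.kruskal` behind the
package's surface (all-tied input short-circuits to H = 0, p = 1); an
independent from-first-principles implementation lives in the test
suite as an oracle. The Dunn–Holland–Wolfe pairwise z on joint mean
ranks is implemented here (no installed package provides it);
the pairwise adjustment is pluggable (Bonferroni default, Holm, none)
because the exact published variant of the procedure is ambiguous.
Multiple testing across genes is BH at α = 0.05. Fold-change uses
de-logged bin means (`expm1` of mean log values, i.e. a geometric-type
mean) with ε = 1e-9 guarding zeros, and the 1.3 threshold is a strict
linear-ratio inequality applied symmetrically (`max(fc, 1/fc) > 1.3`).
The calibration of the Kruskal–Wallis chi-square tail is checked at 25
cells per bin, where the nominal 5% level holds; at very small bins
(5 per group) the chi-square tail is conservative (≈ 3.5%), which the
tests document rather than hide.

A generic over-representation test (one-sided hypergeometric per
user-supplied gene set, BH across sets) stands in for database-backed
ontology analysis; no ontology content ships with the package.

## Stage contrasts and pattern clustering

Per-cell-type stage contrasts (default P8 vs P20) reuse the rank-sum
machinery; BH is applied within each cell type because each volcano is
read on its own; effects are log2 fold-changes of de-logged stage
means, so swapping the stages negates every effect and preserves every
p value. Types with fewer than 3 cells on either side are skipped with
a logged reason.

Panel profiles are mean normalized expression per (cell type, stage)
group; Z-scores use the population (n-denominator) standard deviation,
stated explicitly since both conventions are common; constant rows map
to zeros and are flagged. Hierarchical clustering uses correlation
distance and average linkage (configurable); undefined distances from
constant profiles are set to the maximum (1) with a warning. Tree cuts
come from the linkage (nested by construction; k is a user parameter,
default 20 for the deafness panel); trees serialize to Newick.

## Pipeline and determinism

A single YAML config drives simulate → QC → annotate → tonotopy →
contrast → patterns → enrichment; exactly one of an input triplet or a
simulation block must be present. One global seed fans out to per-stage
child seeds through fixed offsets, so enabling a stage never perturbs
another stage's draws; the output manifest records a SHA-256 per file,
and rerunning a config reproduces identical checksums (the config echo
omits the output directory for that reason).

## Problem sizes used in the checks

The bundled checks run at desk scale, chosen to keep every claim
testable in minutes on one CPU: the default synthetic atlas is 37
populations × 60 cells × 300 genes; the screen power fixture is 800
TBCs with 10 planted two-fold gradients among 500 nulls; null
calibrations use 10,000 Kruskal–Wallis replicates, 5,000
Dunn replicates, and 50 null screen panels. The acceptance script
rebuilds the atlas and reports the number of recovered cell types.

## Known limitations

* Cluster-level annotation cannot split a cluster containing two types
  the clustering failed to separate; the merge pass's 5-gene floor sets
  the resolution limit.
* The anchor-bin screen measures attenuated gradients: noisy anchor
  ordering shrinks every observed between-bin contrast toward 1, so
  weak gradients near the 1.3 gate are systematically under-called
  (conservative, never anti-conservative).
* With very few genes, library normalization couples genes through the
  compositional constraint; if a single gene dominates a cell's counts
  (as a strongly expressed anchor does in tiny gene panels), other
  genes acquire an artifactual opposite gradient. Fixtures use enough
  background genes to keep the anchor below a few percent of depth.
* Exact rank-sum enumeration is used only when both groups have ≤ 10
  cells; between that and the asymptotic regime, small-sample p values
  rely on the normal approximation.
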