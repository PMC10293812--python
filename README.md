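# cochlea-atlas-kit

Analysis toolkit for single-cell and single-nucleus transcriptomes of the
postnatal mouse cochlea, built for the workflows behind a cochlear
cell-type atlas: annotating the ~37 cochlear cell types from marker
genes, ranking one-vs-rest markers, screening tympanic border cells
(TBCs) for **tonotopic gradient genes** by anchor-gene pseudo-spatial
binning, contrasting maturation stages (P8 vs P20), and clustering a
deafness/key-gene panel by expression pattern. A matched synthetic-data
generator with ground truth makes every stage testable without the
deposited datasets.

Intended users: auditory-transcriptomics researchers who have 10x-style
count matrices of cochlear tissue (or want realistic synthetic ones) and
need a reproducible, scriptable version of this analysis chain.

## The core procedure

The cochlea maps sound frequency onto position (tonotopy: high
frequencies at the base, low at the apex), but droplet sequencing
destroys spatial information. The kit's centrepiece imputes position
from expression of an anchor gene, *Emilin2*, a basilar-membrane matrix
gene with a known base-to-apex expression gradient in TBCs:

1. Rank TBCs by normalized anchor expression and split them into four
   equal-sized quartile bins Q1–Q4; Q1 (strongest expression) ↔ base,
   Q4 (weakest) ↔ apex.
2. For every sufficiently detected gene, test heterogeneity across bins
   with the tie-corrected Kruskal–Wallis statistic
   `H = [12/(N(N+1)) Σ nᵢ r̄ᵢ² − 3(N+1)] / [1 − Σ(t³−t)/(N³−N)]`,
   chi-square tail with 3 df, Benjamini–Hochberg adjusted across genes.
3. Run the Dunn–Holland–Wolfe pairwise comparison on joint mean ranks,
   `z₍ᵢⱼ₎ = (r̄ᵢ − r̄ⱼ)/√{[N(N+1)/12 − Σ(t³−t)/(12(N−1))](1/nᵢ + 1/nⱼ)}`,
   Bonferroni-adjusted over the six bin pairs.
4. Keep genes whose base/apex fold-change (de-logged bin means) exceeds
   1.3 in either direction — strictly, so a ratio of exactly 1.3 fails —
   and call the direction `base_high` or `apex_high` when q < α, the
   Q1-vs-Q4 comparison is significant, and the fold-change gate passes.

Around it sit the standard atlas stages: depth normalization
(`log1p(count · 10⁴ / cell_total)`), Leiden clustering with a
cluster-validity merge, cluster-level marker-score cell-type assignment
with a `nonassigned` fallback, Wilcoxon one-vs-rest marker ranking
(exact null for small groups), per-cell-type stage volcanoes, and
correlation-distance/average-linkage clustering of gene-panel profiles.

## Worked example

Simulate 800 TBCs carrying two planted two-fold gradients (a base-high
collagen-like gene and an apex-high gene) among 200 null genes, then run
the screen:

```python
import cochlea_atlas_kit as cak
from cochlea_atlas_kit.simulate import GradientSpec

specs = (GradientSpec("Col4a3", 2.0, "base_high"),
         GradientSpec("Sptssb", 2.0, "apex_high"))
adata, truth = cak.simulate_tbc_gradient(800, specs, n_null_genes=200, seed=42)
norm = cak.normalize(adata)
results = cak.screen(norm.X, list(norm.var_names), min_frac=0.05)
print(results[results.direction != "none"]
      [["gene", "H", "q", "fc", "direction"]].round(3).to_string(index=False))
```

prints

```
   gene       H    q     fc direction
Emilin2 749.064 0.00 10.403 base_high
 Sptssb  39.017 0.00  0.480 apex_high
 Col4a3  17.996 0.03  1.581 base_high
```

Both planted genes are flagged with the correct direction and none of
the 200 null genes is called. The anchor flags itself `base_high` by
construction (the bins are defined by it); its fold-change (10.4) is the
observed Q1/Q4 ratio of its own expression. `fc` below 1 with direction
`apex_high` means the apex bin mean exceeds the base bin mean by more
than the 1.3 gate (1/0.480 ≈ 2.1).

A full pipeline (simulate → QC → annotate → tonotopy → contrast →
patterns) runs from one YAML config:

```sh
cochlea-atlas-kit run --config config.yaml
```

writing TSV result tables with provenance headers, a Newick gene tree,
and a checksummed manifest; rerunning with the same seed reproduces
identical files.

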