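# colonymorph

Quantitative morphometry of adherent stem-cell colonies from manually
traced nuclei.

Pluripotent stem-cell colonies (e.g. hESC cultures) are routinely judged by
eye: good colonies look tightly packed, with small round nuclei and sharp
edges.  `colonymorph` turns those visual impressions into numbers.  Given a
table of nucleus centroids, areas and outlines (an ImageJ "Measure"-style
CSV export) plus an optional colony boundary polygon, it computes:

- **Neighbour structure** — the Voronoi diagram and its dual Delaunay
  triangulation over nucleus centroids; per-cell neighbour counts N_n and
  intercellular distances ℓ_n, with boundary clipping and pruning of
  spurious edges across colony concavities.
- **Per-colony statistics** — mean nucleus area ⟨α⟩ with sample SD σ and
  standard error σ/√N_c, ⟨N_n⟩, ⟨ℓ_n⟩, mean area per cell A/N_c, and the
  nucleus-area probability density function.
- **Shape descriptors** (ImageJ conventions) — circularity 4πA/P², aspect
  ratio of the second-moment fitted ellipse, roundness 4A/(π·major²),
  solidity A/A_hull, and the exact maximum-caliper Feret diameter.
- **Growth scaling** — the power law N_c = κ·A^β fitted across a colony
  series by OLS in log–log space (β ≈ 1 means cells keep a constant
  footprint as colonies grow), with Tukey-boxplot outlier flagging.
- **Size segregation** — the order parameter

      δ = 1 − N_c·N_AB / (N_n·N_A·N_B)

  where an area threshold α* splits cells into small type A (α < α*) and
  large type B (α ≥ α*), and N_AB counts Delaunay adjacencies between the
  classes.  δ ≈ 0 for spatially mixed sizes (exact finite-size expectation
  −1/(N_c−1)), δ → 1 when one class forms a single compact cluster.
  Observed δ(α*) is referenced against a bootstrap null that permutes
  areas across the fixed cell positions.

Because raw microscopy data of this kind is rarely deposited, the package
includes a first-class synthetic-colony generator (jittered-lattice
packings at realistic densities, lognormal nucleus-area fields, tunable
spatial clustering of small cells, and count–area series with a prescribed
exponent) so the entire pipeline is testable end to end.

## Worked example

Generate a 600-cell colony whose small (recently divided) cells are
clustered in patches, then quantify it:

```python
from colonymorph import (SyntheticSpec, generate_colony, delaunay_graph,
                         summarize_colony, segregation_profile)

spec = SyntheticSpec(n_cells=600, label_pattern="clustered",
                     cluster_strength=0.8, seed=7)
colony, _ = generate_colony(spec)
graph = delaunay_graph(colony.centroids)

s = summarize_colony(colony, graph)
print(f"colony area A = {colony.area:.3f} mm^2, N_c = {s.n_cells}")
print(f"<alpha> = {s.mean_area:.1f} +/- {s.se_area:.1f} (+/- {s.sd_area:.1f}) um^2")
print(f"<N_n> = {s.mean_neighbors:.2f}   <l_n> = {s.mean_neighbor_distance:.1f} um")

prof = segregation_profile(colony, graph, n_boot=500, seed=1)
```

This prints

```
colony area A = 0.283 mm^2, N_c = 600
<alpha> = 214.2 +/- 4.6 (+/- 111.5) um^2
<N_n> = 5.84   <l_n> = 22.8 um
```

— a dense colony (≈2,100 cells/mm²) with mean nucleus area 214 µm² and
nearly six Delaunay neighbours per cell.  The segregation profile shows δ
far above its bootstrap null band at every threshold, e.g. at
α* = 200 µm²: δ = +0.763 against a 97.5% null quantile of +0.040 — the
small cells are strongly clustered, exactly as the generator was asked to
arrange them.  Rebuilding the same colony with `label_pattern="mixed"`
keeps δ inside the band everywhere.

The same pipeline runs from the shell:

```sh
colonymorph run --n-colonies 3 --pattern clustered --seed 5 --out-dir results/
colonymorph segregate results/colony_00.csv --n-boot 1000 --seed 5 --out delta.json
```

`run` writes per-colony summaries, the pooled area PDF, the power-law fit,
segregation profiles and a manifest recording every derived seed; reruns
with the same seed are byte-identical.

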