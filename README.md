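# asmb — community-assembly inference for soil microbiome transects

`asmb` quantifies the relative roles of **deterministic** (environmental
selection) and **stochastic** (dispersal, drift) processes in shaping soil
bacterial and archaeal β-diversity along environmental transects. It is
aimed at microbial ecologists working with rarefied OTU tables, a rooted
16S phylogeny, and per-sample environmental metadata — the standard output
of an amplicon survey — and implements the complete analysis chain used in
biogeographic studies of soil microbial communities:

- **β-diversity**: Bray–Curtis (taxonomic) and weighted UniFrac
  (phylogenetic) dissimilarities, rarefaction, abundant/rare partitioning
  (≥ 0.1% / ≤ 0.01% relative abundance).
- **Null models**: βNTI — the standardized effect size of abundance-weighted
  βMNTD under tip-label shuffling,
  βNTI = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null — and RC_Bray, the
  modified Raup–Crick index that ranks observed Bray–Curtis within a
  richness- and occupancy-constrained null, rescaled to [−1, 1]. Each pair
  of communities is assigned one of five assembly processes:
  βNTI > 2 → variable selection; βNTI < −2 → homogeneous selection;
  |βNTI| ≤ 2 with RC < −0.95 → homogenizing dispersal, RC > 0.95 →
  dispersal limitation, otherwise undominated.
- **Distance–decay**: haversine spatial distances, composite environmental
  distances (Euclidean over six group composites: historical temperature
  anomaly, contemporary climate, aboveground vegetation, soil fertility,
  soil pH, soil mineral content), OLS decay slopes on standardized
  distances, Mantel significance, and sample-level permutation contrasts of
  slopes between groups.
- **Drivers**: variation partitioning of β-diversity into unique
  environmental (a), shared (b), unique spatial (c) and residual (d)
  fractions by regression on distance matrices, with
  deterministic% = 100·a/(a+c); per-driver random-forest importance
  (out-of-bag %IncMSE).
- **Group tests**: PERMANOVA, ANOSIM, MRPP, PERMDISP, and paired
  per-taxon-group abundance contrasts between soil layers.
- **Niche breadth**: Levins' B = 1/Σ p², with paired layer t-tests and
  Tukey letters across the overall/abundant/rare community classes.
- **Synthetic transects**: a generator with known assembly regimes
  (selection strength, dispersal range, phylogenetic signal of niche
  optima) so every inference stage is validated by parameter recovery.

## Worked example

```python
import asmb

cfg = asmb.SimulationConfig(n_sites=16, n_otus=200, reads_per_sample=4000, seed=42)
table, tree, metadata = asmb.simulate_dataset(cfg)
part = asmb.partition_by_abundance(table)
print(f"table: {table.shape[0]} samples x {table.shape[1]} OTUs; "
      f"{len(part.abundant_ids)} abundant, {len(part.rare_ids)} rare")

top = metadata.subset_layer("topsoil")
bc = asmb.bray_curtis(table.subset_samples(top.sample_ids))
fit = asmb.fit_distance_decay(bc, asmb.spatial_distance(top), n_perm=999, seed=1)
print(f"topsoil distance decay: slope={fit.slope:.4f}, mantel r={fit.mantel_r:.3f}, p={fit.mantel_p:.3f}")

vp = asmb.variation_partition(bc, asmb.environmental_distance(top), asmb.spatial_distance(top))
print(f"varpart: env unique={vp.env_unique:.3f}, spatial unique={vp.spatial_unique:.3f}, "
      f"shared={vp.shared:.3f}, residual={vp.residual:.3f} -> deterministic {vp.deterministic_pct:.1f}%")

sub = table.subset_samples(top.sample_ids).drop_empty_otus()
b = asmb.bnti(sub, tree, n_rand=199, seed=2)
r = asmb.raup_crick_bray(sub, n_rand=199, seed=3)
summary = asmb.classify_processes(b, r)
print("process fractions:", {k: round(v, 3) for k, v in summary.fractions.items()})
```

prints

```
table: 32 samples x 200 OTUs; 90 abundant, 33 rare
topsoil distance decay: slope=-0.1050, mantel r=-0.394, p=0.002
varpart: env unique=0.048, spatial unique=0.012, shared=0.143, residual=0.797 -> deterministic 80.1%
process fractions: {'variable_selection': 0.6, 'homogeneous_selection': 0.0, 'homogenizing_dispersal': 0.092, 'dispersal_limitation': 0.033, 'undominated': 0.275}
```

Reading the output: community similarity decays significantly with distance
(negative slope per standardized-distance unit, Mantel p = 0.002). Of the
explained β-diversity variance, the unique environmental fraction exceeds
the unique spatial fraction (deterministic 80%), and the null models
attribute most pairwise turnover to variable selection — consistent with
the moderate-selection regime this transect was generated under.

The same analyses are available from the shell:

```bash
asmb simulate --seed 42 --out-dir data/
asmb betadiv --table data/table.tsv --metric braycurtis --out bc.tsv
asmb nullmodel --table data/table.tsv --tree data/tree.nwk --n-rand 999 --seed 1
asmb run --config run.yaml --out results/    # the full pipeline, with manifest
```

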