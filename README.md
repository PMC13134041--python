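# microterroir

Spatially explicit analysis of plot-scale microbiome surveys — built for
vineyard grape microbiota ("microbial terroir"), applicable to any design
where georeferenced samples carry amplicon (ASV) count tables.

Microbial communities on crops vary not just between farms but within a
single field.  Quantifying that variation needs a specific toolkit: even
resampling of uneven sequencing libraries, distance metrics between
communities, permutation tests that respect the spatial design, and
spatial models that interpolate diversity between sampled plants.
`microterroir` implements that pipeline end to end for ecologists and
microbiologists working with marker-gene (16S/ITS) data:

- **Feature-table hygiene** — TSV IO, removal of features unassigned at a
  chosen rank, below a read threshold, or matching organelle/host lineage
  terms (chloroplast, mitochondria, Viridiplantae, Metazoa, and domain
  Eukaryota for 16S).
- **Bootstrapped diversity** — rarefaction with replacement at fixed depth;
  alpha diversity (richness, Shannon *H* in bits) as the median of *N*
  bootstraps; beta diversity (Jaccard, Bray–Curtis) as the medoid of *N*
  bootstrap distance matrices; PCoA.
- **k-mer decomposition** — ASV counts re-expressed as k-mer counts
  (default k = 16) so that diversity reflects sequence similarity, a cheap
  stand-in for phylogenetic metrics.
- **Distance decay** — Mantel tests (Spearman ρ, label permutations)
  between community dissimilarity and haversine geodesic distance, with a
  descriptive pairwise regression.
- **Group inference** — PERMANOVA (pseudo-*F* = (SS_among/(a−1)) /
  (SS_within/(n−a)), effect size R² = SS_among/SS_total), pairwise
  PERMANOVA with BH correction and compact letter displays, stratified
  (restricted-permutation) PERMANOVA for testing cultivar after factoring
  out site, ANOVA and Spearman trends for alpha diversity.
- **Gamma accumulation** — pooled-sample gamma diversity and per-site
  sample-accumulation curves with Monte-Carlo confidence bands.
- **Kriging** — Gaussian-process interpolation of diversity surfaces with
  a Matérn kernel (ν = 1.5 default) plus white noise, fitted by maximum
  marginal likelihood with 10 optimizer restarts.
- **Synthetic vineyards** — a generator of georeferenced multinomial count
  data with site/cultivar effects, Gaussian-random-field spatial structure,
  localized rare taxa and an edge-gradient taxon, used throughout the test
  suite for calibration and power analysis.

## Worked example

```python
import microterroir as mt

cfg = mt.SimulationConfig(seed=11)           # two ~50-vine sites, 1.5 km apart
table, seqs, tax, md, truth = mt.simulate_dataset(cfg)

# medoid-of-10-bootstraps Bray-Curtis at 500 reads/sample
dm = mt.bootstrap_beta(table, "bray_curtis", depth=500, n_boot=10, seed=1)
ids = list(dm.ids)

site = mt.permanova(dm, md.column("vineyard", ids), n_perm=999, seed=2)
print(f"site PERMANOVA: R2={site.r2:.3f}, p={site.p_value:.3f}")

site1 = [s for s in ids if md.column("vineyard")[s] == "site1"]
decay = mt.distance_decay(dm.filter(site1),
                          mt.geodesic_matrix(md, sample_ids=site1),
                          n_perm=999, seed=3)
print(f"distance decay in site1: rho={decay.mantel.rho:.3f}, "
      f"p={decay.mantel.p_value:.3f}")

alpha = mt.bootstrap_alpha(table, "shannon", depth=500, n_boot=10, seed=4)
latlon = md.coords(site1)
coords = mt.project_local(latlon[:, 0], latlon[:, 1])
model = mt.fit_krige(coords, alpha.values.loc[site1].to_numpy(), seed=5)
print(f"kriged Shannon surface: length scale = {model.length_scale_:.1f} m")
```

which prints

```
site PERMANOVA: R2=0.117, p=0.001
distance decay in site1: rho=0.239, p=0.001
kriged Shannon surface: length scale = 7.6 m
```

Read: the two sites explain ~12% of community variation (p = 0.001, the
floor for 999 permutations); within one site, vines further apart host
more dissimilar communities (Mantel ρ = 0.24) — the signature of dispersal
limitation or microclimate gradients; and the fitted Shannon surface
varies on a ~8 m spatial scale.

The same pipeline runs from the shell:

```sh
microterroir simulate --out data/ --seed 42
microterroir filter --table data/table.tsv --taxonomy data/taxonomy.tsv \
    --output filtered.tsv --min-reads 2 --require-rank class --marker 16S
microterroir diversity --table filtered.tsv --output-dir div/ \
    --depth 500 --boots 10 --seed 42
microterroir test permanova --distance div/beta_bray_curtis.tsv \
    --metadata data/metadata.tsv --column vineyard --permutations 999
microterroir gamma --table filtered.tsv --metadata data/metadata.tsv \
    --group vineyard --iters 10 --seed 42 --output gamma.tsv
```

All commands are bit-reproducible for a fixed `--seed`.

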