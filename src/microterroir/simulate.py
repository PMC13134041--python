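"""Synthetic vineyard microbiome generator.

Emulates georeferenced vineyard plots with the statistical structure the
spatial analyses assume: samples on a planted grid, site and cultivar
effects on community composition, spatially autocorrelated taxon abundances
(Gaussian random fields), a pool of highly localized rare taxa, and one
"edge-gradient" taxon whose abundance tracks a coordinate axis (the
signature of a phytopathogen blowing in from a neighbouring field).

The generative model works on log-propensities: for core taxon t at vine v,

    eta(t, v) = intercept_t + site_effect(t, site(v))
                + cultivar_effect(t, cultivar(v)) + w_t * GRF_t(v) + noise

with per-taxon independent GRFs (exponential covariance) and log-normal
loadings w_t.  Relative abundances are the softmax over taxa within each
vine — effects are therefore compositional, the way amplicon counts behave
— and reads are multinomial draws at fixed depth (optionally with a
negative-binomial total depth for uneven libraries).

Defaults describe a pair of ~50-vine sampling grids a couple of kilometres
apart, with site effects dominating cultivar effects and a spatial
correlation length well inside the plot extent, so distance decay is
detectable within a single site.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spatial import project_local, unproject_local
from .tables import (FeatureTable, FeatureTableError, SampleMetadata,
                     SequenceCatalog, TaxonomyTable)

_CONTAMINANT_LINEAGES = (
    "d__Bacteria; p__Cyanobacteria; c__Cyanobacteriia; o__Chloroplast; "
    "f__Chloroplast; g__Chloroplast; s__uncultured_chloroplast",
    "d__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rickettsiales; "
    "f__Mitochondria; g__Mitochondria; s__uncultured_mitochondria",
    "d__Eukaryota; p__Streptophyta; c__Magnoliopsida; o__Vitales; "
    "f__Vitaceae; g__Vitis; s__Viridiplantae_host",
    "d__Eukaryota; p__Arthropoda; c__Insecta; o__Diptera; "
    "f__Drosophilidae; g__Drosophila; s__Metazoa_visitor",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic vineyard.

    Spatial layout is a regular grid of vines per site; effect sizes are
    standard deviations on the log-propensity scale; ``length_scale`` is
    the e-folding distance (meters) of the exponential spatial covariance.
    """

    n_rows: int = 7
    vines_per_row: int = 7
    row_spacing: float = 10.0     # m between sampled rows
    vine_spacing: float = 8.0     # m between sampled vines within a row
    origin: tuple[float, float] = (38.45, -122.70)  # (lat, lon), Sonoma-like
    orientation: float = 0.0      # degrees from north of the within-row axis
    n_sites: int = 2
    site_offset: float = 1500.0   # m easting between site origins
    n_taxa_core: int = 50
    n_taxa_rare: int = 20
    n_contaminants: int = 0
    depth: int = 2000             # reads per sample
    depth_dispersion: float | None = None  # NB dispersion of total depth; None = fixed
    sigma_taxon: float = 1.0      # taxon intercept spread (community unevenness)
    sigma_site: float = 2.0
    sigma_cultivar: float = 0.5
    sigma_spatial: float = 1.5
    length_scale: float = 20.0    # m
    sigma_noise: float = 0.5
    loading_sigma: float = 0.5    # log-sd of per-taxon spatial loadings w_t
    cultivar_layout: str = "interplanted"   # or "monoclonal"
    cultivar_proportions: dict[str, float] = field(default_factory=lambda: {
        "Zinfandel": 0.6, "Carignane": 0.25, "PetiteSirah": 0.15})
    monoclonal_cultivar: str = "Chardonnay"
    rare_radius: float = 10.0     # m around each rare taxon's focal vine
    rare_level: float = -1.0      # log-propensity of a rare taxon near its focus
    gradient_axis: str = "lon"    # coordinate the edge taxon tracks
    gradient_slope: float = 0.18  # log-propensity per meter along the axis
    gradient_intercept: float = 0.5
    seq_length: int = 150
    seed: int | None = 0

    def __post_init__(self) -> None:
        for name in ("sigma_taxon", "sigma_site", "sigma_cultivar",
                     "sigma_spatial", "sigma_noise"):
            if getattr(self, name) < 0:
                raise FeatureTableError(f"{name} must be >= 0")
        if self.row_spacing <= 0 or self.vine_spacing <= 0:
            raise FeatureTableError("spacings must be > 0")
        if self.cultivar_layout == "interplanted":
            total = sum(self.cultivar_proportions.values())
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise FeatureTableError("cultivar proportions must sum to 1")
        elif self.cultivar_layout != "monoclonal":
            raise FeatureTableError("cultivar_layout must be monoclonal or interplanted")
        if self.gradient_axis not in ("lat", "lon"):
            raise FeatureTableError("gradient_axis must be 'lat' or 'lon'")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load from a flat key=value text file (``#`` comments allowed)."""
        kwargs: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in fields:
                    raise FeatureTableError(f"unknown config key {key!r}")
                if key == "origin":
                    kwargs[key] = tuple(float(v) for v in raw.split(","))
                elif key == "cultivar_proportions":
                    pairs = [p.split(":") for p in raw.split(",")]
                    kwargs[key] = {k.strip(): float(v) for k, v in pairs}
                elif key in ("cultivar_layout", "gradient_axis",
                             "monoclonal_cultivar"):
                    kwargs[key] = raw
                elif key in ("depth_dispersion", "seed") and raw.lower() == "none":
                    kwargs[key] = None
                else:
                    val = float(raw)
                    kwargs[key] = int(val) if val == int(val) and fields[key].type == "int" else val
        for key in ("n_rows", "vines_per_row", "n_sites", "n_taxa_core",
                    "n_taxa_rare", "n_contaminants", "depth", "seq_length", "seed"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = int(kwargs[key])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Layout


def make_layout(config: SimulationConfig, rng=None) -> SampleMetadata:
    """Lay vines out on rotated regular grids, one per site.

    ``orientation`` is the compass bearing of the within-row direction:
    0 means rows run north–south (vine position varies in latitude), 90
    means east–west.  Planar positions are converted to WGS84 by inverse
    equirectangular projection about the configured origin.
    """
    if config.n_rows < 1 or config.vines_per_row < 1:
        raise FeatureTableError("need at least one row and one vine")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    theta = math.radians(config.orientation)
    rows = []
    for si in range(config.n_sites):
        for r in range(config.n_rows):
            for v in range(config.vines_per_row):
                along = v * config.vine_spacing
                across = r * config.row_spacing
                x = across * math.cos(theta) + along * math.sin(theta)
                y = -across * math.sin(theta) + along * math.cos(theta)
                rows.append({
                    "sample_id": f"S{si + 1}R{r + 1:02d}V{v + 1:02d}",
                    "vineyard": f"site{si + 1}",
                    "row": r + 1, "vine": v + 1,
                    "_x": x + si * config.site_offset, "_y": y,
                })
    df = pd.DataFrame(rows).set_index("sample_id")
    latlon = unproject_local(df[["_x", "_y"]].to_numpy(), config.origin)
    df["latitude"], df["longitude"] = latlon[:, 0], latlon[:, 1]
    if config.cultivar_layout == "monoclonal":
        df["cultivar"] = config.monoclonal_cultivar
    else:
        names = list(config.cultivar_proportions)
        probs = np.array([config.cultivar_proportions[c] for c in names])
        df["cultivar"] = rng.choice(names, size=len(df), p=probs)
    df = df.drop(columns=["_x", "_y"])
    df.index.name = None
    return SampleMetadata(df[["vineyard", "cultivar", "latitude", "longitude",
                              "row", "vine"]])


# ---------------------------------------------------------------------------
# Gaussian random fields


def sample_grf(coords, length_scale: float, variance: float, seed=None) -> np.ndarray:
    """Draw a zero-mean Gaussian random field at the given planar points.

    Exponential covariance C(d) = variance * exp(-d / length_scale)
    (Matérn nu = 1/2), realised by Cholesky factorisation with a 1e-10
    diagonal jitter.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise FeatureTableError("coords must be a non-empty (n, d) array")
    if length_scale <= 0:
        raise FeatureTableError("length_scale must be > 0")
    n = coords.shape[0]
    if variance == 0:
        return np.zeros(n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    cov = variance * np.exp(-d / length_scale) + 1e-10 * np.eye(n)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise FeatureTableError("covariance not positive definite after jitter") from exc
    return chol @ rng.standard_normal(n)


# ---------------------------------------------------------------------------
# Dataset simulation


@dataclass
class SimulationTruth:
    """Ground-truth effect values stored for recovery tests."""

    intercepts: pd.Series
    site_effects: pd.DataFrame        # taxa x sites
    cultivar_effects: pd.DataFrame    # taxa x cultivars
    loadings: pd.Series               # w_t per core taxon
    grf: pd.DataFrame                 # core taxa x samples (spatial fields)
    relative_abundance: pd.DataFrame  # samples x all taxa (pre-multinomial)
    gradient_taxon: str | None
    gradient_axis: str
    gradient_slope: float
    rare_focal: dict[str, str]        # rare taxon -> focal sample id


def _random_sequences(rng, n: int, length: int) -> list[str]:
    alphabet = np.array(list("ACGT"))
    return ["".join(alphabet[rng.integers(0, 4, size=length)]) for _ in range(n)]


def _core_lineage(i: int) -> str:
    return (f"d__Bacteria; p__Phylum{i % 7 + 1}; c__Class{i % 11 + 1}; "
            f"o__Order{i % 13 + 1}; f__Family{i % 17 + 1}; "
            f"g__Genus{i + 1}; s__Species{i + 1}")


def simulate_dataset(config: SimulationConfig):
    """Generate a complete synthetic dataset.

    Returns ``(table, sequences, taxonomy, metadata, truth)`` where the
    table holds multinomial read counts at the configured depth, and
    ``truth`` records every effect used so recovery tests can compare
    estimates against it.  The same seed always yields bit-identical output.
    """
    if config.depth < 1:
        raise FeatureTableError("depth must be >= 1")
    rng = np.random.default_rng(config.seed)
    metadata = make_layout(config, rng)
    sample_ids = metadata.sample_ids
    n = len(sample_ids)
    latlon = metadata.coords()
    coords = project_local(latlon[:, 0], latlon[:, 1], origin=config.origin)
    sites = metadata.column("vineyard").to_numpy()
    cultivars = metadata.column("cultivar").to_numpy()
    site_levels = list(pd.unique(sites))
    cult_levels = list(pd.unique(cultivars))

    # coordinates relative to each site's centroid, so within-site spatial
    # structure is unaffected by where the site sits on the globe
    rel = coords.copy()
    for s in site_levels:
        mask = sites == s
        rel[mask] -= rel[mask].mean(axis=0)

    nc = config.n_taxa_core
    core_ids = [f"ASV{i + 1:04d}" for i in range(nc)]
    intercepts = rng.normal(0.0, config.sigma_taxon, size=nc)
    site_eff = rng.normal(0.0, config.sigma_site, size=(nc, len(site_levels)))
    cult_eff = rng.normal(0.0, config.sigma_cultivar, size=(nc, len(cult_levels)))
    loadings = rng.lognormal(0.0, config.loading_sigma, size=nc)
    site_idx = np.array([site_levels.index(s) for s in sites])
    cult_idx = np.array([cult_levels.index(c) for c in cultivars])

    grf = np.zeros((nc, n))
    for t in range(nc):
        grf[t] = sample_grf(coords, config.length_scale,
                            config.sigma_spatial ** 2, seed=rng)
    noise = rng.normal(0.0, config.sigma_noise, size=(nc, n))
    eta_core = (intercepts[:, None] + site_eff[:, site_idx]
                + cult_eff[:, cult_idx] + loadings[:, None] * grf + noise)

    all_ids = list(core_ids)
    etas = [eta_core]
    lineages = {fid: _core_lineage(i) for i, fid in enumerate(core_ids)}

    rare_focal: dict[str, str] = {}
    if config.n_taxa_rare:
        rare_ids = [f"RARE{i + 1:04d}" for i in range(config.n_taxa_rare)]
        eta_rare = np.full((config.n_taxa_rare, n), -np.inf)
        for i, fid in enumerate(rare_ids):
            focus = int(rng.integers(n))
            rare_focal[fid] = sample_ids[focus]
            dist = np.sqrt(((coords - coords[focus]) ** 2).sum(axis=1))
            eta_rare[i, dist <= config.rare_radius] = config.rare_level
            lineages[fid] = _core_lineage(nc + i)
        all_ids += rare_ids
        etas.append(eta_rare)

    gradient_id: str | None = None
    if config.gradient_slope != 0:
        gradient_id = "GRAD0001"
        axis = 0 if config.gradient_axis == "lon" else 1
        eta_grad = (config.gradient_intercept
                    + config.gradient_slope * rel[:, axis])[None, :]
        all_ids.append(gradient_id)
        etas.append(eta_grad)
        lineages[gradient_id] = (
            "d__Fungi; p__Ascomycota; c__Leotiomycetes; o__Helotiales; "
            "f__Erysiphaceae; g__EdgeMold; s__edge_gradient")

    if config.n_contaminants:
        cont_ids = [f"CONT{i + 1:04d}" for i in range(config.n_contaminants)]
        eta_cont = rng.normal(-1.0, 0.5, size=(config.n_contaminants, 1)) \
            + np.zeros((config.n_contaminants, n))
        for i, fid in enumerate(cont_ids):
            lineages[fid] = _CONTAMINANT_LINEAGES[i % len(_CONTAMINANT_LINEAGES)]
        all_ids += cont_ids
        etas.append(eta_cont)

    eta = np.vstack(etas)  # taxa x samples
    eta_shift = eta - np.nanmax(np.where(np.isfinite(eta), eta, -np.inf),
                                axis=0, keepdims=True)
    expeta = np.where(np.isfinite(eta_shift), np.exp(eta_shift), 0.0)
    probs = expeta / expeta.sum(axis=0, keepdims=True)

    counts = np.zeros((n, len(all_ids)), dtype=np.int64)
    for j in range(n):
        depth = config.depth
        if config.depth_dispersion is not None:
            k = config.depth_dispersion
            depth = max(1, int(rng.negative_binomial(k, k / (k + config.depth))))
        counts[j] = rng.multinomial(depth, probs[:, j])

    table = FeatureTable(pd.DataFrame(counts, index=sample_ids, columns=all_ids))
    sequences = SequenceCatalog(dict(zip(
        all_ids, _random_sequences(rng, len(all_ids), config.seq_length))))
    taxonomy = TaxonomyTable({fid: lineages[fid] for fid in all_ids},
                             {fid: 0.99 for fid in all_ids})
    truth = SimulationTruth(
        intercepts=pd.Series(intercepts, index=core_ids),
        site_effects=pd.DataFrame(site_eff, index=core_ids, columns=site_levels),
        cultivar_effects=pd.DataFrame(cult_eff, index=core_ids, columns=cult_levels),
        loadings=pd.Series(loadings, index=core_ids),
        grf=pd.DataFrame(grf, index=core_ids, columns=sample_ids),
        relative_abundance=pd.DataFrame(probs.T, index=sample_ids, columns=all_ids),
        gradient_taxon=gradient_id,
        gradient_axis=config.gradient_axis,
        gradient_slope=config.gradient_slope,
        rare_focal=rare_focal,
    )
    return table, sequences, taxonomy, metadata, truth


def write_dataset(out_dir, table: FeatureTable, sequences: SequenceCatalog,
                  taxonomy: TaxonomyTable, metadata: SampleMetadata) -> None:
    """Write a simulated dataset in the TSV/FASTA dialects the pipeline reads."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.write_tsv(out / "table.tsv")
    sequences.write_fasta(out / "sequences.fasta")
    taxonomy.write_tsv(out / "taxonomy.tsv")
    metadata.write_tsv(out / "metadata.tsv")
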