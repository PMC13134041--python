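"""Feature tables, sequences, taxonomy and sample metadata: containers, IO, filtering.

The central currency of the pipeline is the :class:`FeatureTable`, a
samples-by-features matrix of non-negative integer read counts (e.g. ASV
counts from an amplicon survey).  The canonical on-disk dialect is TSV with
features as rows and samples as columns — the orientation most amplicon
exports use — with a ``transpose`` flag for samples-as-rows files.

Filtering implements the standard amplicon hygiene rules: drop features
unassigned at a required taxonomic rank, drop features below a minimum total
read count, and drop features whose lineage matches host/organelle
contaminant terms (chloroplast, mitochondria, Viridiplantae, Metazoa; plus
domain Eukaryota for 16S data).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Lineage substrings removed by default (case-insensitive).
DEFAULT_EXCLUDE_TERMS = ("chloroplast", "mitochondria", "viridiplantae", "metazoa")

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")


class FeatureTableError(ValueError):
    """Raised on malformed or inconsistent feature-table input."""


@dataclass
class FeatureTable:
    """Samples-by-features matrix of non-negative integer counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample id, columns by feature id, integer counts.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate feature ids: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)):
                raise FeatureTableError("counts must be finite")
            if np.any(values != np.floor(values)):
                raise FeatureTableError("counts must be integers")
            df = df.astype(np.int64)
        if values.size and df.to_numpy().min() < 0:
            raise FeatureTableError("counts must be non-negative")
        self.data = df.astype(np.int64) if values.size else df.astype(np.int64)

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as an int array of shape (n_samples, n_features)."""
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def feature_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def filter_samples(self, keep: Sequence[str]) -> "FeatureTable":
        missing = set(keep) - set(self.data.index)
        if missing:
            raise FeatureTableError(f"unknown sample ids: {sorted(missing)}")
        return FeatureTable(self.data.loc[list(keep)].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.data.equals(other.data)

    # -- IO ----------------------------------------------------------------
    def write_tsv(self, path, transpose: bool = False) -> None:
        """Write as TSV, features-as-rows by default (the canonical dialect)."""
        out = self.data if transpose else self.data.T
        label = "#SampleID" if transpose else "#FeatureID"
        out.to_csv(path, sep="\t", index_label=label)


def read_feature_table(path, format: str = "tsv", transpose: bool = False) -> FeatureTable:
    """Read a feature table.

    The canonical TSV dialect has features as rows and samples as columns,
    first column the feature id.  Pass ``transpose=True`` for files with
    samples as rows.

    Raises
    ------
    FeatureTableError
        On duplicate ids, negative or non-integer counts, or ragged rows.
    """
    if format == "biom":
        raise FeatureTableError(
            "BIOM input is not enabled in this build; convert to TSV "
            "(e.g. `biom convert --to-tsv`) and use format='tsv'"
        )
    if format != "tsv":
        raise FeatureTableError(f"unknown format: {format!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    col_ids = header[1:]
    if len(set(col_ids)) != len(col_ids):
        dups = sorted({c for c in col_ids if col_ids.count(c) > 1})
        raise FeatureTableError(f"duplicate column ids in {path}: {dups}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FeatureTableError(f"malformed TSV {path}: {exc}") from exc
    if df.isna().to_numpy().any():
        raise FeatureTableError(f"ragged or missing cells in {path}")
    try:
        df = df.astype(np.float64)
    except ValueError as exc:
        raise FeatureTableError(f"non-numeric cell in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    if not transpose:
        df = df.T
    return FeatureTable(df)


# ---------------------------------------------------------------------------
# Sequences


@dataclass
class SequenceCatalog:
    """Mapping of feature id to DNA sequence over {A, C, G, T, N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for fid, seq in self.sequences.items():
            if not seq:
                raise FeatureTableError(f"empty sequence for feature {fid!r}")
            if not set(seq.upper()) <= set("ACGTN"):
                bad = sorted(set(seq.upper()) - set("ACGTN"))
                raise FeatureTableError(f"invalid characters {bad} in sequence {fid!r}")
        self.sequences = {fid: seq.upper() for fid, seq in self.sequences.items()}

    def __getitem__(self, fid: str) -> str:
        return self.sequences[fid]

    def __contains__(self, fid: str) -> bool:
        return fid in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=fid, description="")
            for fid, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")


def read_sequences(path) -> SequenceCatalog:
    """Read a FASTA file of feature sequences."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FeatureTableError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    return SequenceCatalog(seqs)


# ---------------------------------------------------------------------------
# Taxonomy


def parse_lineage(lineage: str) -> list[str]:
    """Split a rank-delimited lineage string into rank names.

    Splits on ``;``, strips whitespace and rank prefixes of the form
    ``x__``.  An absent or empty entry yields an empty string (unassigned at
    that rank).  Covers both SILVA- and UNITE-style lineage strings.
    """
    parts = [p.strip() for p in lineage.split(";")]
    return [_RANK_PREFIX.sub("", p).strip() for p in parts]


@dataclass
class TaxonomyTable:
    """Per-feature lineage strings with optional classifier confidence."""

    lineages: dict[str, str]
    confidence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fid, conf in self.confidence.items():
            if not (0.0 <= conf <= 1.0):
                raise FeatureTableError(
                    f"confidence for {fid!r} outside [0, 1]: {conf}"
                )

    def __contains__(self, fid: str) -> bool:
        return fid in self.lineages

    def ranks(self, fid: str) -> list[str]:
        return parse_lineage(self.lineages[fid])

    def assigned_at(self, fid: str, rank: str) -> bool:
        """Whether the feature has a non-empty assignment at ``rank``."""
        rank = rank.lower()
        if rank not in RANKS:
            raise FeatureTableError(f"unknown rank {rank!r}; expected one of {RANKS}")
        idx = RANKS.index(rank)
        parts = self.ranks(fid)
        return idx < len(parts) and parts[idx] != ""

    def write_tsv(self, path) -> None:
        rows = []
        for fid, lin in self.lineages.items():
            row = {"Feature ID": fid, "Taxon": lin}
            if fid in self.confidence:
                row["Confidence"] = self.confidence[fid]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> TaxonomyTable:
    """Read a taxonomy TSV (feature id, lineage string, optional confidence)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FeatureTableError(f"taxonomy file {path} needs >= 2 columns")
    fids = df.iloc[:, 0].astype(str)
    if fids.duplicated().any():
        raise FeatureTableError(f"duplicate feature ids in taxonomy {path}")
    lineages = dict(zip(fids, df.iloc[:, 1].fillna("")))
    confidence: dict[str, float] = {}
    if df.shape[1] >= 3:
        conf = pd.to_numeric(df.iloc[:, 2], errors="coerce")
        confidence = {
            fid: float(c) for fid, c in zip(fids, conf) if np.isfinite(c)
        }
    return TaxonomyTable(lineages, confidence)


# ---------------------------------------------------------------------------
# Sample metadata


@dataclass
class SampleMetadata:
    """Per-sample grouping factors and WGS84 coordinates.

    Expected columns: ``vineyard``, ``cultivar``, ``latitude``, ``longitude``;
    optional: ``row``, ``vine``, ``vine_group``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FeatureTableError("duplicate sample ids in metadata")
        for col, lo, hi in (("latitude", -90.0, 90.0), ("longitude", -180.0, 180.0)):
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce")
                bad = df.index[(vals < lo) | (vals > hi)].tolist()
                if bad:
                    raise FeatureTableError(f"{col} out of range for samples {bad}")
                df[col] = vals

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def coords(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """(latitude, longitude) array in degrees; errors on missing values."""
        df = self.data if sample_ids is None else self.data.loc[list(sample_ids)]
        for col in ("latitude", "longitude"):
            if col not in df.columns:
                raise FeatureTableError(f"metadata lacks a {col!r} column")
            missing = df.index[df[col].isna()].tolist()
            if missing:
                raise FeatureTableError(f"missing {col} for samples {missing}")
        return df[["latitude", "longitude"]].to_numpy(dtype=float)

    def column(self, name: str, sample_ids: Sequence[str] | None = None) -> pd.Series:
        if name not in self.data.columns:
            raise FeatureTableError(f"metadata lacks a {name!r} column")
        if sample_ids is None:
            return self.data[name]
        return self.data.loc[list(sample_ids), name]

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="#SampleID")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return SampleMetadata(df)


# ---------------------------------------------------------------------------
# Filtering and merging


def filter_features(
    table: FeatureTable,
    taxonomy: TaxonomyTable,
    min_reads: int = 2,
    exclude_terms: Iterable[str] = DEFAULT_EXCLUDE_TERMS,
    require_rank: str | None = "class",
    marker: str | None = None,
) -> FeatureTable:
    """Apply amplicon feature-hygiene filters.

    Removes features that are (i) unassigned at ``require_rank``, (ii) below
    ``min_reads`` total count across all samples, or (iii) whose lineage
    contains any of ``exclude_terms`` (case-insensitive substring match).
    For ``marker="16S"``, features whose domain is Eukaryota are also removed
    (host and other eukaryotic off-target reads in a prokaryotic survey).

    Samples left with zero total reads are retained and logged; dropping
    shallow samples is a rarefaction-depth decision, kept orthogonal here.
    """
    if min_reads < 0:
        raise FeatureTableError("min_reads must be >= 0")
    missing = [f for f in table.feature_ids if f not in taxonomy]
    if missing:
        raise FeatureTableError(f"features missing from taxonomy: {missing[:5]}")
    terms = [t.lower() for t in exclude_terms]
    totals = table.feature_totals()
    keep = []
    for fid in table.feature_ids:
        lineage = taxonomy.lineages[fid]
        low = lineage.lower()
        if require_rank is not None and not taxonomy.assigned_at(fid, require_rank):
            continue
        if totals[fid] < min_reads:
            continue
        if any(t in low for t in terms):
            continue
        if marker is not None and marker.upper() == "16S":
            parts = taxonomy.ranks(fid)
            if parts and parts[0].lower() == "eukaryota":
                continue
        keep.append(fid)
    out = FeatureTable(table.data[keep].copy())
    if not keep:
        warnings.warn("all features removed by filtering", stacklevel=2)
    empty = out.data.index[out.sample_totals() == 0].tolist()
    if empty:
        logger.info("samples with zero reads after filtering: %s", empty)
    logger.info(
        "filter_features kept %d/%d features", len(keep), table.n_features
    )
    return out


def merge_tables(a: FeatureTable, b: FeatureTable,
                 prefixes: tuple[str, str] | None = None) -> FeatureTable:
    """Merge two tables over the intersection of their samples.

    Feature id spaces must be disjoint; pass ``prefixes=(pa, pb)`` to
    namespace the ids first.  The merged feature set is the union; the
    merged sample set is the intersection (samples missing from either
    table carry no counts there, so only shared samples are comparable).
    """
    da, db = a.data, b.data
    if prefixes is not None:
        pa, pb = prefixes
        da = da.rename(columns=lambda c: f"{pa}{c}")
        db = db.rename(columns=lambda c: f"{pb}{c}")
    overlap = set(da.columns) & set(db.columns)
    if overlap:
        raise FeatureTableError(
            f"overlapping feature ids (pass prefixes= to namespace): "
            f"{sorted(overlap)[:5]}"
        )
    shared = [s for s in da.index if s in set(db.index)]
    if not shared:
        raise FeatureTableError("no samples in common between tables")
    merged = pd.concat([da.loc[shared], db.loc[shared]], axis=1)
    return FeatureTable(merged)
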