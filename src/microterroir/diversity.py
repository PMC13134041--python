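"""Bootstrapped rarefaction, k-mer decomposition, alpha/beta diversity, PCoA.

Alpha and beta diversity are estimated on even subsamples of each sample's
reads (rarefaction).  The bootstrap scheme resamples reads WITH replacement
at a fixed depth, repeats ``n_boot`` times, and summarises: alpha metrics by
the element-wise median across bootstraps, distance matrices by the medoid
(the bootstrap matrix minimising total Frobenius distance to the others).

Shannon entropy is reported in bits (log base 2) throughout.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .tables import FeatureTable, FeatureTableError, SequenceCatalog

logger = logging.getLogger(__name__)

ALPHA_METRICS = ("observed_features", "shannon")
BETA_METRICS = ("jaccard", "bray_curtis")


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Rarefaction


def rarefy(table: FeatureTable, depth: int, with_replacement: bool = False,
           seed=None) -> FeatureTable:
    """Evenly subsample every sample to ``depth`` reads.

    Without replacement (classical rarefaction) samples shallower than
    ``depth`` are dropped and logged.  With replacement (the bootstrap mode)
    reads are redrawn multinomially from the sample's observed proportions,
    so any sample with at least one read is retained.

    Every retained output sample totals exactly ``depth``.
    """
    if depth <= 0:
        raise FeatureTableError("rarefaction depth must be >= 1")
    rng = _as_rng(seed)
    counts = table.counts
    totals = counts.sum(axis=1)
    rows = []
    kept = []
    dropped = []
    for i, sid in enumerate(table.sample_ids):
        total = totals[i]
        if with_replacement:
            if total < 1:
                dropped.append(sid)
                continue
            row = rng.multinomial(depth, counts[i] / total)
        else:
            if total < depth:
                dropped.append(sid)
                continue
            row = rng.multivariate_hypergeometric(counts[i], depth)
        rows.append(row)
        kept.append(sid)
    if dropped:
        logger.info("rarefy dropped %d shallow/empty samples: %s",
                    len(dropped), dropped[:10])
    if not kept:
        raise FeatureTableError(f"no samples survive rarefaction at depth {depth}")
    data = pd.DataFrame(np.asarray(rows, dtype=np.int64),
                        index=kept, columns=table.feature_ids)
    return FeatureTable(data)


# ---------------------------------------------------------------------------
# Alpha diversity


def alpha_diversity(counts, metric: str) -> float:
    """Alpha diversity of a single count vector.

    ``observed_features``: number of features with count > 0.
    ``shannon``: Shannon entropy in bits, -sum p_i log2 p_i over p_i > 0.

    An all-zero vector gives richness 0; Shannon is undefined there and
    returns 0 with a warning.
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise FeatureTableError("counts must be non-negative")
    if metric == "observed_features":
        return float(np.count_nonzero(x))
    if metric == "shannon":
        total = x.sum()
        if total == 0:
            warnings.warn("Shannon undefined for an all-zero sample; returning 0",
                          stacklevel=2)
            return 0.0
        p = x[x > 0] / total
        return float(-(p * np.log2(p)).sum())
    raise FeatureTableError(f"unknown alpha metric {metric!r}; use one of {ALPHA_METRICS}")


@dataclass
class AlphaVector:
    """Per-sample alpha-diversity values for one metric."""

    values: pd.Series
    metric: str

    def __getitem__(self, sid: str) -> float:
        return float(self.values[sid])


def bootstrap_alpha(table: FeatureTable, metric: str, depth: int,
                    n_boot: int = 10, seed=None) -> AlphaVector:
    """Median-of-bootstraps alpha diversity.

    Each bootstrap is a with-replacement rarefaction to ``depth``; the
    metric is computed per sample in each bootstrap and the element-wise
    median across the ``n_boot`` replicates is returned.
    """
    if n_boot < 1:
        raise FeatureTableError("n_boot must be >= 1")
    rng = _as_rng(seed)
    boots = []
    ids = None
    for _ in range(n_boot):
        rt = rarefy(table, depth, with_replacement=True, seed=rng)
        vals = pd.Series(
            [alpha_diversity(row, metric) for row in rt.counts], index=rt.sample_ids
        )
        if ids is None:
            ids = rt.sample_ids
        boots.append(vals.loc[ids])
    med = pd.concat(boots, axis=1).median(axis=1)
    med.name = metric
    return AlphaVector(med, metric)


# ---------------------------------------------------------------------------
# Beta diversity


def beta_diversity(table: FeatureTable, metric: str) -> DistanceMatrix:
    """Pairwise community dissimilarity.

    ``jaccard`` works on presence/absence: 1 - |A ∩ B| / |A ∪ B|.
    ``bray_curtis`` works on counts: sum |u_i - v_i| / sum (u_i + v_i).

    Pairs of all-zero samples get distance 0 by convention (logged), so the
    matrix stays finite for downstream permutation tests.
    """
    if table.n_samples < 2:
        raise FeatureTableError("beta diversity needs >= 2 samples")
    x = table.counts.astype(float)
    if metric == "jaccard":
        b = (x > 0).astype(float)
        inter = b @ b.T
        sizes = b.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - inter / union
        empty_pairs = union == 0
    elif metric == "bray_curtis":
        num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
        den = x.sum(axis=1)[:, None] + x.sum(axis=1)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = num / den
        empty_pairs = den == 0
    else:
        raise FeatureTableError(f"unknown beta metric {metric!r}; use one of {BETA_METRICS}")
    if empty_pairs.any():
        logger.warning("all-zero sample pair(s): distance set to 0 by convention")
        d = np.where(empty_pairs, 0.0, d)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, ids=table.sample_ids)


def medoid_index(matrices: list[np.ndarray]) -> int:
    """Index of the matrix minimising summed Frobenius distance to the rest.

    Ties break to the lowest index, so the result is deterministic and
    independent of generation order beyond the list order itself.
    """
    stack = np.asarray(matrices, dtype=float)
    n = len(stack)
    cost = np.zeros(n)
    for i in range(n):
        diffs = stack - stack[i]
        cost[i] = np.sqrt((diffs ** 2).sum(axis=(1, 2))).sum()
    return int(np.argmin(cost))


def bootstrap_beta(table: FeatureTable, metric: str, depth: int,
                   n_boot: int = 10, seed=None) -> DistanceMatrix:
    """Medoid-of-bootstraps distance matrix.

    The metric is computed on each of ``n_boot`` with-replacement
    rarefactions; the bootstrap whose distance matrix minimises the sum of
    Frobenius distances to the others is returned.  The medoid is always a
    member of the bootstrap set, so it is a realisable distance matrix.
    """
    if n_boot < 1:
        raise FeatureTableError("n_boot must be >= 1")
    rng = _as_rng(seed)
    mats = []
    ids = None
    for _ in range(n_boot):
        rt = rarefy(table, depth, with_replacement=True, seed=rng)
        dm = beta_diversity(rt, metric)
        if ids is None:
            ids = dm.ids
        mats.append(dm.filter(ids).data)
    best = medoid_index(mats)
    return DistanceMatrix(mats[best], ids=ids)


# ---------------------------------------------------------------------------
# k-mer decomposition


def kmerize(table: FeatureTable, sequences: SequenceCatalog, k: int = 16) -> FeatureTable:
    """Decompose a feature table into k-mer counts.

    Each feature's reads are replaced by the k-mers of its sequence: the
    count of k-mer m in sample s is the sum over features of
    count(s, f) x occurrences(m, seq(f)).  This acts as a cheap
    pseudo-phylogenetic representation — sequence-similar features share
    k-mers, so k-mer tables blend abundance with sequence identity.

    k-mers containing N are skipped.  The default k=16 is configurable;
    reverse complements are not collapsed.
    """
    if k < 1:
        raise FeatureTableError("k must be >= 1")
    missing = [f for f in table.feature_ids if f not in sequences]
    if missing:
        raise FeatureTableError(f"features without sequences: {missing[:5]}")
    shortest = min(len(sequences[f]) for f in table.feature_ids) if table.feature_ids else 0
    if table.feature_ids and k > shortest:
        raise FeatureTableError(
            f"k={k} exceeds shortest sequence length {shortest}"
        )
    kmer_ids: dict[str, int] = {}
    per_feature: list[Counter] = []
    for fid in table.feature_ids:
        seq = sequences[fid]
        cnt: Counter = Counter()
        for i in range(len(seq) - k + 1):
            mer = seq[i:i + k]
            if "N" in mer:
                continue
            cnt[mer] += 1
        per_feature.append(cnt)
        for mer in cnt:
            kmer_ids.setdefault(mer, len(kmer_ids))
    occ = np.zeros((table.n_features, len(kmer_ids)), dtype=np.int64)
    for j, cnt in enumerate(per_feature):
        for mer, c in cnt.items():
            occ[j, kmer_ids[mer]] = c
    data = pd.DataFrame(table.counts @ occ, index=table.sample_ids,
                        columns=list(kmer_ids))
    return FeatureTable(data)


# ---------------------------------------------------------------------------
# Principal coordinates analysis


@dataclass
class OrdinationResult:
    """Classical-MDS embedding of a distance matrix.

    ``coordinates`` holds one row per sample, columns PC1.. for each
    positive eigenvalue; ``eigenvalues`` includes negative ones (reported
    but excluded from coordinates); ``proportion_explained`` normalises by
    the sum of positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis (classical metric MDS).

    Double-centres -0.5 D^2, eigendecomposes, and scales eigenvectors by
    the square roots of the positive eigenvalues.  Negative eigenvalues
    (non-Euclidean distances) are reported but contribute no axes.
    """
    n = dm.shape[0]
    if n < 3:
        raise FeatureTableError("pcoa needs >= 3 samples")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals).max(), 1.0) * 1e-12 * n
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    pos_sum = vals[pos].sum()
    prop = vals[pos] / pos_sum if pos_sum > 0 else np.zeros(pos.sum())
    cols = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=vals,
        proportion_explained=prop,
    )
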