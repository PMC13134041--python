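"""Spatial statistics: geodesic distances, Mantel distance decay, kriging, screening.

Distance decay — the rise of community dissimilarity with geographic
distance — is the classic signature of dispersal limitation.  Inference
uses the Mantel permutation test (Spearman correlation between distance
matrices); the pairwise OLS regression reported alongside is descriptive
only, since sample pairs are not independent.

Spatial interpolation uses Gaussian-process regression (kriging) with a
Matérn covariance plus a white-noise term, fitted by maximising the log
marginal likelihood from multiple restarts.  Coordinates are projected to
local planar meters (equirectangular about the centroid) before fitting —
vineyard extents are tiny relative to Earth's radius, so planar error is
negligible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from skbio import DistanceMatrix
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable, FeatureTableError, SampleMetadata

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius


# ---------------------------------------------------------------------------
# Geodesics and projection


def haversine(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in meters between WGS84 points (degrees)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geodesic_matrix(metadata: SampleMetadata,
                    sample_ids=None) -> DistanceMatrix:
    """Pairwise haversine distances (meters) between samples."""
    ids = list(sample_ids) if sample_ids is not None else metadata.sample_ids
    latlon = metadata.coords(ids)
    lat, lon = latlon[:, 0], latlon[:, 1]
    d = haversine(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, ids=ids)


def project_local(lat, lon, origin: tuple[float, float] | None = None) -> np.ndarray:
    """Project lat/lon (degrees) to local planar meters.

    Equirectangular about ``origin`` (default: the centroid): x is easting,
    y is northing.  Adequate when the extent is far below Earth's radius.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if origin is None:
        origin = (float(lat.mean()), float(lon.mean()))
    lat0, lon0 = origin
    x = np.radians(lon - lon0) * EARTH_RADIUS_M * math.cos(math.radians(lat0))
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    return np.column_stack([x, y])


def unproject_local(xy, origin: tuple[float, float]) -> np.ndarray:
    """Inverse of :func:`project_local`: planar meters back to (lat, lon)."""
    xy = np.asarray(xy, dtype=float)
    lat0, lon0 = origin
    lat = lat0 + np.degrees(xy[:, 1] / EARTH_RADIUS_M)
    lon = lon0 + np.degrees(xy[:, 0] / (EARTH_RADIUS_M * math.cos(math.radians(lat0))))
    return np.column_stack([lat, lon])


# ---------------------------------------------------------------------------
# Mantel test


@dataclass
class MantelResult:
    rho: float
    p_value: float
    n_permutations: int
    n_pairs: int


def _condensed(square: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(square.shape[0], k=1)
    return square[iu]


def _align(dm_a: DistanceMatrix, dm_b: DistanceMatrix):
    if set(dm_a.ids) != set(dm_b.ids):
        raise FeatureTableError("distance matrices cover different sample sets")
    return dm_a, dm_b.filter(dm_a.ids)


def mantel(dm_a: DistanceMatrix, dm_b: DistanceMatrix, n_perm: int | str = 999,
           seed=None) -> MantelResult:
    """Mantel permutation test with Spearman correlation.

    rho is the Spearman correlation of the upper-triangle entries (average
    ranks for ties).  Significance permutes the sample labels of ``dm_b``
    (simultaneous row/column shuffles); two-sided on |rho| with the add-one
    estimator p = (1 + hits) / (1 + n_perm), so p is never 0.

    ``n_perm="exact"`` enumerates all n! label permutations; p is then the
    exact fraction of permutations (identity included) at least as extreme.
    """
    dm_a, dm_b = _align(dm_a, dm_b)
    n = dm_a.shape[0]
    if n < 4:
        raise FeatureTableError("mantel needs >= 4 samples")
    va = _condensed(np.asarray(dm_a.data, dtype=float))
    vb_sq = np.asarray(dm_b.data, dtype=float)
    vb = _condensed(vb_sq)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise FeatureTableError("constant distance vector: Spearman rho undefined")
    ra = scipy.stats.rankdata(va)
    rb = scipy.stats.rankdata(vb)
    # ranks are invariant under label permutation, so permute the rank
    # matrix of b rather than re-ranking every permutation
    rb_sq = np.zeros_like(vb_sq)
    iu = np.triu_indices(n, k=1)
    rb_sq[iu] = rb
    rb_sq = rb_sq + rb_sq.T

    ra_c = ra - ra.mean()
    denom_a = np.sqrt((ra_c ** 2).sum())

    def corr_with(rows: np.ndarray) -> np.ndarray:
        # rows: (P, m) permuted rank vectors of b
        rc = rows - rows.mean(axis=1, keepdims=True)
        den = denom_a * np.sqrt((rc ** 2).sum(axis=1))
        return (rc @ ra_c) / den

    rho = float(corr_with(rb[None, :])[0])

    if n_perm == "exact":
        perms = np.array(list(itertools.permutations(range(n))))
        permuted = rb_sq[perms[:, iu[0]], perms[:, iu[1]]]
        stats = corr_with(permuted)
        p = float(np.mean(np.abs(stats) >= abs(rho) - 1e-12))
        n_used = perms.shape[0]
    else:
        n_perm = int(n_perm)
        if n_perm < 1:
            raise FeatureTableError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        permuted = rb_sq[perms[:, iu[0]], perms[:, iu[1]]]
        stats = corr_with(permuted)
        hits = int(np.sum(np.abs(stats) >= abs(rho) - 1e-12))
        p = (1 + hits) / (1 + n_perm)
        n_used = n_perm
    return MantelResult(rho=rho, p_value=p, n_permutations=n_used,
                        n_pairs=len(va))


@dataclass
class DistanceDecayResult:
    """Mantel inference plus a descriptive OLS fit over sample pairs.

    The regression slope quantifies how fast community dissimilarity grows
    per meter; its CI treats pairs as independent, which they are not, so
    use the Mantel p-value for inference.
    """

    mantel: MantelResult
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    pairs: pd.DataFrame = field(repr=False)


def distance_decay(dm_community: DistanceMatrix, dm_geo: DistanceMatrix,
                   n_perm: int | str = 999, seed=None) -> DistanceDecayResult:
    """Distance-decay analysis: Mantel test + pairwise OLS of community on geo."""
    dm_c, dm_g = _align(dm_community, dm_geo)
    res = mantel(dm_c, dm_g, n_perm=n_perm, seed=seed)
    y = _condensed(np.asarray(dm_c.data, dtype=float))
    x = _condensed(np.asarray(dm_g.data, dtype=float))
    if np.ptp(y) == 0:
        slope, intercept, ci = 0.0, float(y[0]), (0.0, 0.0)
    else:
        fit = scipy.stats.linregress(x, y)
        tcrit = scipy.stats.t.ppf(0.975, len(x) - 2)
        slope, intercept = float(fit.slope), float(fit.intercept)
        ci = (slope - tcrit * fit.stderr, slope + tcrit * fit.stderr)
    ids = list(dm_c.ids)
    iu = np.triu_indices(len(ids), k=1)
    pairs = pd.DataFrame({
        "sample_a": [ids[i] for i in iu[0]],
        "sample_b": [ids[j] for j in iu[1]],
        "geo_m": x,
        "community": y,
    })
    return DistanceDecayResult(mantel=res, slope=slope, intercept=intercept,
                               slope_ci=ci, pairs=pairs)


def pair_class_distances(dm: DistanceMatrix, metadata: SampleMetadata) -> pd.DataFrame:
    """Label every sample pair by spatial relationship class.

    ``within_vine``: both samples share a non-null ``vine_group`` (e.g. the
    repeatedly sampled clusters of one oversampled vine); ``within_vineyard``:
    same vineyard, different vines; ``between_vineyard``: otherwise.
    Returns a tidy frame (sample_a, sample_b, distance, pair_class).
    """
    ids = list(dm.ids)
    vineyard = metadata.column("vineyard", ids)
    has_group = "vine_group" in metadata.data.columns
    group = metadata.column("vine_group", ids) if has_group else None
    rows = []
    d = np.asarray(dm.data, dtype=float)
    for i, j in itertools.combinations(range(len(ids)), 2):
        a, b = ids[i], ids[j]
        if (group is not None and pd.notna(group[a]) and pd.notna(group[b])
                and group[a] == group[b]):
            cls = "within_vine"
        elif vineyard[a] == vineyard[b]:
            cls = "within_vineyard"
        else:
            cls = "between_vineyard"
        rows.append((a, b, d[i, j], cls))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "distance", "pair_class"])


# ---------------------------------------------------------------------------
# Kriging (Gaussian-process spatial interpolation)


@dataclass
class KrigingTraceEntry:
    restart: int
    length_scale: float
    amplitude: float
    noise: float
    log_marginal_likelihood: float


class MaternKriging:
    """Gaussian-process spatial interpolation with a Matérn kernel.

    Fits amplitude * Matérn(length_scale, nu) + white noise to standardized
    values at planar-meter coordinates, maximising the log marginal
    likelihood from ``n_restarts`` log-uniform random initializations plus
    one heuristic start at the median inter-point distance.

    Parameters
    ----------
    nu : float
        Matérn smoothness; 0.5 (exponential), 1.5 (default, once
        differentiable) or 2.5.
    n_restarts : int
        Number of random restarts in addition to the heuristic start.
    noise_bounds : tuple
        Bounds for the white-noise variance on the standardized scale; pin
        both ends near zero for exact interpolation.
    """

    def __init__(self, nu: float = 1.5, n_restarts: int = 10,
                 noise_bounds: tuple[float, float] = (1e-8, 10.0),
                 seed=None):
        self.nu = nu
        self.n_restarts = n_restarts
        self.noise_bounds = noise_bounds
        self.seed = seed
        self._gpr: GaussianProcessRegressor | None = None

    def fit(self, coords, values) -> "MaternKriging":
        coords = np.asarray(coords, dtype=float)
        values = np.asarray(values, dtype=float)
        if coords.ndim != 2:
            raise FeatureTableError("coords must be (n, d)")
        if coords.shape[0] < 5:
            raise FeatureTableError("kriging needs >= 5 training points")
        if not np.all(np.isfinite(values)):
            raise FeatureTableError("non-finite training values")
        self.y_mean_ = float(values.mean())
        self.y_std_ = float(values.std())
        if self.y_std_ == 0:
            self.y_std_ = 1.0
        y = (values - self.y_mean_) / self.y_std_

        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        pos = d[d > 0]
        if pos.size == 0:
            raise FeatureTableError("all training coordinates coincide")
        ls_lo, ls_hi = 0.1 * float(pos.min()), 10.0 * float(pos.max())
        ls0 = float(np.median(pos))
        amp_bounds = (1e-3, 1e3)

        rng = np.random.default_rng(self.seed)
        starts = [(ls0, 1.0, 1e-4)]
        for _ in range(self.n_restarts):
            starts.append((
                float(np.exp(rng.uniform(np.log(ls_lo), np.log(ls_hi)))),
                float(np.exp(rng.uniform(np.log(amp_bounds[0]), np.log(amp_bounds[1])))),
                float(np.exp(rng.uniform(np.log(self.noise_bounds[0]),
                                         np.log(self.noise_bounds[1])))),
            ))
        best = None
        trace: list[KrigingTraceEntry] = []
        for i, (ls, amp, noise) in enumerate(starts):
            noise = float(np.clip(noise, *self.noise_bounds))
            kernel = (ConstantKernel(amp, amp_bounds)
                      * Matern(length_scale=ls, length_scale_bounds=(ls_lo, ls_hi),
                               nu=self.nu)
                      + WhiteKernel(noise, self.noise_bounds))
            gpr = GaussianProcessRegressor(kernel=kernel, n_restarts_optimizer=0,
                                           normalize_y=False)
            try:
                # hyperparameters pinned at a bound are routine here (e.g.
                # noise forced to ~0 for exact interpolation)
                import warnings as _warnings
                from sklearn.exceptions import ConvergenceWarning
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore", ConvergenceWarning)
                    gpr.fit(coords, y)
            except (np.linalg.LinAlgError, ValueError):
                continue
            lml = float(gpr.log_marginal_likelihood_value_)
            k = gpr.kernel_
            trace.append(KrigingTraceEntry(
                restart=i,
                length_scale=float(k.k1.k2.length_scale),
                amplitude=float(k.k1.k1.constant_value),
                noise=float(k.k2.noise_level),
                log_marginal_likelihood=lml,
            ))
            if best is None or lml > best[0]:
                best = (lml, gpr)
        if best is None:
            raise FeatureTableError("GP optimisation failed on every restart")
        self._gpr = best[1]
        self.trace_ = trace
        k = self._gpr.kernel_
        self.length_scale_ = float(k.k1.k2.length_scale)
        self.amplitude_ = float(k.k1.k1.constant_value)
        self.noise_ = float(k.k2.noise_level)
        self.log_marginal_likelihood_ = best[0]
        self.train_coords_ = coords
        return self

    def predict(self, coords) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and standard deviation, de-standardized."""
        if self._gpr is None:
            raise FeatureTableError("model is not fitted")
        coords = np.asarray(coords, dtype=float)
        mean, sd = self._gpr.predict(coords, return_std=True)
        return mean * self.y_std_ + self.y_mean_, np.maximum(sd, 0.0) * self.y_std_


def fit_krige(coords, values, nu: float = 1.5, n_restarts: int = 10,
              seed=None, noise_bounds=(1e-8, 10.0)) -> MaternKriging:
    """Fit a Matérn GP to values at planar-meter coordinates."""
    return MaternKriging(nu=nu, n_restarts=n_restarts,
                         noise_bounds=noise_bounds, seed=seed).fit(coords, values)


def predict_krige(model: MaternKriging, coords) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and sd of a fitted kriging model at query coordinates."""
    return model.predict(coords)


# ---------------------------------------------------------------------------
# Taxon-vs-coordinate screening


def taxon_coordinate_screen(table: FeatureTable, metadata: SampleMetadata,
                            min_prevalence: float = 0.1,
                            correction: str = "bh") -> pd.DataFrame:
    """Screen taxa for latitude/longitude abundance gradients.

    Converts counts to per-sample relative abundances, then computes
    Spearman rho and p for each sufficiently prevalent taxon against
    latitude and against longitude.  ``correction="bh"`` applies
    Benjamini–Hochberg across all tests in the screen; ``"none"`` reports
    raw p-values as q-values.

    Returns one row per screened taxon with columns
    rho_latitude/p_latitude/q_latitude and the longitude equivalents.
    """
    if correction not in ("bh", "none"):
        raise FeatureTableError("correction must be 'bh' or 'none'")
    latlon = metadata.coords(table.sample_ids)
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, counts / totals, 0.0)
    prevalence = (counts > 0).mean(axis=0)
    keep = np.flatnonzero(prevalence >= min_prevalence)
    if keep.size == 0:
        import warnings
        warnings.warn("no taxon passes the prevalence filter", stacklevel=2)
        return pd.DataFrame(columns=[
            "feature_id", "prevalence", "rho_latitude", "p_latitude",
            "q_latitude", "rho_longitude", "p_longitude", "q_longitude"])
    rows = []
    for j in keep:
        r_lat, p_lat = scipy.stats.spearmanr(rel[:, j], latlon[:, 0])
        r_lon, p_lon = scipy.stats.spearmanr(rel[:, j], latlon[:, 1])
        rows.append({
            "feature_id": table.feature_ids[j],
            "prevalence": float(prevalence[j]),
            "rho_latitude": float(r_lat), "p_latitude": float(p_lat),
            "rho_longitude": float(r_lon), "p_longitude": float(p_lon),
        })
    out = pd.DataFrame(rows)
    pvals = np.concatenate([out["p_latitude"], out["p_longitude"]])
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    if correction == "bh":
        q = multipletests(pvals, method="fdr_bh")[1]
    else:
        q = pvals
    k = len(out)
    out["q_latitude"] = q[:k]
    out["q_longitude"] = q[k:]
    return out
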