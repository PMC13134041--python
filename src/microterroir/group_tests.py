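"""Group-difference inference: PERMANOVA family, ANOVA, Spearman trends.

PERMANOVA partitions the squared distances of a community distance matrix
into among- and within-group sums of squares and tests the pseudo-F by
label permutation.  The effect size reported is R^2 = SS_among / SS_total.
The stratified variant tests a factor (e.g. cultivar) while holding a
confounder (e.g. vineyard site) fixed, by permuting labels only within
strata — the permutation analogue of "after factoring for site".

Pairwise PERMANOVA results are summarised as a compact letter display:
groups sharing no letter differ significantly after BH adjustment.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests
from sympy.utilities.iterables import multiset_permutations

from .diversity import AlphaVector
from .tables import FeatureTableError


@dataclass
class PermanovaResult:
    pseudo_F: float
    r2: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]
    n_samples: int


def _group_onehot(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
    levels, codes = np.unique(labels, return_inverse=True)
    z = np.zeros((len(labels), len(levels)))
    z[np.arange(len(labels)), codes] = 1.0
    return z, codes, list(levels)


def _permanova_stats(d2: np.ndarray, codes_matrix: np.ndarray,
                     sizes: np.ndarray, ss_total: float, n: int):
    """Vectorised pseudo-F over rows of permuted one-hot stacks.

    ``codes_matrix``: (P, n) integer label codes; returns (F, R2) arrays.
    SS_within = sum_g (sum of squared within-group distances) / n_g, with
    the pair sum obtained as 0.5 * z_g' D2 z_g.
    """
    p_count, _ = codes_matrix.shape
    a = len(sizes)
    zs = np.zeros((p_count, n, a))
    rows = np.repeat(np.arange(p_count), n)
    cols = np.tile(np.arange(n), p_count)
    zs[rows, cols, codes_matrix.ravel()] = 1.0
    # within-group pair sums per permutation and group
    w = 0.5 * np.einsum("pia,ij,pja->pa", zs, d2, zs)
    ss_within = (w / sizes).sum(axis=1)
    ss_among = ss_total - ss_within
    df_among = a - 1
    df_within = n - a
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_among / df_among) / (ss_within / df_within)
    f = np.where(ss_within == 0, np.inf, f)
    r2 = ss_among / ss_total if ss_total > 0 else np.zeros_like(ss_among)
    return f, r2


def permanova(dm: DistanceMatrix, grouping, n_perm: int | str = 999,
              seed=None) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the analogous
    per-group quantities; pseudo-F = (SS_among/(a-1)) / (SS_within/(n-a)).
    p is by label permutation with the add-one estimator; ``n_perm="exact"``
    enumerates every distinct assignment of the label multiset and returns
    the exact fraction at least as extreme (identity included).
    """
    labels = _labels_for(dm, grouping)
    n = dm.shape[0]
    levels, codes = np.unique(labels, return_inverse=True)
    sizes = np.bincount(codes).astype(float)
    if len(levels) < 2:
        raise FeatureTableError("permanova needs >= 2 groups")
    if sizes.min() < 2:
        small = [str(levels[i]) for i in np.flatnonzero(sizes < 2)]
        raise FeatureTableError(f"singleton group(s): {small}")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n

    f_obs, r2_obs = _permanova_stats(d2, codes[None, :], sizes, ss_total, n)
    f_obs, r2_obs = float(f_obs[0]), float(r2_obs[0])

    if n_perm == "exact":
        perms = np.array(list(multiset_permutations(codes.tolist())))
        f_perm, _ = _permanova_stats(d2, perms, sizes, ss_total, n)
        p = float(np.mean(f_perm >= f_obs - 1e-12))
        n_used = perms.shape[0]
    else:
        n_perm = int(n_perm)
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
        f_perm, _ = _permanova_stats(d2, perms, sizes, ss_total, n)
        p = (1 + int(np.sum(f_perm >= f_obs - 1e-12))) / (1 + n_perm)
        n_used = n_perm
    return PermanovaResult(
        pseudo_F=f_obs, r2=r2_obs, p_value=p, n_permutations=n_used,
        group_sizes={str(l): int(s) for l, s in zip(levels, sizes)},
        n_samples=n,
    )


def _labels_for(dm: DistanceMatrix, grouping) -> np.ndarray:
    """Align a grouping (Series or array) to the distance matrix's ids."""
    if isinstance(grouping, pd.Series):
        missing = [s for s in dm.ids if s not in grouping.index]
        if missing:
            raise FeatureTableError(f"grouping missing samples: {missing[:5]}")
        return grouping.loc[list(dm.ids)].to_numpy()
    labels = np.asarray(grouping)
    if len(labels) != dm.shape[0]:
        raise FeatureTableError("grouping length does not match distance matrix")
    return labels


# ---------------------------------------------------------------------------
# Pairwise PERMANOVA with compact letters


@dataclass
class PairwiseLetters:
    """Compact letter display over pairwise PERMANOVA results.

    ``letters`` maps each group to its letter string; two groups share a
    letter iff their BH-adjusted p exceeds alpha.  ``p_values`` and
    ``q_values`` are symmetric matrices over groups.
    """

    letters: dict[str, str]
    p_values: pd.DataFrame
    q_values: pd.DataFrame
    alpha: float


def compact_letters(groups: list[str], significant) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant(a, b)`` returns True when groups a, b differ.  Groups in
    the same letter set never differ; every non-differing pair shares at
    least one letter.
    """
    sets: list[set[str]] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if not significant(a, b):
            continue
        for s in [s for s in sets if a in s and b in s]:
            sets.remove(s)
            s1, s2 = s - {a}, s - {b}
            for cand in (s1, s2):
                if not any(cand <= other for other in sets):
                    sets.append(cand)
        # absorb: drop sets contained in another
        sets = [s for s in sets if not any(s < t for t in sets)]
    sets.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = string.ascii_lowercase
    out = {g: "" for g in groups}
    for i, s in enumerate(sets):
        letter = alphabet[i % 26] * (i // 26 + 1)
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def permanova_pairwise(dm: DistanceMatrix, grouping, n_perm: int = 999,
                       alpha: float = 0.05, seed=None) -> PairwiseLetters:
    """All-pairs PERMANOVA with BH adjustment and compact letters."""
    labels = _labels_for(dm, grouping)
    series = pd.Series(labels, index=list(dm.ids))
    groups = [str(g) for g in pd.unique(series)]
    if len(groups) < 2:
        raise FeatureTableError("pairwise permanova needs >= 2 groups")
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(groups, 2))
    pvals = []
    for a, b in pairs:
        ids = series.index[series.astype(str).isin([a, b])]
        sub = dm.filter(ids)
        res = permanova(sub, series.loc[list(sub.ids)], n_perm=n_perm,
                        seed=rng.integers(2 ** 31))
        pvals.append(res.p_value)
    qvals = multipletests(pvals, method="fdr_bh")[1] if pairs else np.array([])
    pmat = pd.DataFrame(np.nan, index=groups, columns=groups)
    qmat = pd.DataFrame(np.nan, index=groups, columns=groups)
    sig = {}
    for (a, b), p, q in zip(pairs, pvals, qvals):
        pmat.loc[a, b] = pmat.loc[b, a] = p
        qmat.loc[a, b] = qmat.loc[b, a] = q
        sig[(a, b)] = sig[(b, a)] = q <= alpha
    letters = compact_letters(groups, lambda a, b: sig[(a, b)])
    return PairwiseLetters(letters=letters, p_values=pmat, q_values=qmat,
                           alpha=alpha)


# ---------------------------------------------------------------------------
# Stratified (restricted-permutation) PERMANOVA


def permanova_stratified(dm: DistanceMatrix, factor, strata,
                         n_perm: int = 999, seed=None) -> PermanovaResult:
    """PERMANOVA of ``factor`` with permutations restricted within ``strata``.

    The statistic pools the factor sums of squares within each stratum:
    SS_total and SS_within(factor) are computed per stratum and summed, with
    pooled degrees of freedom sum(a_s - 1) and sum(n_s - a_s).  Permutations
    shuffle factor labels only within each stratum, so any between-stratum
    structure (site effects) is held fixed under the null.
    """
    f_labels = _labels_for(dm, factor)
    s_labels = _labels_for(dm, strata)
    n = dm.shape[0]
    d2 = np.asarray(dm.data, dtype=float) ** 2
    strata_ids = pd.unique(s_labels)
    per_stratum = []
    informative = False
    for s in strata_ids:
        idx = np.flatnonzero(s_labels == s)
        labs = f_labels[idx]
        levels, codes = np.unique(labs, return_inverse=True)
        if len(levels) >= 2:
            informative = True
        per_stratum.append((idx, codes, len(levels)))
    if not informative:
        raise FeatureTableError(
            "factor is constant within every stratum: confounded design")

    def pooled_stats(assignments: list[np.ndarray]):
        """assignments[k]: (P, n_k) permuted codes for stratum k."""
        p_count = assignments[0].shape[0]
        ss_total = 0.0
        ss_within = np.zeros(p_count)
        df_among = 0
        df_within = 0
        for (idx, _, a_s), codes_p in zip(per_stratum, assignments):
            n_s = len(idx)
            sub = d2[np.ix_(idx, idx)]
            ss_total += sub[np.triu_indices(n_s, k=1)].sum() / n_s
            if a_s < 2:
                continue
            sizes = np.bincount(codes_p[0]).astype(float)
            zs = np.zeros((p_count, n_s, a_s))
            rows = np.repeat(np.arange(p_count), n_s)
            cols = np.tile(np.arange(n_s), p_count)
            zs[rows, cols, codes_p.ravel()] = 1.0
            w = 0.5 * np.einsum("pia,ij,pja->pa", zs, sub, zs)
            ss_within += (w / sizes).sum(axis=1)
            df_among += a_s - 1
            df_within += n_s - a_s
        ss_among = ss_total - ss_within
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (ss_among / df_among) / (ss_within / df_within)
        f = np.where(ss_within == 0, np.inf, f)
        return f, ss_among / ss_total if ss_total > 0 else np.zeros_like(f)

    obs_assign = [codes[None, :] for (_, codes, _) in per_stratum]
    f_obs, r2_obs = pooled_stats(obs_assign)
    f_obs, r2_obs = float(f_obs[0]), float(r2_obs[0])

    rng = np.random.default_rng(seed)
    perm_assign = []
    for (idx, codes, _) in per_stratum:
        perm_assign.append(
            np.array([rng.permutation(codes) for _ in range(int(n_perm))]))
    f_perm, _ = pooled_stats(perm_assign)
    p = (1 + int(np.sum(f_perm >= f_obs - 1e-12))) / (1 + int(n_perm))

    levels, _ = np.unique(f_labels, return_inverse=True)
    sizes = {str(l): int(np.sum(f_labels == l)) for l in levels}
    return PermanovaResult(pseudo_F=f_obs, r2=r2_obs, p_value=p,
                           n_permutations=int(n_perm), group_sizes=sizes,
                           n_samples=n)


# ---------------------------------------------------------------------------
# Classical tests on alpha diversity


@dataclass
class AnovaResult:
    table: pd.DataFrame  # one row per factor: F, df_num, df_den, p_value


def _alpha_values(alpha) -> pd.Series:
    if isinstance(alpha, AlphaVector):
        return alpha.values
    return pd.Series(alpha)


def anova_alpha(alpha, factors) -> AnovaResult:
    """ANOVA of alpha diversity on one or two grouping factors.

    One factor: classical one-way F-test.  Two factors: main-effects ANOVA
    with type II sums of squares and no interaction — appropriate for the
    unbalanced vineyard-by-cultivar designs this models.
    """
    y = _alpha_values(alpha)
    if isinstance(factors, (pd.Series, np.ndarray)):
        factors = [factors]
    elif isinstance(factors, (list, tuple)) and factors and np.isscalar(factors[0]):
        factors = [factors]  # a single flat factor given as a plain list
    factors = [f.loc[y.index] if isinstance(f, pd.Series) else
               pd.Series(np.asarray(f), index=y.index) for f in factors]
    if len(factors) == 1:
        f1 = factors[0]
        groups = [y[f1 == g].to_numpy() for g in pd.unique(f1)]
        if len(groups) < 2:
            raise FeatureTableError("anova needs >= 2 groups")
        if np.ptp(np.concatenate(groups)) == 0:
            # degenerate: all observations identical
            k, n = len(groups), len(y)
            tbl = pd.DataFrame([{"factor": "factor1", "F": 0.0,
                                 "df_num": k - 1, "df_den": n - k,
                                 "p_value": 1.0}])
            return AnovaResult(tbl)
        f, p = scipy.stats.f_oneway(*groups)
        tbl = pd.DataFrame([{"factor": "factor1", "F": float(f),
                             "df_num": len(groups) - 1,
                             "df_den": len(y) - len(groups),
                             "p_value": float(p)}])
        return AnovaResult(tbl)
    if len(factors) != 2:
        raise FeatureTableError("anova_alpha accepts one or two factors")
    f1, f2 = factors
    cells = pd.crosstab(f1, f2)
    if (cells == 0).to_numpy().any():
        raise FeatureTableError(
            "empty cell in two-way design; use one-way ANOVA per factor")
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    df = pd.DataFrame({"y": y.to_numpy(), "f1": f1.to_numpy(), "f2": f2.to_numpy()})
    model = smf.ols("y ~ C(f1) + C(f2)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    rows = []
    for name, label in (("C(f1)", "factor1"), ("C(f2)", "factor2")):
        rows.append({"factor": label, "F": float(aov.loc[name, "F"]),
                     "df_num": int(aov.loc[name, "df"]),
                     "df_den": int(aov.loc["Residual", "df"]),
                     "p_value": float(aov.loc[name, "PR(>F)"])})
    return AnovaResult(pd.DataFrame(rows))


def spearman_trend(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Average ranks for ties; exact permutation p for n <= 9 (all n!
    orderings enumerated), t-approximation otherwise.  Typical use:
    alpha diversity against vineyard row position.
    """
    x = np.asarray(x, dtype=float)
    if isinstance(y, AlphaVector):
        y = y.values.to_numpy()
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise FeatureTableError("x and y must be the same length")
    n = len(x)
    if n < 4:
        raise FeatureTableError("spearman_trend needs n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise FeatureTableError("constant input: Spearman rho undefined")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean(axis=-1, keepdims=True)
        return (b @ a) / np.sqrt((a ** 2).sum() * (b ** 2).sum(axis=-1))

    rho = float(corr(rx, ry[None, :])[0])
    if n <= 9:
        perms = np.array(list(itertools.permutations(range(n))))
        stats = corr(rx, ry[perms])
        p = float(np.mean(np.abs(stats) >= abs(rho) - 1e-12))
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho ** 2))
        p = float(2 * scipy.stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)
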