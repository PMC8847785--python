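"""Distance-matrix group tests and the divergence-over-time regression.

Everything here is implemented from the defining formulas:

* :func:`permanova` — one-factor permutational MANOVA on a distance matrix.
  With ``N`` samples in ``g`` groups,

      SS_total  = (1/N) * sum_{i<j} d_ij^2
      SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
      SS_among  = SS_total - SS_within
      pseudo-F  = (SS_among/(g-1)) / (SS_within/(N-g))

  The permutation p-value uses the +1 convention,
  p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations), so p is never 0 and
  has resolution 1/(n_permutations + 1).

* :func:`dispersion_test` — homogeneity of multivariate dispersions:
  principal-coordinates embedding of -1/2 d^2 (double-centred), distances
  to group centroids computed as sqrt(max(0, real-axis sq. distance minus
  imaginary-axis sq. distance)), then a one-way ANOVA F with a label
  permutation p-value (centroids recomputed under each permutation).

* :func:`rank_sum_test` — two-sample Wilcoxon / Mann-Whitney U from
  midranks; exact enumeration (dynamic programming over rank subsets) when
  ``n_a * n_b <= 400`` and there are no ties, else the normal approximation
  with tie and continuity corrections.

* :func:`divergence_regression` — OLS of common-garden-vs-field
  dissimilarity on days in the garden, pooled and per population.

Scikit-bio offers PERMANOVA/PERMDISP as well; those serve as independent
cross-checks in the test suite, not as the implementation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix

from .errors import DegenerateDesignError, InsufficientDataError, ParameterError


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    R_squared: float
    p_value: float
    n_permutations: int
    df_among: int
    df_within: int
    n_samples: int
    method: str = "sampled"

    def to_dict(self) -> Dict:
        return asdict(self)


@dataclass
class DispersionResult:
    group_dispersions: Dict[str, float]
    F_statistic: float
    p_value: float
    n_permutations: int

    def to_dict(self) -> Dict:
        return asdict(self)


@dataclass
class RankSumResult:
    statistic_U: float
    p_value: float
    n_a: int
    n_b: int
    alternative: str
    method: str
    degenerate: bool = False

    def to_dict(self) -> Dict:
        return asdict(self)


@dataclass
class DivergenceResult:
    slope: float
    intercept: float
    slope_p_value: float
    r_squared: float
    population: str
    n_pairs: int

    def to_dict(self) -> Dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _group_codes(ids: Sequence[str], groups) -> np.ndarray:
    if isinstance(groups, pd.Series):
        missing = [s for s in ids if s not in groups.index]
        if missing:
            raise ParameterError(f"group labels missing for samples: {missing}")
        labels = groups.loc[list(ids)].to_numpy()
    else:
        labels = np.asarray(list(groups))
        if labels.shape[0] != len(ids):
            raise ParameterError("group labels do not cover all samples")
    codes, _ = pd.factorize(labels)
    return codes


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    total = 0.0
    for g in range(n_groups):
        mask = codes == g
        n_g = int(mask.sum())
        if n_g > 1:
            total += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    return total


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int, ss_total: float):
    n = d2.shape[0]
    ss_within = _ss_within(d2, codes, n_groups)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0:
        f = np.inf if ss_among > 0 else 0.0
    else:
        f = (ss_among / df_among) / (ss_within / df_within)
    return f, ss_within, ss_among


def permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: Optional[int] = None,
    method: str = "sampled",
) -> PermanovaResult:
    """One-factor PERMANOVA of a distance matrix against group labels.

    Parameters
    ----------
    dist : skbio.DistanceMatrix
    groups : mapping, Series, or sequence aligned with ``dist.ids``
    n_permutations : int
        Number of label permutations for ``method="sampled"``.
    seed : int
        Seed for the permutation stream (required when sampling).
    method : {"sampled", "exhaustive"}
        "exhaustive" enumerates every distinct assignment of the label
        multiset to samples (small designs only) and returns the exact
        permutation p-value.
    """
    ids = list(dist.ids)
    n = len(ids)
    codes = _group_codes(ids, groups)
    n_groups = int(codes.max()) + 1
    counts = np.bincount(codes, minlength=n_groups)
    if n_groups < 2:
        raise DegenerateDesignError(
            "PERMANOVA needs at least 2 groups; a single group equal to the "
            "whole sample set is a degenerate design"
        )
    if (counts == 0).any():
        raise DegenerateDesignError("empty group in design")

    d2 = dist.data.astype(float) ** 2
    ss_total = d2.sum() / (2.0 * n)
    f_obs, ss_within, ss_among = _pseudo_f(d2, codes, n_groups, ss_total)
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    r2 = float(min(max(r2, 0.0), 1.0))

    if method == "exhaustive":
        seen = set()
        f_all = []
        for perm in itertools.permutations(codes.tolist()):
            if perm in seen:
                continue
            seen.add(perm)
            f_p, _, _ = _pseudo_f(d2, np.array(perm), n_groups, ss_total)
            f_all.append(f_p)
        f_all = np.array(f_all)
        # observed labelling is part of the enumeration
        p = float(np.mean(f_all >= f_obs - 1e-12))
        n_perm = len(f_all)
    elif method == "sampled":
        if n_permutations < 1:
            raise ParameterError("n_permutations must be positive")
        if seed is None:
            raise ParameterError("seed is required for sampled permutations")
        rng = np.random.default_rng(seed)
        count_ge = 0
        for _ in range(n_permutations):
            perm_codes = rng.permutation(codes)
            f_p, _, _ = _pseudo_f(d2, perm_codes, n_groups, ss_total)
            if f_p >= f_obs - 1e-12:
                count_ge += 1
        p = (1.0 + count_ge) / (1.0 + n_permutations)
        n_perm = n_permutations
    else:
        raise ParameterError(f"unknown method {method!r}")

    return PermanovaResult(
        pseudo_F=float(f_obs),
        R_squared=r2,
        p_value=float(p),
        n_permutations=n_perm,
        df_among=n_groups - 1,
        df_within=n - n_groups,
        n_samples=n,
        method=method,
    )


# ---------------------------------------------------------------------------
# Homogeneity of dispersions
# ---------------------------------------------------------------------------

def _pcoa_axes(d: np.ndarray):
    """Principal-coordinates embedding of a distance matrix.

    Returns (real_coords, imag_coords): coordinates on positive- and
    negative-eigenvalue axes, each scaled by sqrt(|eigenvalue|).
    """
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    tol = np.abs(eigval).max() * 1e-10 if eigval.size else 0.0
    pos = eigval > tol
    neg = eigval < -tol
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return real, imag


def _centroid_distances(real: np.ndarray, imag: np.ndarray, codes: np.ndarray,
                        n_groups: int) -> np.ndarray:
    z = np.empty(codes.shape[0])
    for g in range(n_groups):
        mask = codes == g
        cr = real[mask].mean(axis=0)
        ci = imag[mask].mean(axis=0) if imag.shape[1] else np.zeros(0)
        sq = ((real[mask] - cr) ** 2).sum(axis=1)
        if imag.shape[1]:
            sq = sq - ((imag[mask] - ci) ** 2).sum(axis=1)
        z[mask] = np.sqrt(np.maximum(sq, 0.0))
    return z


def _anova_f(z: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = z.shape[0]
    grand = z.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        zg = z[codes == g]
        ss_between += zg.shape[0] * (zg.mean() - grand) ** 2
        ss_within += ((zg - zg.mean()) ** 2).sum()
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within <= 1e-300:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_b) / (ss_within / df_w)


def dispersion_test(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> DispersionResult:
    """Permutation test for homogeneity of group dispersions.

    Dispersions are mean distances to group centroids in the
    principal-coordinates embedding, with negative-eigenvalue axes
    subtracting from the squared distances (floored at zero).
    """
    ids = list(dist.ids)
    codes = _group_codes(ids, groups)
    n_groups = int(codes.max()) + 1
    counts = np.bincount(codes, minlength=n_groups)
    if n_groups < 2:
        raise DegenerateDesignError("dispersion test needs at least 2 groups")
    labels = pd.factorize(
        groups.loc[list(ids)].to_numpy() if isinstance(groups, pd.Series)
        else np.asarray(list(groups))
    )[1]
    small = [str(labels[g]) for g in range(n_groups) if counts[g] < 2]
    if small:
        raise DegenerateDesignError(
            f"group(s) with a single sample have undefined dispersion: {small}"
        )
    if seed is None:
        raise ParameterError("seed is required for the permutation test")

    real, imag = _pcoa_axes(dist.data.astype(float))
    z = _centroid_distances(real, imag, codes, n_groups)
    f_obs = _anova_f(z, codes, n_groups)
    group_disp = {
        str(labels[g]): float(z[codes == g].mean()) for g in range(n_groups)
    }

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        z_p = _centroid_distances(real, imag, perm, n_groups)
        if _anova_f(z_p, perm, n_groups) >= f_obs - 1e-12:
            count_ge += 1
    p = (1.0 + count_ge) / (1.0 + n_permutations)
    return DispersionResult(
        group_dispersions=group_disp,
        F_statistic=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Rank-sum (two-sample Wilcoxon / Mann-Whitney)
# ---------------------------------------------------------------------------

def _exact_u_pmf(n_a: int, n_b: int) -> np.ndarray:
    """Exact null distribution of U by counting rank subsets.

    dp[k][u] = number of ways to choose k of the ranks seen so far with
    rank-sum offset u; equivalent to enumerating all C(n_a+n_b, n_a)
    arrangements.
    """
    max_u = n_a * n_b
    dp = np.zeros((n_a + 1, max_u + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, n_a + n_b + 1):
        for k in range(min(r, n_a), 0, -1):
            # picking rank r as the k-th element of sample A contributes
            # (r - k) to U = sum(ranks_A) - n_a(n_a+1)/2
            u_add = r - k
            if u_add > max_u:
                continue
            dp[k, u_add:] += dp[k - 1, : max_u + 1 - u_add]
    pmf = dp[n_a]
    return pmf / pmf.sum()


def rank_sum_test(values_a, values_b, alternative: str = "two_sided") -> RankSumResult:
    """Mann-Whitney U test from midranks.

    Exact enumeration when ``n_a * n_b <= 400`` and the pooled data are
    tie-free; otherwise a normal approximation with tie correction and
    continuity correction. ``statistic_U`` is the U of the first sample.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    if alternative not in ("two_sided", "less", "greater"):
        raise ParameterError(f"unknown alternative {alternative!r}")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return RankSumResult(
            statistic_U=n_a * n_b / 2.0, p_value=1.0, n_a=n_a, n_b=n_b,
            alternative=alternative, method="degenerate", degenerate=True,
        )
    ranks = sps.rankdata(pooled)  # midranks
    u_a = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    nm = n_a * n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()

    if not has_ties and nm <= 400:
        pmf = _exact_u_pmf(n_a, n_b)
        u = int(round(u_a))
        if alternative == "two_sided":
            lo = min(u, nm - u)
            p = pmf[: lo + 1].sum() + pmf[nm - lo:].sum()
            if lo == nm - lo:  # centre counted twice
                p -= pmf[lo]
        elif alternative == "less":
            p = pmf[: u + 1].sum()
        else:
            p = pmf[u:].sum()
        return RankSumResult(
            statistic_U=float(u_a), p_value=float(min(p, 1.0)),
            n_a=n_a, n_b=n_b, alternative=alternative, method="exact",
        )

    n = n_a + n_b
    mu = nm / 2.0
    tie_term = (tie_counts ** 3 - tie_counts).sum() / ((n * (n - 1)) or 1)
    sigma2 = nm / 12.0 * (n + 1 - tie_term)
    sigma = np.sqrt(sigma2)
    if sigma == 0:
        p = 1.0
    elif alternative == "two_sided":
        z = (abs(u_a - mu) - 0.5) / sigma
        p = 2.0 * sps.norm.sf(max(z, 0.0))
    elif alternative == "less":
        z = (u_a - mu + 0.5) / sigma
        p = sps.norm.cdf(z)
    else:
        z = (u_a - mu - 0.5) / sigma
        p = sps.norm.sf(z)
    p = float(min(max(p, np.finfo(float).tiny), 1.0))  # keep p in (0, 1]
    return RankSumResult(
        statistic_U=float(u_a), p_value=p,
        n_a=n_a, n_b=n_b, alternative=alternative, method="normal",
    )


# ---------------------------------------------------------------------------
# Divergence-over-time regression
# ---------------------------------------------------------------------------

def _ols_line(t: np.ndarray, y: np.ndarray, population: str) -> DivergenceResult:
    n = t.size
    if np.unique(t).size < 2:
        raise InsufficientDataError(
            f"divergence regression for {population!r}: a single timepoint "
            "gives no variance in the predictor"
        )
    tbar, ybar = t.mean(), y.mean()
    sxx = ((t - tbar) ** 2).sum()
    sxy = ((t - tbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    resid = y - (intercept + slope * t)
    sse = (resid ** 2).sum()
    sst = ((y - ybar) ** 2).sum()
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    df = n - 2
    if df <= 0 or sse <= 1e-300:
        p = 0.0 if (df > 0 and slope != 0) else 1.0
        if sse <= 1e-300 and slope == 0:
            p = 1.0
    else:
        se = np.sqrt(sse / df / sxx)
        tstat = slope / se
        p = 2.0 * sps.t.sf(abs(tstat), df)
    return DivergenceResult(
        slope=float(slope), intercept=float(intercept),
        slope_p_value=float(p), r_squared=float(max(min(r2, 1.0), 0.0)),
        population=population, n_pairs=int(n),
    )


def divergence_regression(pairs: pd.DataFrame, per_population: bool = False) -> List[DivergenceResult]:
    """OLS of within-population garden-vs-field dissimilarity on days.

    ``pairs`` is a long-format comparison frame (see
    :func:`restrans.distance.pairwise_comparisons`); only rows with
    ``comparison_class == "within_population"`` and a defined timepoint are
    used. Each garden-sample x field-sample pair is one observation.
    Returns the pooled fit first, then one fit per population when
    ``per_population`` is set.
    """
    sub = pairs[
        (pairs["comparison_class"] == "within_population")
        & pairs["timepoint"].notna()
    ]
    if sub.empty:
        raise InsufficientDataError("no within-population garden-vs-field pairs")
    t = sub["timepoint"].to_numpy(dtype=float)
    y = sub["dissimilarity"].to_numpy(dtype=float)
    results = [_ols_line(t, y, "pooled")]
    if per_population:
        for pop, block in sub.groupby("population_a", sort=True):
            results.append(
                _ols_line(
                    block["timepoint"].to_numpy(dtype=float),
                    block["dissimilarity"].to_numpy(dtype=float),
                    str(pop),
                )
            )
    return results
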