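"""Bray-Curtis dissimilarity, PCoA ordination, and permutation group tests.

PERMANOVA (one-factor pseudo-F on the distance sum-of-squares decomposition),
ANOSIM (Clarke's rank-based R) and MRPP (group-size-weighted mean within-group
distance delta with chance-corrected A) are implemented directly from their
defining statistics.  Significance comes from label permutation; for
two-group designs with few enough distinct label assignments the full set is
enumerated, which removes Monte-Carlo noise (a 6+6 design has 924 splits).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .errors import InvalidDesignError, UndefinedDistanceError
from .matrix import NormalizedMatrix


def bray_curtis(nm: NormalizedMatrix) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarities
    ``d(i,j) = sum|x_i - x_j| / sum(x_i + x_j)``."""
    x = nm.rel.T.values
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise UndefinedDistanceError("two all-zero samples have undefined distance")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=nm.samples, columns=nm.samples)


# ---------------------------------------------------------------------------
# permutation machinery


@dataclass
class MultivariateTestResult:
    """Observed statistic of a permutation test plus its permutation p value.

    ``method`` is ``"exact"`` when every distinct label assignment was
    enumerated (then the p value is seed-independent) and ``"sampled"``
    otherwise.  ``extras`` carries test-specific quantities (e.g. MRPP's
    chance-corrected A)."""

    name: str
    statistic: float
    p_value: float
    n_perm: int
    method: str
    extras: dict = field(default_factory=dict)


def _as_codes(groups) -> tuple[np.ndarray, list]:
    labels = list(groups)
    uniq: list = []
    for g in labels:
        if g not in uniq:
            uniq.append(g)
    codes = np.array([uniq.index(g) for g in labels])
    counts = np.bincount(codes)
    if len(uniq) < 2:
        raise InvalidDesignError("at least two groups required")
    if (counts < 2).any():
        raise InvalidDesignError("each group needs at least 2 samples")
    return codes, uniq


def _check_dist(dist: pd.DataFrame) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    return d


def _permutation_test(
    stat_fun, codes: np.ndarray, n_perm: int, seed: int,
    alternative: str, max_exact: int = 10_000,
):
    """Generic label-permutation engine.

    Returns (observed, p, n_perm_used, method, perm_stats).  Exact
    enumeration (2-group designs) iterates every distinct assignment of the
    smaller group's positions; the observed assignment is among them, so the
    p value can never be 0.
    """
    observed = stat_fun(codes)
    n = len(codes)
    counts = np.bincount(codes)
    two_groups = len(counts) == 2
    n_exact = comb(n, counts[0]) if two_groups else None
    ge = (lambda s: s >= observed - 1e-12) if alternative == "greater" else (
        lambda s: s <= observed + 1e-12)

    if two_groups and n_exact <= max_exact:
        stats_all = np.empty(n_exact)
        template = np.ones(n, dtype=codes.dtype)
        for k, idx in enumerate(combinations(range(n), int(counts[0]))):
            perm = template.copy()
            perm[list(idx)] = 0
            stats_all[k] = stat_fun(perm)
        extreme = int(sum(ge(s) for s in stats_all))
        return observed, extreme / n_exact, n_exact, "exact", stats_all

    rng = np.random.default_rng(seed)
    stats_all = np.empty(n_perm)
    for k in range(n_perm):
        stats_all[k] = stat_fun(rng.permutation(codes))
    extreme = int(sum(ge(s) for s in stats_all))
    return observed, (extreme + 1) / (n_perm + 1), n_perm, "sampled", stats_all


# ---------------------------------------------------------------------------
# the three tests


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, 1)
    return iu[0], iu[1]


def permanova(
    dist: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0,
    max_exact: int = 10_000,
) -> MultivariateTestResult:
    """One-factor PERMANOVA: pseudo-F from the within/between decomposition
    of squared distances, p by label permutation."""
    d = _check_dist(dist)
    codes, uniq = _as_codes(groups)
    n = len(codes)
    a = len(uniq)
    ii, jj = _pair_indices(n)
    d2 = d[ii, jj] ** 2
    ss_total = d2.sum() / n

    def pseudo_f(perm: np.ndarray) -> float:
        ss_within = 0.0
        for g in range(a):
            mask = (perm[ii] == g) & (perm[jj] == g)
            n_g = int((perm == g).sum())
            ss_within += d2[mask].sum() / n_g
        ss_between = ss_total - ss_within
        if ss_within <= 0:
            return np.inf
        return (ss_between / (a - 1)) / (ss_within / (n - a))

    obs, p, used, method, _ = _permutation_test(
        pseudo_f, codes, n_perm, seed, "greater", max_exact)
    return MultivariateTestResult("pseudo-F", float(obs), float(p), used, method)


def anosim(
    dist: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0,
    max_exact: int = 10_000,
) -> MultivariateTestResult:
    """Clarke's ANOSIM R = (mean between-group rank - mean within-group rank)
    divided by M/2 with M = n(n-1)/2; midrank ties."""
    d = _check_dist(dist)
    codes, _ = _as_codes(groups)
    n = len(codes)
    ii, jj = _pair_indices(n)
    ranks = rankdata(d[ii, jj])
    m = n * (n - 1) / 2

    def r_stat(perm: np.ndarray) -> float:
        within = perm[ii] == perm[jj]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)

    obs, p, used, method, _ = _permutation_test(
        r_stat, codes, n_perm, seed, "greater", max_exact)
    return MultivariateTestResult("R", float(obs), float(p), used, method)


def mrpp(
    dist: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0,
    max_exact: int = 10_000,
) -> MultivariateTestResult:
    """MRPP delta = sum_g (n_g/N) * mean within-group distance; small delta
    indicates group cohesion, so p is one-sided toward small values.  The
    chance-corrected within-group agreement A = 1 - delta / E[delta] uses the
    permutation mean as E[delta]."""
    d = _check_dist(dist)
    codes, uniq = _as_codes(groups)
    n = len(codes)
    ii, jj = _pair_indices(n)
    dc = d[ii, jj]

    def delta(perm: np.ndarray) -> float:
        out = 0.0
        for g in range(len(uniq)):
            mask = (perm[ii] == g) & (perm[jj] == g)
            n_g = int((perm == g).sum())
            out += (n_g / n) * dc[mask].mean()
        return out

    obs, p, used, method, perm_stats = _permutation_test(
        delta, codes, n_perm, seed, "less", max_exact)
    expected = float(np.mean(perm_stats)) if method == "exact" else float(
        np.mean(np.append(perm_stats, obs)))
    a_stat = 1.0 - obs / expected if expected > 0 else np.nan
    return MultivariateTestResult(
        "delta", float(obs), float(p), used, method,
        extras={"A": float(a_stat), "expected_delta": expected},
    )


# ---------------------------------------------------------------------------
# ordination


@dataclass
class PCoAResult:
    """Classical (metric) scaling of a dissimilarity matrix.

    ``eigenvalues`` contains the full spectrum in descending order including
    any negative values (a diagnostic for non-Euclidean dissimilarities);
    coordinates use the positive eigenvalues only."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dist: pd.DataFrame) -> PCoAResult:
    """Principal-coordinates analysis via double-centering of squared
    distances."""
    d = _check_dist(dist)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10 * max(1.0, abs(eigval[0]))
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    # deterministic sign: largest-magnitude loading positive per axis
    for k in range(coords.shape[1]):
        i_max = np.argmax(np.abs(coords[:, k]))
        if coords[i_max, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = eigval[pos].sum()
    prop = np.where(pos, eigval / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(n)
    cols = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    return PCoAResult(pd.DataFrame(coords, index=index, columns=cols), eigval, prop)
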