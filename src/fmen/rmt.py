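"""RMT-thresholded functional gene co-occurrence networks.

The similarity threshold St is chosen by a random-matrix-theory criterion:
as the threshold rises, the eigenvalue nearest-neighbor spacing distribution
(NNSD) of the thresholded correlation matrix transitions from
Gaussian-orthogonal-ensemble (Wigner) statistics, typical of dense random
correlations, to Poisson statistics ``P(s) = exp(-s)``, typical of systems of
independent blocks.  St is the smallest grid value whose NNSD is
Poisson-consistent and stays consistent for every larger grid value.

Unfolding maps eigenvalues through a smooth fit of the cumulative spectral
function so the mean spacing is exactly 1.  Thresholded correlation matrices
carry heavily degenerate eigenvalues (isolated rows contribute exact 1s, and
a correlation matrix estimated from few samples is rank-deficient, so exact
0s appear); degenerate values are collapsed to a single representative before
unfolding, as zero spacings would otherwise swamp the spacing statistics.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyNetworkError, InsufficientSpectrumError, InvalidDesignError, NoTransitionError
from .matrix import NormalizedMatrix


# ---------------------------------------------------------------------------
# correlations


@dataclass
class CorrelationMatrix:
    """Gene x gene Pearson correlations within one group's samples."""

    genes: list[str]
    r: np.ndarray
    group: str
    n_samples: int
    dropped_zero_variance: list[str] = field(default_factory=list)


def correlation_matrix(
    nm: NormalizedMatrix,
    group: str,
    min_detected_fraction: float = 0.5,
    families: tuple[str, ...] | None = None,
    catalog: pd.DataFrame | None = None,
) -> CorrelationMatrix:
    """Pearson correlations between genes across one group's samples.

    Genes detected in fewer than ``min_detected_fraction`` of the group's
    samples are excluded (correlation over 6 samples is already fragile;
    heavy missingness makes it meaningless).  ``families`` optionally
    restricts to a set of gene families (requires ``catalog``).
    Zero-variance genes are excluded with a warning rather than propagating
    NaNs.
    """
    cols = nm.sample_ids(group)
    if len(cols) < 3:
        raise InvalidDesignError("Pearson correlation needs at least 3 samples")
    keep = nm.detected[cols].mean(axis=1) >= min_detected_fraction
    if families is not None:
        if catalog is None:
            raise ValueError("families filter requires a catalog")
        keep &= catalog.loc[nm.rel.index, "gene_family"].isin(families)
    x = nm.rel.loc[keep, cols].values
    genes = list(nm.rel.index[keep])
    sd = x.std(axis=1)
    nonconst = sd > 0
    dropped = [g for g, ok in zip(genes, nonconst) if not ok]
    if dropped:
        warnings.warn(f"excluded {len(dropped)} zero-variance genes")
    x = x[nonconst]
    genes = [g for g, ok in zip(genes, nonconst) if ok]
    if len(genes) < 2:
        raise InvalidDesignError("fewer than 2 genes available for correlation")
    r = np.corrcoef(x)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(genes, r, group, len(cols), dropped)


# ---------------------------------------------------------------------------
# NNSD machinery


def threshold_matrix(r: np.ndarray, st: float) -> np.ndarray:
    """Zero out off-diagonal entries with ``|r| < st`` (diagonal stays 1)."""
    a = np.where(np.abs(r) >= st, r, 0.0)
    np.fill_diagonal(a, 1.0)
    return a


def unfold_spacings(
    eigenvalues: np.ndarray,
    method: str = "spline",
    n_knots: int = 15,
    degree: int = 5,
) -> np.ndarray:
    """Nearest-neighbor spacings of the unfolded spectrum.

    The cumulative spectral function (eigenvalue rank vs eigenvalue) is fit
    with a smooth monotone curve; eigenvalues are mapped through the fit and
    differenced, and the spacings rescaled so their mean is exactly 1.

    ``method="spline"`` (default) interpolates the staircase with a monotone
    piecewise cubic (PCHIP) through quantile knots, which adapts to strongly
    non-uniform spectral densities (a thresholded correlation matrix has a
    dense bulk plus isolated block eigenvalues).  The knot count scales with
    the spectrum (one per ~15 levels, capped at ``n_knots``) so that local
    spacing fluctuations — the signal NNSD measures — are not smoothed away.
    ``method="poly"`` uses a global polynomial of the given degree; it is not
    monotone, so locally decreasing stretches are clipped to zero spacing.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    n = len(lam)
    if n < 3:
        raise InsufficientSpectrumError(n, 3)
    if method == "spline":
        from scipy.interpolate import PchipInterpolator

        k = max(3, min(n_knots, n // 15, n))
        pos = np.unique(np.linspace(0, n - 1, k).astype(int))
        fit = PchipInterpolator(lam[pos], pos + 1.0)
        xi = fit(lam)
    elif method == "poly":
        deg = min(degree, n - 1)
        coeffs = np.polyfit(lam, np.arange(1, n + 1, dtype=float), deg)
        xi = np.polyval(coeffs, lam)
    else:
        raise ValueError("method must be 'spline' or 'poly'")
    s = np.clip(np.diff(xi), 0.0, None)
    mean = s.mean()
    if mean <= 0:
        raise InsufficientSpectrumError(n, 3)
    return s / mean


def poisson_spacing_gof(
    spacings: np.ndarray,
    bin_width: float = 0.5,
    s_max: float = 5.0,
    min_expected: float = 5.0,
) -> tuple[float, float]:
    """Chi-square goodness of fit of spacings against ``P(s) = exp(-s)``.

    Fixed bins of ``bin_width`` on ``[0, s_max]`` plus an open tail; sparse
    rightmost bins are pooled until each expected count reaches
    ``min_expected``.  Returns ``(chi2, p)``.
    """
    s = np.asarray(spacings, dtype=float)
    n = len(s)
    edges = list(np.arange(0.0, s_max + bin_width / 2, bin_width)) + [np.inf]
    probs = [np.exp(-edges[k]) - np.exp(-edges[k + 1]) for k in range(len(edges) - 1)]
    observed = np.histogram(s, bins=edges)[0].astype(float)
    expected = n * np.array(probs)
    # pool the right tail until expected counts are adequate
    while len(expected) > 2 and expected[-1] < min_expected:
        expected[-2] += expected[-1]
        observed[-2] += observed[-1]
        expected, observed = expected[:-1], observed[:-1]
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    dof = len(expected) - 1
    return chi2, float(stats.chi2.sf(chi2, dof))


@dataclass
class NNSDResult:
    chi2: float
    p_value: float
    spacings: np.ndarray
    n_eigenvalues: int


def nnsd_poisson_gof(
    corr: CorrelationMatrix | np.ndarray,
    st: float,
    min_eigenvalues: int = 100,
    dedup_decimals: int = 8,
    method: str = "spline",
    n_knots: int = 15,
    degree: int = 5,
) -> NNSDResult:
    """NNSD Poisson test of the correlation matrix thresholded at ``st``."""
    if not 0.0 < st < 1.0:
        raise ValueError("st must lie in (0, 1)")
    r = corr.r if isinstance(corr, CorrelationMatrix) else np.asarray(corr)
    a = threshold_matrix(r, st)
    eig = np.linalg.eigvalsh(a)
    uniq = np.unique(np.round(eig, dedup_decimals))
    if len(uniq) < min_eigenvalues:
        raise InsufficientSpectrumError(len(uniq), min_eigenvalues)
    s = unfold_spacings(uniq, method=method, n_knots=n_knots, degree=degree)
    chi2, p = poisson_spacing_gof(s)
    return NNSDResult(chi2, p, s, len(uniq))


@dataclass
class ThresholdScanResult:
    st: float
    trace: pd.DataFrame  # threshold, n_eigenvalues, chi2, p, consistent
    method: str = "scan"  # "scan" | "max_p_fallback"


def rmt_threshold_scan(
    corr: CorrelationMatrix | np.ndarray,
    grid: np.ndarray | None = None,
    alpha: float = 0.05,
    min_eigenvalues: int = 100,
    method: str = "spline",
    n_knots: int = 15,
    degree: int = 5,
    on_no_transition: str = "raise",
) -> ThresholdScanResult:
    """Scan a threshold grid for the GOE -> Poisson transition.

    St is the smallest grid value whose NNSD is Poisson-consistent
    (``p > alpha``), the transition-detection convention of RMT-based
    correlation-network pipelines.  Thresholds far beyond the transition
    fragment the matrix into many near-identical 2-3-gene blocks whose
    near-degenerate eigenvalues cluster, so the spacing test rejects again
    up there; those rejections are over-thresholding artifacts, not part of
    the GOE -> Poisson transition, and do not veto the selection.  The full
    per-threshold trace is returned for audit.  Thresholds whose spectrum is
    too small to evaluate are recorded with NaN and skipped.

    With few samples per group the Poisson-consistent window can shrink to a
    single grid point whose p value hovers around ``alpha``;
    ``on_no_transition="max_p"`` then falls back to the most Poisson-like
    threshold (largest p) instead of raising, flagged in ``result.method``.
    """
    if on_no_transition not in ("raise", "max_p"):
        raise ValueError("on_no_transition must be 'raise' or 'max_p'")
    if grid is None:
        grid = np.round(np.arange(0.30, 0.995, 0.01), 2)
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be ascending and non-empty")
    rows = []
    for st in grid:
        try:
            res = nnsd_poisson_gof(corr, st, min_eigenvalues=min_eigenvalues,
                                   method=method, n_knots=n_knots, degree=degree)
            rows.append((st, res.n_eigenvalues, res.chi2, res.p_value,
                         res.p_value > alpha))
        except InsufficientSpectrumError as e:
            rows.append((st, e.n_found, np.nan, np.nan, None))
    trace = pd.DataFrame(
        rows, columns=["threshold", "n_eigenvalues", "chi2", "p", "consistent"]
    )
    selected = None
    for _, row in trace.iterrows():
        if row["consistent"]:
            selected = float(row["threshold"])
            break
    if selected is not None:
        return ThresholdScanResult(selected, trace, "scan")
    if on_no_transition == "max_p" and trace["p"].notna().any():
        # Restrict the fallback to thresholds that retain at least half the
        # genes' eigenvalues: far beyond the transition most of the spectrum
        # collapses into degenerate isolated-row eigenvalues, and the spacing
        # test there says nothing about the GOE -> Poisson transition.
        n_genes = (corr.r if isinstance(corr, CorrelationMatrix) else
                   np.asarray(corr)).shape[0]
        eligible = trace[trace["n_eigenvalues"] >= n_genes / 2]
        pool = eligible if eligible["p"].notna().any() else trace
        best = pool["p"].idxmax()
        warnings.warn(
            f"no Poisson-consistent threshold at alpha={alpha}; falling back "
            f"to the most Poisson-like grid point "
            f"St={trace.loc[best, 'threshold']}")
        return ThresholdScanResult(
            float(trace.loc[best, "threshold"]), trace, "max_p_fallback")
    raise NoTransitionError(
        "no threshold reaches Poisson statistics; try a finer or wider grid")


# ---------------------------------------------------------------------------
# graph construction and topology


def build_network(
    corr: CorrelationMatrix,
    st: float,
    catalog: pd.DataFrame | None = None,
) -> nx.Graph:
    """Signed undirected graph with an edge wherever ``|r| >= st`` off the
    diagonal.  Nodes with no edges are dropped ("network size" counts
    connected genes only)."""
    n = len(corr.genes)
    iu = np.triu_indices(n, 1)
    mask = np.abs(corr.r[iu]) >= st
    g = nx.Graph(st=st, group=corr.group)
    for i, j in zip(iu[0][mask], iu[1][mask]):
        r = float(corr.r[i, j])
        g.add_edge(corr.genes[i], corr.genes[j], r=r, sign=1 if r >= 0 else -1)
    if g.number_of_edges() == 0:
        raise EmptyNetworkError(f"no correlations reach |r| >= {st}")
    if catalog is not None:
        for node in g.nodes:
            if node in catalog.index:
                g.nodes[node]["gene_family"] = str(catalog.loc[node, "gene_family"])
                g.nodes[node]["category"] = str(catalog.loc[node, "category"])
    return g


def avg_connectivity(n_nodes: int, n_links: int) -> float:
    """Average connectivity avgK = 2L/n."""
    return 2.0 * n_links / n_nodes


def harmonic_geodesic_distance(g: nx.Graph) -> float:
    """Harmonic mean of geodesic distances over all unordered node pairs.

    Disconnected pairs contribute zero reciprocal distance, so the statistic
    stays finite on disconnected graphs (the usual case after RMT
    thresholding, where networks split into many modules)."""
    n = g.number_of_nodes()
    if n < 2:
        return float("nan")
    recip = 0.0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for d in lengths.values():
            if d > 0:
                recip += 1.0 / d
    recip /= 2.0  # each unordered pair visited twice
    if recip == 0:
        return float("inf")
    return (n * (n - 1) / 2) / recip


def power_law_r2(g: nx.Graph) -> float:
    """R^2 of the OLS fit of log frequency on log degree over the nonempty
    degree bins — the scale-free screening statistic, not a rigorous
    power-law fit."""
    degs = np.array([d for _, d in g.degree()])
    vals, counts = np.unique(degs[degs > 0], return_counts=True)
    if len(vals) < 2:
        return float("nan")
    fit = stats.linregress(np.log(vals), np.log(counts))
    return float(fit.rvalue ** 2)


def modularity_partition(g: nx.Graph) -> tuple[list[set], float, int]:
    """Greedy agglomerative (CNM) modularity maximization, signs ignored.

    Returns the partition (communities ordered by smallest member), the
    modularity Q = sum_i (e_ii - a_i^2), and the module count."""
    comms = nx.community.greedy_modularity_communities(g)
    partition = sorted((set(c) for c in comms), key=lambda c: min(map(str, c)))
    q = nx.community.modularity(g, partition)
    return partition, float(q), len(partition)


@dataclass
class TopologySummary:
    """The per-network row of a two-lake topology comparison."""

    n_nodes: int
    n_links: int
    positive_fraction: float
    negative_fraction: float
    avg_k: float
    power_law_r2: float
    harmonic_geodesic_distance: float
    avg_clustering: float
    modularity: float
    n_modules: int

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_links": self.n_links,
            "positive_fraction": self.positive_fraction,
            "negative_fraction": self.negative_fraction,
            "avg_k": self.avg_k,
            "power_law_r2": self.power_law_r2,
            "harmonic_geodesic_distance": self.harmonic_geodesic_distance,
            "avg_clustering": self.avg_clustering,
            "modularity": self.modularity,
            "n_modules": self.n_modules,
        }


def topology_summary(g: nx.Graph) -> TopologySummary:
    """Topology statistics of a signed network: size, links, sign fractions,
    avgK, power-law R^2, harmonic geodesic distance, average clustering
    (nodes of degree < 2 count as 0), modularity and module count."""
    n, l = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise EmptyNetworkError("empty network")
    signs = [d.get("sign", 1) for _, _, d in g.edges(data=True)]
    pos = sum(1 for s in signs if s > 0)
    _, q, n_mod = modularity_partition(g)
    return TopologySummary(
        n_nodes=n,
        n_links=l,
        positive_fraction=pos / l if l else float("nan"),
        negative_fraction=(l - pos) / l if l else float("nan"),
        avg_k=avg_connectivity(n, l),
        power_law_r2=power_law_r2(g),
        harmonic_geodesic_distance=harmonic_geodesic_distance(g),
        avg_clustering=float(nx.average_clustering(g, count_zeros=True)),
        modularity=q,
        n_modules=n_mod,
    )


def hub_genes(g: nx.Graph, k: int = 5) -> pd.DataFrame:
    """Top-k nodes by degree (ties broken by node ID), with annotations."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > g.number_of_nodes():
        warnings.warn(f"k={k} exceeds network size {g.number_of_nodes()}; returning all")
        k = g.number_of_nodes()
    ranked = sorted(g.degree(), key=lambda nd: (-nd[1], str(nd[0])))[:k]
    rows = [
        (node, deg, g.nodes[node].get("gene_family"), g.nodes[node].get("category"))
        for node, deg in ranked
    ]
    return pd.DataFrame(rows, columns=["gene", "degree", "gene_family", "category"])
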