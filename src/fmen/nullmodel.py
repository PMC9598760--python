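"""Degree-preserving rewiring null models and the two-lake comparison report.

The null model is the Maslov-Sneppen switch chain: repeatedly propose a
uniformly random pair of distinct edges and swap their endpoints, rejecting
proposals that would create a self-loop or duplicate an existing edge.  The
number of *attempts* (including rejections) is ``swap_factor x L``; counting
rejected proposals keeps the chain's stationary distribution uniform over the
set of simple graphs with the empirical degree sequence.  Edge signs are
reassigned at random, preserving the global positive/negative counts.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigMismatchError
from .rmt import (
    TopologySummary,
    harmonic_geodesic_distance,
    modularity_partition,
    topology_summary,
)


def rewire_degree_preserving(
    g: nx.Graph, swap_factor: float = 10.0, seed: int = 0
) -> nx.Graph:
    """Degree-preserving randomization by double-edge swaps.

    Performs ``swap_factor x L`` swap attempts.  Graphs that admit no valid
    swap (a star, a single triangle) come back unchanged with a warning.
    """
    h = g.copy()
    edges = [tuple(sorted(e)) for e in h.edges()]
    l = len(edges)
    if l < 2:
        warnings.warn("graph has fewer than 2 edges; no rewiring possible")
        return h
    rng = np.random.default_rng(seed)
    edge_set = set(edges)
    n_attempts = max(1, int(round(swap_factor * l)))
    successes = 0
    pick = rng.integers(0, l, size=(n_attempts, 2))
    orient = rng.random(n_attempts) < 0.5
    for t in range(n_attempts):
        i, j = pick[t]
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if orient[t]:
            c, d = d, c
        # proposed replacement: (a,c) and (b,d)
        if a == c or b == d:
            continue
        e1 = (a, c) if a < c else (c, a)
        e2 = (b, d) if b < d else (d, b)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i], edges[j] = e1, e2
        successes += 1
    if successes == 0:
        warnings.warn("no valid double-edge swap was found; returning the "
                      "graph unchanged")
        return h
    signs = [d.get("sign", 1) for _, _, d in g.edges(data=True)]
    rng.shuffle(signs)
    out = nx.Graph(**g.graph)
    out.add_nodes_from(g.nodes(data=True))
    for (u, v), s in zip(sorted(edge_set), signs):
        out.add_edge(u, v, sign=int(s))
    return out


NULL_METRICS = ("harmonic_geodesic_distance", "avg_clustering", "modularity")


@dataclass
class NullEnsembleSummary:
    """Null-ensemble statistics of the rewired replicates.

    ``table`` has one row per metric with the empirical value, the null mean
    and SD over replicates, and the z score (empirical - mean) / SD.  A zero
    null SD yields an infinite z, flagged in ``degenerate``."""

    n_replicates: int
    swap_factor: float
    seed: int
    table: pd.DataFrame
    degenerate: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "swap_factor": self.swap_factor,
            "seed": self.seed,
            "table": {m: {c: float(self.table.loc[m, c]) for c in self.table.columns}
                      for m in self.table.index},
            "degenerate": dict(self.degenerate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NullEnsembleSummary":
        table = pd.DataFrame(d["table"]).T.loc[list(NULL_METRICS)]
        return cls(d["n_replicates"], d["swap_factor"], d["seed"], table,
                   dict(d["degenerate"]))


def _null_metrics(h: nx.Graph) -> dict[str, float]:
    return {
        "harmonic_geodesic_distance": harmonic_geodesic_distance(h),
        "avg_clustering": float(nx.average_clustering(h, count_zeros=True)),
        "modularity": modularity_partition(h)[1],
    }


def null_ensemble_summary(
    g: nx.Graph,
    n_replicates: int = 100,
    swap_factor: float = 10.0,
    seed: int = 0,
) -> NullEnsembleSummary:
    """Metric means/SDs over degree-preserving rewired replicates with the
    empirical z score per metric.  Per-replicate seeds are derived from the
    master seed by fixed increments; every replicate's degree sequence is
    asserted equal to the empirical one."""
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    empirical_degrees = dict(g.degree())
    empirical = _null_metrics(g)
    reps = {m: np.empty(n_replicates) for m in NULL_METRICS}
    for i in range(n_replicates):
        h = rewire_degree_preserving(g, swap_factor, seed=seed + 1 + i)
        if dict(h.degree()) != empirical_degrees:
            raise AssertionError("rewired replicate changed the degree sequence")
        vals = _null_metrics(h)
        for m in NULL_METRICS:
            reps[m][i] = vals[m]
    rows, degenerate = [], {}
    for m in NULL_METRICS:
        mean = float(reps[m].mean())
        sd = float(reps[m].std(ddof=1))
        if sd == 0:
            z = float(np.inf) if empirical[m] != mean else 0.0
            degenerate[m] = True
        else:
            z = (empirical[m] - mean) / sd
            degenerate[m] = False
        rows.append((empirical[m], mean, sd, z))
    table = pd.DataFrame(rows, index=list(NULL_METRICS),
                         columns=["empirical", "null_mean", "null_sd", "z"])
    return NullEnsembleSummary(n_replicates, swap_factor, seed, table, degenerate)


# ---------------------------------------------------------------------------
# two-lake comparison report


@dataclass
class LakeReport:
    """One lake's network results under a given analysis configuration."""

    group: str
    st: float
    n_genes_correlated: int
    topology: TopologySummary
    null_summary: NullEnsembleSummary
    hubs: pd.DataFrame
    config: dict
    st_method: str = "scan"

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "st": self.st,
            "st_method": self.st_method,
            "n_genes_correlated": self.n_genes_correlated,
            "topology": self.topology.to_dict(),
            "null_summary": self.null_summary.to_dict(),
            "hubs": self.hubs.to_dict(orient="records"),
            "config": dict(self.config),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LakeReport":
        return cls(
            group=d["group"],
            st=d["st"],
            st_method=d.get("st_method", "scan"),
            n_genes_correlated=d["n_genes_correlated"],
            topology=TopologySummary(**d["topology"]),
            null_summary=NullEnsembleSummary.from_dict(d["null_summary"]),
            hubs=pd.DataFrame(d["hubs"], columns=["gene", "degree", "gene_family",
                                                  "category"]),
            config=dict(d["config"]),
        )


@dataclass
class LakeComparisonReport:
    """Side-by-side topology comparison of the two lakes, plus optional
    diversity / community-test sections attached by the pipeline."""

    reports: dict[str, LakeReport]
    sections: dict = field(default_factory=dict)

    def side_by_side(self) -> pd.DataFrame:
        cols = {}
        for g, rep in self.reports.items():
            col = rep.topology.to_dict()
            col["st"] = rep.st
            col["n_genes_correlated"] = rep.n_genes_correlated
            for m in rep.null_summary.table.index:
                col[f"null_mean_{m}"] = rep.null_summary.table.loc[m, "null_mean"]
                col[f"null_sd_{m}"] = rep.null_summary.table.loc[m, "null_sd"]
                col[f"z_{m}"] = rep.null_summary.table.loc[m, "z"]
            cols[g] = col
        return pd.DataFrame(cols)

    def to_dict(self) -> dict:
        return {
            "reports": {g: r.to_dict() for g, r in self.reports.items()},
            "sections": self.sections,
        }

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "LakeComparisonReport":
        return cls(
            reports={g: LakeReport.from_dict(r) for g, r in d["reports"].items()},
            sections=d.get("sections", {}),
        )

    @classmethod
    def from_json(cls, text: str) -> "LakeComparisonReport":
        return cls.from_dict(json.loads(text))

    def to_tsv(self, path: str) -> None:
        table = self.side_by_side()
        table.index.name = "metric"
        table.to_csv(path, sep="\t")


def compare_lakes(
    report_a: LakeReport, report_b: LakeReport, sections: dict | None = None
) -> LakeComparisonReport:
    """Combine two per-lake reports produced under the same configuration."""
    if report_a.config != report_b.config:
        raise ConfigMismatchError(
            "lake reports were produced under different analysis configs")
    return LakeComparisonReport(
        reports={report_a.group: report_a, report_b.group: report_b},
        sections=sections or {},
    )
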