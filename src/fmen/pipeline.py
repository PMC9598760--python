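"""End-to-end two-lake analysis: preprocessing -> diversity -> community
tests -> per-lake RMT network -> null ensemble -> comparison report."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import community, diversity, rmt
from .matrix import NormalizedMatrix, SignalMatrix
from .preprocess import preprocess as _preprocess
from .nullmodel import LakeComparisonReport, LakeReport, compare_lakes, null_ensemble_summary
from .synthetic import CORE_NETWORK_FAMILIES


@dataclass
class AnalysisConfig:
    """Parameters of the full pipeline (shared by both lakes)."""

    snr_min: float = 2.0
    min_detected_fraction: float = 0.5
    families: tuple[str, ...] | None = CORE_NETWORK_FAMILIES
    grid_start: float = 0.30
    grid_stop: float = 0.99
    grid_step: float = 0.01
    alpha_rmt: float = 0.05
    min_eigenvalues: int = 100
    unfold_method: str = "spline"
    unfold_knots: int = 15
    unfold_degree: int = 5
    st_override: float | None = None
    scan_fallback: bool = True
    n_perm: int = 999
    n_null: int = 100
    swap_factor: float = 10.0
    hub_k: int = 5

    def grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.grid_start, self.grid_stop + self.grid_step / 2,
                      self.grid_step),
            6,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["families"] is not None:
            d["families"] = list(d["families"])
        return d


def analyze_lake(
    nm: NormalizedMatrix,
    catalog: pd.DataFrame,
    group: str,
    config: AnalysisConfig,
    seed: int = 0,
) -> LakeReport:
    """RMT network + null ensemble for one lake."""
    corr = rmt.correlation_matrix(
        nm, group,
        min_detected_fraction=config.min_detected_fraction,
        families=config.families,
        catalog=catalog,
    )
    if config.st_override is not None:
        st, st_method = config.st_override, "override"
    else:
        scan = rmt.rmt_threshold_scan(
            corr, grid=config.grid(), alpha=config.alpha_rmt,
            min_eigenvalues=config.min_eigenvalues,
            method=config.unfold_method, n_knots=config.unfold_knots,
            degree=config.unfold_degree,
            on_no_transition="max_p" if config.scan_fallback else "raise",
        )
        st, st_method = scan.st, scan.method
    g = rmt.build_network(corr, st, catalog=catalog)
    topo = rmt.topology_summary(g)
    null = null_ensemble_summary(
        g, n_replicates=config.n_null, swap_factor=config.swap_factor, seed=seed)
    hubs = rmt.hub_genes(g, config.hub_k)
    return LakeReport(
        group=group,
        st=st,
        st_method=st_method,
        n_genes_correlated=len(corr.genes),
        topology=topo,
        null_summary=null,
        hubs=hubs,
        config=config.to_dict(),
    )


@dataclass
class TwoLakeResult:
    """Everything the pipeline computes on a two-lake dataset."""

    normalized: NormalizedMatrix
    preprocess_log: pd.DataFrame
    alpha: diversity.AlphaDiversityResult
    partition: diversity.GenePartition
    category_table: pd.DataFrame
    dissimilarity: pd.DataFrame
    tests: dict[str, community.MultivariateTestResult]
    report: LakeComparisonReport
    networks: dict = field(default_factory=dict)


def analyze_two_lakes(
    sm: SignalMatrix,
    catalog: pd.DataFrame,
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> TwoLakeResult:
    """Run the full comparison pipeline on a raw two-lake signal matrix."""
    config = config or AnalysisConfig()
    nm, log = _preprocess(sm, snr_min=config.snr_min)
    alpha = diversity.alpha_diversity(nm)
    sets = diversity.group_detected_sets(nm)
    ga, gb = nm.group_names()
    partition = diversity.shared_unique_partition(sets[ga], sets[gb])
    cat_table = diversity.category_intensity_compare(nm, catalog, by="category")

    dist = community.bray_curtis(nm)
    groups = nm.groups
    tests = {
        "permanova": community.permanova(dist, groups, config.n_perm, seed),
        "anosim": community.anosim(dist, groups, config.n_perm, seed),
        "mrpp": community.mrpp(dist, groups, config.n_perm, seed),
    }

    rep_a = analyze_lake(nm, catalog, ga, config, seed=seed)
    rep_b = analyze_lake(nm, catalog, gb, config, seed=seed + 10_000)
    sections = {
        "alpha_diversity": {
            "per_sample": alpha.per_sample.to_dict(orient="index"),
            "tests": alpha.tests.to_dict(orient="index"),
        },
        "gene_partition": {
            "shared": len(partition.shared),
            f"unique_{ga}": len(partition.unique_a),
            f"unique_{gb}": len(partition.unique_b),
            "shared_pct": partition.shared_pct,
        },
        "community_tests": {
            name: {"statistic": t.statistic, "p": t.p_value, "method": t.method,
                   **t.extras}
            for name, t in tests.items()
        },
    }
    report = compare_lakes(rep_a, rep_b, sections=sections)
    return TwoLakeResult(
        normalized=nm,
        preprocess_log=log,
        alpha=alpha,
        partition=partition,
        category_table=cat_table,
        dissimilarity=dist,
        tests=tests,
        report=report,
    )
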