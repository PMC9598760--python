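"""Alpha diversity, shared/unique gene partitioning, and category comparisons.

Indices are computed per sample from relative signal intensities ``p_i``:

* richness ``S`` — number of detected genes;
* Shannon ``H = -sum p_i ln p_i`` (nats);
* inverse Simpson ``D = 1 / sum p_i^2`` (effective gene number);
* Pielou's evenness ``J = H / ln S``;
* Simpson's evenness ``E = D / S``.

Group comparisons use Welch's (unequal-variance) two-sided t test throughout.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyPartitionError, InvalidDesignError
from .matrix import NormalizedMatrix

INDEX_NAMES = ("richness", "shannon", "inv_simpson", "pielou", "simpson_evenness")


@dataclass
class AlphaDiversityResult:
    per_sample: pd.DataFrame       # sample x index
    group_stats: pd.DataFrame      # (group, mean/sd) x index
    tests: pd.DataFrame            # index x (t, p)


@dataclass
class GenePartition:
    """Set algebra of two groups' detected gene sets."""

    shared: set
    unique_a: set
    unique_b: set

    @property
    def union_size(self) -> int:
        return len(self.shared) + len(self.unique_a) + len(self.unique_b)

    @property
    def shared_pct(self) -> float:
        return 100.0 * len(self.shared) / self.union_size


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0.0):
        # both groups constant: identical -> t = 0, p = 1; else infinite t
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return math_inf_sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def math_inf_sign(x: float) -> float:
    return float(np.inf if x > 0 else -np.inf)


def alpha_diversity(nm: NormalizedMatrix) -> AlphaDiversityResult:
    """Per-sample diversity/evenness indices plus Welch t tests between the
    two groups.  A sample with a single detected gene has undefined Pielou
    evenness; it is reported as NaN with a warning."""
    rows = []
    for sample in nm.samples:
        p = nm.rel[sample].values
        p = p[(nm.detected[sample].values) & (p > 0)]
        s = int(nm.detected[sample].sum())
        if s < 1:
            raise InvalidDesignError(f"sample {sample!r} has no detected genes")
        h = float(-(p * np.log(p)).sum())
        inv_d = float(1.0 / (p ** 2).sum())
        if s > 1:
            pielou = h / np.log(s)
        else:
            warnings.warn(f"sample {sample!r}: richness 1, Pielou evenness undefined")
            pielou = np.nan
        rows.append((s, h, inv_d, pielou, inv_d / s))
    per_sample = pd.DataFrame(rows, index=pd.Index(nm.samples, name="sample"),
                              columns=list(INDEX_NAMES))

    groups = nm.group_names()
    if len(groups) != 2:
        raise InvalidDesignError("alpha diversity comparison needs exactly 2 groups")
    ga, gb = groups
    stats_rows = {}
    for g in groups:
        sub = per_sample.loc[nm.sample_ids(g)]
        stats_rows[(g, "mean")] = sub.mean()
        stats_rows[(g, "sd")] = sub.std(ddof=1)
    group_stats = pd.DataFrame(stats_rows).T

    tests = {}
    for idx in INDEX_NAMES:
        a = per_sample.loc[nm.sample_ids(ga), idx].dropna().values
        b = per_sample.loc[nm.sample_ids(gb), idx].dropna().values
        tests[idx] = _welch(a, b)
    tests_df = pd.DataFrame(tests, index=["t", "p"]).T
    return AlphaDiversityResult(per_sample, group_stats, tests_df)


def group_detected_sets(nm: NormalizedMatrix) -> dict[str, set]:
    """Genes detected in at least one sample of each group."""
    out: dict[str, set] = {}
    for g in nm.group_names():
        mask = nm.detected[nm.sample_ids(g)].any(axis=1)
        out[g] = set(nm.detected.index[mask])
    return out


def shared_unique_partition(detected_a: set, detected_b: set) -> GenePartition:
    """Partition two detected-gene sets into shared and unique parts."""
    a, b = set(detected_a), set(detected_b)
    if not a and not b:
        raise EmptyPartitionError("both gene sets are empty")
    return GenePartition(shared=a & b, unique_a=a - b, unique_b=b - a)


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def category_intensity_compare(
    nm: NormalizedMatrix,
    catalog: pd.DataFrame,
    by: str = "category",
    levels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-category (or per-gene-family) summed relative intensity comparison.

    Returns one row per level with group means, the between-group delta in
    percentage points, the Welch t statistic, the two-sided p value, and
    significance stars (* p<0.05, ** p<0.01).
    """
    if by not in ("category", "gene_family"):
        raise ValueError("by must be 'category' or 'gene_family'")
    missing = nm.rel.index.difference(catalog.index)
    if len(missing):
        raise KeyError(f"{len(missing)} probes missing from the catalog")
    ann = catalog.loc[nm.rel.index, by]
    available = set(ann.unique())
    if levels is not None:
        unknown = [lv for lv in levels if lv not in available]
        if unknown:
            raise KeyError(f"unknown {by} level(s): {unknown}")
    else:
        levels = sorted(available)

    per_sample = nm.rel.groupby(ann).sum()  # level x sample
    groups = nm.group_names()
    if len(groups) != 2:
        raise InvalidDesignError("category comparison needs exactly 2 groups")
    ga, gb = groups
    cols_a, cols_b = nm.sample_ids(ga), nm.sample_ids(gb)
    rows = []
    for lv in levels:
        if lv not in per_sample.index:
            vals = pd.Series(0.0, index=nm.samples)
        else:
            vals = per_sample.loc[lv]
        a, b = vals[cols_a].values, vals[cols_b].values
        t, p = _welch(a, b)
        delta_pp = (a.mean() - b.mean()) * 100.0
        rows.append((lv, a.mean(), b.mean(), delta_pp, t, p, _stars(p)))
    return pd.DataFrame(
        rows,
        columns=[by, f"mean_{ga}", f"mean_{gb}", "delta_pp", "t", "p", "stars"],
    ).set_index(by)
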