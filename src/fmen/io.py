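"""Plain-text readers and writers.

The signal TSV dialect: one row per probe with annotation columns
``probe_id`` (index), ``gene_family``, ``category``, ``lineage``, followed by
``<sample>_signal`` and ``<sample>_snr`` columns.  Sample IDs are
``<group><index>`` (e.g. ``HL1``); the group label is the ID with trailing
digits stripped.
"""
from __future__ import annotations

import json
import re

import networkx as nx
import pandas as pd

from .matrix import SignalMatrix
from .synthetic import GroundTruth

ANNOTATION_COLS = ("gene_family", "category", "lineage")


def _group_of(sample: str) -> str:
    return re.sub(r"\d+$", "", sample)


def write_signal_tsv(sm: SignalMatrix, catalog: pd.DataFrame, path: str) -> None:
    out = catalog.loc[sm.signal.index, list(ANNOTATION_COLS)].copy()
    for s in sm.samples:
        out[f"{s}_signal"] = sm.signal[s]
        out[f"{s}_snr"] = sm.snr[s]
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_signal_tsv(path: str) -> tuple[SignalMatrix, pd.DataFrame]:
    raw = pd.read_csv(path, sep="\t", index_col="probe_id")
    catalog = raw[list(ANNOTATION_COLS)].copy()
    samples = [c[:-7] for c in raw.columns if c.endswith("_signal")]
    signal = pd.DataFrame({s: raw[f"{s}_signal"] for s in samples})
    snr = pd.DataFrame({s: raw[f"{s}_snr"] for s in samples})
    groups = pd.Series({s: _group_of(s) for s in samples}, name="group")
    return SignalMatrix(signal, snr, groups), catalog


def write_ground_truth_json(truth: GroundTruth, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)


def read_ground_truth_json(path: str) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth(**json.load(fh))


def write_distance_tsv(dist: pd.DataFrame, path: str) -> None:
    dist.to_csv(path, sep="\t", index_label="sample")


def write_edgelist_tsv(g: nx.Graph, path: str) -> None:
    """Signed edge list (gene_a, gene_b, r, sign) for external viewers."""
    rows = [
        (u, v, d.get("r", float("nan")), d.get("sign", 1))
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "sign"]).to_csv(
        path, sep="\t", index=False)


def write_graphml(g: nx.Graph, path: str) -> None:
    nx.write_graphml(g, path)
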