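"""In-memory containers for probe-level signal data.

A :class:`SignalMatrix` holds raw (or partially preprocessed) probe x sample
fluorescence intensities together with per-entry signal-to-noise ratios and a
boolean detection mask.  A :class:`NormalizedMatrix` is the end product of the
preprocessing chain: per-sample relative signal intensities that sum to one
over the detected probes of each sample.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _check_aligned(a: pd.DataFrame, b: pd.DataFrame, what: str) -> None:
    if not a.index.equals(b.index) or not a.columns.equals(b.columns):
        raise ValueError(f"{what} must share index and columns with the signal matrix")


@dataclass
class SignalMatrix:
    """Probe x sample intensities with signal-to-noise ratios.

    Parameters
    ----------
    signal:
        Nonnegative fluorescence intensities, probes as rows, samples as
        columns (arbitrary units).
    snr:
        Signal-to-noise ratios aligned with ``signal``.
    groups:
        Mapping from sample ID to group label (e.g. ``"HL"`` / ``"RAL"``).
    detected:
        Boolean mask of entries still considered detected.  Defaults to all
        True; the preprocessing steps narrow it.
    """

    signal: pd.DataFrame
    snr: pd.DataFrame
    groups: pd.Series
    detected: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _check_aligned(self.snr, self.signal, "snr")
        if self.detected is None:
            self.detected = pd.DataFrame(
                True, index=self.signal.index, columns=self.signal.columns
            )
        _check_aligned(self.detected, self.signal, "detected")
        if (self.signal.values < 0).any():
            raise ValueError("negative signal intensities")
        if (self.snr.values < 0).any():
            raise ValueError("negative signal-to-noise ratios")
        missing = [s for s in self.signal.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.groups = self.groups.loc[self.signal.columns]

    @property
    def samples(self) -> list[str]:
        return list(self.signal.columns)

    @property
    def probes(self) -> list[str]:
        return list(self.signal.index)

    def copy(self) -> "SignalMatrix":
        return SignalMatrix(
            self.signal.copy(), self.snr.copy(), self.groups.copy(), self.detected.copy()
        )


@dataclass
class NormalizedMatrix:
    """Per-sample relative signal intensities (the metabolic-potential proxy).

    ``rel`` entries of undetected probes are exactly zero; detected entries of
    each sample sum to one.
    """

    rel: pd.DataFrame
    detected: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        _check_aligned(self.detected, self.rel, "detected")
        self.groups = self.groups.loc[self.rel.columns]

    @property
    def samples(self) -> list[str]:
        return list(self.rel.columns)

    def sample_ids(self, group: str) -> list[str]:
        return [s for s in self.rel.columns if self.groups[s] == group]

    def richness(self) -> pd.Series:
        """Detected probe count per sample."""
        return self.detected.sum(axis=0)

    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen


def group_columns(groups: pd.Series, group: str) -> np.ndarray:
    """Boolean mask over ``groups.index`` selecting one group's samples."""
    return (groups == group).values
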