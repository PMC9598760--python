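"""Preprocessing chain from raw probe signals to relative signal intensities.

The chain is order-fixed:

(a) discard entries with signal-to-noise ratio below a quality cutoff
    (default 2; strict ``snr < cutoff`` is discarded, ``snr >= cutoff``
    retained);
(b) take logarithms of intensities greater than 1 and divide by the sample's
    mean logged intensity (intensities at or below 1 are treated as
    undetected — their logarithm would be nonpositive);
(c) divide by the per-sample total so each sample's detected probes sum to 1
    (the relative signal intensity, a proxy for metabolic potential).

The mean in step (b) is taken over the same sample's detected logged
intensities, which makes the log base immaterial: a change of base rescales
numerator and denominator alike.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError
from .matrix import NormalizedMatrix, SignalMatrix


def filter_by_snr(matrix: SignalMatrix, snr_min: float = 2.0) -> SignalMatrix:
    """Mark entries with ``snr < snr_min`` undetected and zero their signal."""
    if snr_min <= 0:
        raise ValueError("snr_min must be positive")
    keep = matrix.detected & (matrix.snr >= snr_min)
    signal = matrix.signal.where(keep, 0.0)
    return SignalMatrix(signal, matrix.snr.copy(), matrix.groups.copy(), keep)


def log_mean_scale(matrix: SignalMatrix, base: float = math.e) -> SignalMatrix:
    """Replace each detected intensity ``x > 1`` by ``log x / mean(log x)``.

    The mean runs over the sample's own detected intensities above 1.
    Detected intensities at or below 1 become undetected.  ``base`` only
    exists to demonstrate base-invariance; the output is identical for any
    base > 1.
    """
    if base <= 1:
        raise ValueError("log base must exceed 1")
    keep = matrix.detected & (matrix.signal > 1.0)
    out = np.zeros(matrix.signal.shape)
    vals = matrix.signal.values
    for j, sample in enumerate(matrix.signal.columns):
        mask = keep.values[:, j]
        if not mask.any():
            raise DegenerateSampleError(sample, "log_mean_scale")
        logs = np.log(vals[mask, j]) / math.log(base)
        out[mask, j] = logs / logs.mean()
    signal = pd.DataFrame(out, index=matrix.signal.index, columns=matrix.signal.columns)
    return SignalMatrix(signal, matrix.snr.copy(), matrix.groups.copy(), keep)


def relative_intensity(matrix: SignalMatrix) -> NormalizedMatrix:
    """Divide each detected entry by its sample total (sums to 1 per sample)."""
    totals = matrix.signal.where(matrix.detected, 0.0).sum(axis=0)
    for sample, tot in totals.items():
        if tot <= 0:
            raise DegenerateSampleError(str(sample), "relative_intensity")
    rel = matrix.signal.where(matrix.detected, 0.0).div(totals, axis=1)
    return NormalizedMatrix(rel, matrix.detected.copy(), matrix.groups.copy())


def preprocess(
    matrix: SignalMatrix, snr_min: float = 2.0
) -> tuple[NormalizedMatrix, pd.DataFrame]:
    """Run the full (a) -> (b) -> (c) chain.

    Returns the normalized matrix and a per-sample log of how many probes
    each step discarded.
    """
    n0 = matrix.detected.sum(axis=0)
    filtered = filter_by_snr(matrix, snr_min)
    n1 = filtered.detected.sum(axis=0)
    scaled = log_mean_scale(filtered)
    n2 = scaled.detected.sum(axis=0)
    normalized = relative_intensity(scaled)
    log = pd.DataFrame(
        {
            "input_detected": n0,
            "discarded_low_snr": n0 - n1,
            "discarded_not_above_one": n1 - n2,
            "detected": n2,
        }
    )
    log.index.name = "sample"
    return normalized, log
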