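"""Exception types shared across the pipeline stages."""


class FMENError(Exception):
    """Base class for all package-specific errors."""


class DegenerateSampleError(FMENError):
    """A sample has no usable probes at some preprocessing stage."""

    def __init__(self, sample: str, stage: str):
        self.sample = sample
        self.stage = stage
        super().__init__(f"sample {sample!r} is degenerate at stage {stage!r}: "
                         "no detected probes remain")


class EmptyPartitionError(FMENError):
    """Both gene sets of a shared/unique partition are empty."""


class UndefinedDistanceError(FMENError):
    """A dissimilarity is undefined (e.g. two all-zero samples)."""


class InvalidDesignError(FMENError):
    """The grouping design cannot support the requested test."""


class InsufficientSpectrumError(FMENError):
    """Too few distinct eigenvalues remain for spectral unfolding."""

    def __init__(self, n_found: int, n_required: int):
        self.n_found = n_found
        self.n_required = n_required
        super().__init__(f"only {n_found} distinct eigenvalues available; "
                         f"{n_required} required for unfolding")


class NoTransitionError(FMENError):
    """No similarity threshold on the grid reaches Poisson statistics."""


class EmptyNetworkError(FMENError):
    """Thresholding left no edges."""


class ConfigMismatchError(FMENError):
    """Two lake reports were produced under different analysis configs."""
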