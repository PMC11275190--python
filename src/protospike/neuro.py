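"""Neuromorphic abstraction of chronoamperometric current traces.

Current recordings are mapped onto a toy spiking-network representation:
samples above a threshold (default 1e-4 uA) become '1' bits of a binary
temporal code; a random subset of the active samples — sized inversely to
the neuron count — seeds the artificial neurons; and an n x n synaptic
weight matrix is initialised uniformly on [-1, 1). Only initialisation is
modelled: the iterative learning rule alluded to in the source study is
never specified and no network dynamics are claimed. Cumulative charge is
recovered from I(t) = dQ/dt by trapezoidal integration, and per-condition
current distributions are summarised with Tukey boxplot statistics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import UnitMismatchError
from .io import Trace

__all__ = ["BinaryTemporalCode", "SynapticWeightMatrix", "binarize_current",
           "subsample_active", "init_weights", "cumulative_charge",
           "current_distribution_stats"]

#: default activity threshold (uA) for binary temporal coding
DEFAULT_THRESHOLD_UA = 1e-4
#: default simulated-network size
DEFAULT_N_NEURONS = 30


@dataclass
class BinaryTemporalCode:
    """Thresholded 0/1 activity sequence derived from a current trace."""

    bits: np.ndarray
    threshold: float
    source: str = ""

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be over {0, 1}")

    @property
    def n_active(self) -> int:
        return int(self.bits.sum())


@dataclass
class SynapticWeightMatrix:
    """n x n random synaptic weights, entries in [-1, 1)."""

    n: int
    W: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (self.n, self.n):
            raise ValueError("W must be n x n")
        if np.any(self.W < -1) or np.any(self.W >= 1):
            raise ValueError("entries must lie in [-1, 1)")


def _require_current(trace: Trace) -> None:
    if trace.unit != "uA":
        raise UnitMismatchError(
            f"expected a current trace in uA, got unit {trace.unit!r}")


def binarize_current(trace: Trace,
                     threshold: float = DEFAULT_THRESHOLD_UA
                     ) -> BinaryTemporalCode:
    """Bit i = 1 iff value_i > threshold (strict); one bit per sample."""
    _require_current(trace)
    bits = (trace.values > threshold).astype(np.uint8)
    return BinaryTemporalCode(bits=bits, threshold=threshold,
                              source=trace.label)


def subsample_active(code: BinaryTemporalCode,
                     n_neurons: int = DEFAULT_N_NEURONS,
                     seed: int | None = None) -> np.ndarray:
    """Random subset of active-bit indices, sized floor(n_active/n_neurons).

    The subset size is inversely related to the neuron count; it is at least
    1 whenever any bit is active, and empty (not an error) otherwise.
    Returned indices are sorted; the draw is uniform without replacement.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    active = np.flatnonzero(code.bits)
    if active.size == 0:
        return np.empty(0, dtype=int)
    size = max(active.size // n_neurons, 1)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(active, size=size, replace=False))


def init_weights(n: int = DEFAULT_N_NEURONS,
                 seed: int | None = None) -> SynapticWeightMatrix:
    """Initialise an n x n weight matrix, i.i.d. uniform on [-1, 1).

    Entries are 2u - 1 with u uniform on [0, 1), the standard symmetric
    random initialisation; variance 1/3.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    W = 2.0 * rng.random((n, n)) - 1.0
    return SynapticWeightMatrix(n=n, W=W, seed=seed)


def cumulative_charge(trace: Trace) -> np.ndarray:
    """Cumulative charge Q(t_k) in uC by trapezoidal integration of I(t).

    Q(t_0) = 0; finite differences of the result recover the current at
    interior points up to discretisation error.
    """
    _require_current(trace)
    return cumulative_trapezoid(trace.values, dx=trace.dt, initial=0.0)


def current_distribution_stats(trace: Trace) -> dict:
    """Tukey boxplot statistics of a current trace.

    Quartiles use linear interpolation (type 7); whiskers extend to the most
    extreme samples within 1.5*IQR of the quartiles; samples beyond the
    fences are listed as outliers.
    """
    _require_current(trace)
    v = trace.values
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "mean": float(np.mean(v)),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": v[(v < lo_fence) | (v > hi_fence)],
    }
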