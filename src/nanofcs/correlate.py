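"""Autocorrelation estimators for photon-count traces.

Two estimators are provided: a multi-tau correlator on a quasi-logarithmic
lag grid (the workhorse, spanning microseconds to seconds at fixed cost)
and a brute-force linear-lag estimator used as its arithmetic oracle.

Both use symmetric normalization: at each lag the left and right means are
computed over the valid overlap only, which removes the finite-trace bias
of the naive global-mean estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .trace import PhotonTrace

__all__ = [
    "CorrelationCurve",
    "multitau_autocorrelate",
    "direct_autocorrelate",
    "average_curves",
]


@dataclass
class CorrelationCurve:
    """Normalized autocorrelation G(tau) on a set of positive lags.

    lags are in seconds and strictly increasing; ``sd``, when present, is a
    per-lag standard deviation of G; ``mean_rate`` is the mean count rate of
    the source trace in kHz.
    """

    lags: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None
    mean_rate: float | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.ndim != 1 or self.values.shape != self.lags.shape:
            raise ValueError("lags and values must be 1-D and equally long")
        if len(self.lags) and (self.lags[0] <= 0 or np.any(np.diff(self.lags) <= 0)):
            raise ValueError("lags must be positive and strictly increasing")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.values.shape:
                raise ValueError("sd must have the same length as values")

    def __len__(self) -> int:
        return len(self.lags)


def _symmetric_g(x: np.ndarray, lags_bins: np.ndarray) -> np.ndarray:
    """G at integer bin lags with per-lag (symmetric) normalization.

    G(k) = <x_i x_{i+k}> / (<x>_left <x>_right) - 1, means over the overlap.
    """
    n = len(x)
    out = np.empty(len(lags_bins))
    for j, k in enumerate(lags_bins):
        a = x[: n - k]
        b = x[k:]
        ma = a.mean()
        mb = b.mean()
        if ma == 0.0 or mb == 0.0:
            raise ValueError(
                "zero-mean trace segment: normalization undefined at lag "
                f"{k} bins"
            )
        out[j] = float(a @ b) / (len(a) * ma * mb) - 1.0
    return out


def direct_autocorrelate(trace: PhotonTrace, max_lag_bins: int) -> CorrelationCurve:
    """Brute-force autocorrelation at every integer lag 1..max_lag_bins.

    O(N * L); used as the arithmetic oracle for the multi-tau estimator and
    for short traces where a dense linear lag grid is wanted.
    """
    n = len(trace.counts)
    if max_lag_bins < 1:
        raise ValueError("max_lag_bins must be >= 1")
    if max_lag_bins >= n:
        raise ValueError(
            f"max_lag_bins ({max_lag_bins}) must be smaller than the trace "
            f"length ({n} bins)"
        )
    x = trace.counts.astype(float)
    if x.mean() == 0.0:
        raise ValueError("zero-mean trace: normalization undefined")
    lags_bins = np.arange(1, max_lag_bins + 1)
    g = _symmetric_g(x, lags_bins)
    return CorrelationCurve(
        lags=lags_bins * trace.bin_width,
        values=g,
        mean_rate=trace.mean_rate,
        provenance={"estimator": "direct", "max_lag_bins": max_lag_bins},
    )


def multitau_autocorrelate(trace: PhotonTrace, m: int = 16) -> CorrelationCurve:
    """Multi-tau autocorrelation on a quasi-logarithmic lag grid.

    Level 0 evaluates ``m`` linear lags at the base bin width; each further
    level doubles the bin width (pairwise rebinning of counts) and adds
    ``m/2`` lags (indices m/2+1..m of the rebinned trace). Every level is
    the symmetric-normalization estimator applied literally to the rebinned
    trace, so level-0 values agree bit-for-bit with
    :func:`direct_autocorrelate` and coarser levels with the direct
    estimator on an externally rebinned trace.

    Lag 0 (shot-noise dominated) is never part of the output.
    """
    if m < 2 or m % 2:
        raise ValueError(f"m must be an even integer >= 2, got {m}")
    n = len(trace.counts)
    if n < 2 * m:
        raise ValueError(f"trace has {n} bins; need at least 2*m = {2 * m}")
    x = trace.counts.astype(float)
    if x.mean() == 0.0:
        raise ValueError("zero-mean trace: normalization undefined")

    lags: list[np.ndarray] = []
    values: list[np.ndarray] = []
    level0 = np.arange(1, m + 1)
    lags.append(level0 * trace.bin_width)
    values.append(_symmetric_g(x, level0))

    higher = np.arange(m // 2 + 1, m + 1)
    width = trace.bin_width
    while True:
        half = len(x) // 2
        x = x[: 2 * half : 2] + x[1 : 2 * half : 2]
        width *= 2.0
        if len(x) < 2 * m:
            break
        lags.append(higher * width)
        values.append(_symmetric_g(x, higher))

    return CorrelationCurve(
        lags=np.concatenate(lags),
        values=np.concatenate(values),
        mean_rate=trace.mean_rate,
        provenance={"estimator": "multitau", "m": m},
    )


def average_curves(curves: Sequence[CorrelationCurve]) -> CorrelationCurve:
    """Pointwise mean of replicate curves on an identical lag grid.

    The per-lag sample standard deviation (ddof=1) becomes ``sd`` and the
    mean rate is the mean of the member rates. This mirrors the convention
    of averaging several independent measurements of the same sample.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to average")
    lags = curves[0].lags
    for c in curves[1:]:
        if not np.array_equal(c.lags, lags):
            raise ValueError("curves are on different lag grids")
    stack = np.vstack([c.values for c in curves])
    rates = [c.mean_rate for c in curves if c.mean_rate is not None]
    return CorrelationCurve(
        lags=lags.copy(),
        values=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=1),
        mean_rate=float(np.mean(rates)) if rates else None,
        provenance={"estimator": "average", "n_curves": len(curves)},
    )
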