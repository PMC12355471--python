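"""Binned photon-count time traces, the raw observable of confocal FCS."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["PhotonTrace"]


@dataclass
class PhotonTrace:
    """A uniformly binned detector record.

    Parameters
    ----------
    bin_width:
        Width of one counting bin, in seconds.
    counts:
        Non-negative integer photon counts, one entry per bin.
    metadata:
        Free-form provenance record (seed, simulation ground truth, source
        file, ...). Never interpreted by the numerics.
    """

    bin_width: float
    counts: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D sequence")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts).astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if len(self.counts) and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def duration(self) -> float:
        """Total trace length in seconds."""
        return len(self.counts) * self.bin_width

    @property
    def mean_rate(self) -> float:
        """Mean detected count rate in kHz."""
        return float(self.counts.mean()) / self.bin_width * 1e-3

    @property
    def times(self) -> np.ndarray:
        """Left edge of every bin, in seconds."""
        return np.arange(len(self.counts)) * self.bin_width
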