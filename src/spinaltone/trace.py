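"""Uniformly sampled single-channel time series.

A :class:`Trace` carries one channel of a patch-clamp or imaging recording:
membrane current (pA) in voltage clamp, membrane voltage (mV) in current
clamp, or a fluorescence/ΔF/F signal.  Metadata holds acquisition context
such as the holding potential and drug-application epochs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Recognized physical units for trace samples.
VALID_UNITS = ("pA", "mV", "au", "percent")


class ParameterError(ValueError):
    """A generator or analysis parameter violates its contract."""


@dataclass
class Trace:
    """One channel of uniformly sampled data.

    Parameters
    ----------
    values
        Sample array; must be finite.
    sample_rate
        Sampling rate in Hz (20 000 for electrophysiology, 2 for imaging).
    units
        One of ``pA``, ``mV``, ``au`` (raw fluorescence) or ``percent``
        (ΔF/F).
    t0
        Time of the first sample, in seconds.
    metadata
        Free-form annotations.  Conventional keys: ``hold_voltage_mv``,
        ``drug_epochs`` (list of ``{name, start_s, end_s}``), ``steps``
        (current-clamp step windows), ``preparation``.
    """

    values: np.ndarray
    sample_rate: float
    units: str
    t0: float = 0.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("trace values must be one-dimensional")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ParameterError("trace contains non-finite samples")
        if not self.sample_rate > 0:
            raise ParameterError("sample_rate must be positive")
        if self.units not in VALID_UNITS:
            raise ParameterError(
                f"unknown units {self.units!r}; expected one of {VALID_UNITS}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    def index_of(self, t_s: float) -> int:
        """Sample index of time ``t_s`` (clipped to the valid range)."""
        i = int(round((t_s - self.t0) * self.sample_rate))
        return min(max(i, 0), self.n_samples)

    def slice_values(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples within ``[start_s, end_s)``."""
        if end_s <= start_s:
            raise ParameterError("epoch must have positive length")
        return self.values[self.index_of(start_s): self.index_of(end_s)]

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Trace":
        """A copy sharing acquisition metadata but carrying new samples."""
        return Trace(
            values=np.asarray(values, dtype=float),
            sample_rate=self.sample_rate,
            units=self.units if units is None else units,
            t0=self.t0,
            metadata=dict(self.metadata),
        )
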