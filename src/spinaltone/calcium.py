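"""ΔF/F computation, threshold calibration, activity calling and cohorts.

The spiking threshold for GCaMP6f signals is calibrated from paired
current-injection data: the ΔF/F of the lowest current step whose mean
evoked spike count reaches the criterion (one spike) defines the cut-off
below which calcium signals are treated as noise.  Per-cell activity is
called from suprathreshold peaks, with repeated bursting defined as at
least three peaks within any five-minute span.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .trace import ParameterError, Trace

#: ΔF/F threshold (%) below which calcium signals are treated as noise.
DFF_THRESHOLD_PCT = 3.5
#: Sliding window (s) and minimum peak count defining repeated bursting.
BURST_WINDOW_S = 300.0
BURST_MIN_PEAKS = 3


def compute_dff(trace: Trace, baseline_window: tuple[float, float]) -> Trace:
    """ΔF/F in percent: 100·(F − F0)/F0 with F0 the baseline-window mean."""
    seg = trace.slice_values(*baseline_window)
    if seg.size == 0:
        raise ParameterError("baseline window contains no samples")
    f0 = float(np.mean(seg))
    if f0 <= 0:
        raise ParameterError("baseline fluorescence must be positive")
    out = trace.with_values(100.0 * (trace.values - f0) / f0, units="percent")
    out.metadata["f0"] = f0
    return out


def detect_calcium_peaks(
    dff: Trace,
    threshold_pct: float = DFF_THRESHOLD_PCT,
    min_separation_s: float = 2.0,
) -> np.ndarray:
    """Times (s) of local ΔF/F maxima strictly above threshold.

    Signals at or below the threshold are noise by the calibration rule,
    so the comparison is strict.  Peaks closer than ``min_separation_s``
    collapse to the larger one.
    """
    if not threshold_pct > 0:
        raise ParameterError("threshold must be positive")
    if dff.units != "percent":
        raise ParameterError("detect_calcium_peaks expects a ΔF/F trace")
    distance = max(int(round(min_separation_s * dff.sample_rate)), 1)
    peaks, props = signal.find_peaks(dff.values, height=threshold_pct, distance=distance)
    strict = props["peak_heights"] > threshold_pct
    return dff.t0 + peaks[strict] / dff.sample_rate


@dataclass
class CalibrationPoint:
    """One current step of the simultaneous patch/imaging calibration."""

    current_pa: float
    mean_spikes: float
    mean_dff_pct: float
    sem_spikes: float = float("nan")
    sem_dff_pct: float = float("nan")

    def __post_init__(self) -> None:
        if not self.current_pa > 0:
            raise ParameterError("calibration current must be positive")
        if self.mean_spikes < 0 or self.mean_dff_pct < 0:
            raise ParameterError("calibration means must be non-negative")


def calibrate_threshold(
    points: list[CalibrationPoint], spike_criterion: float = 1.0
) -> float:
    """ΔF/F (%) of the lowest step whose mean spike count meets criterion."""
    if len(points) < 2:
        raise ParameterError("need at least two calibration points")
    for pt in sorted(points, key=lambda p: p.current_pa):
        if pt.mean_spikes >= spike_criterion:
            return pt.mean_dff_pct
    raise ParameterError("no calibration point reaches the spike criterion")


@dataclass
class CalciumCellRecord:
    """Per-ROI ΔF/F trace with its activity call."""

    dff: Trace
    peaks_s: np.ndarray = field(default_factory=lambda: np.array([]))
    label: str = "inactive"
    reaction_time_min: float | None = None
    spontaneously_active: bool = False
    condition: str = "control"
    preparation: str = "intact"

    @property
    def max_dff_pct(self) -> float:
        return float(np.max(self.dff.values)) if self.dff.n_samples else float("nan")


def classify_cell_activity(
    record: CalciumCellRecord,
    threshold_pct: float = DFF_THRESHOLD_PCT,
    window_s: float = BURST_WINDOW_S,
    burst_min_peaks: int = BURST_MIN_PEAKS,
    min_separation_s: float = 2.0,
) -> CalciumCellRecord:
    """Call a cell inactive / active / repeated_bursting.

    No suprathreshold peak → inactive; at least one → active; at least
    ``burst_min_peaks`` peaks inside any sliding ``window_s`` span →
    repeated_bursting (implying active).
    """
    peaks = detect_calcium_peaks(record.dff, threshold_pct, min_separation_s)
    record.peaks_s = peaks
    if peaks.size == 0:
        record.label = "inactive"
    else:
        record.label = "active"
        for i in range(peaks.size):
            in_window = np.count_nonzero(
                (peaks >= peaks[i]) & (peaks <= peaks[i] + window_s)
            )
            if in_window >= burst_min_peaks:
                record.label = "repeated_bursting"
                break
    return record


def measure_reaction_time(
    record: CalciumCellRecord, drug_arrival_s: float
) -> float | None:
    """Minutes from drug arrival to the first suprathreshold peak.

    A peak before drug arrival flags the cell as spontaneously active and
    excludes it from the responder set (returns ``None``), as does the
    absence of any peak.
    """
    if record.condition == "control":
        raise ParameterError("reaction time requires a drug-application recording")
    peaks = np.asarray(record.peaks_s, dtype=float)
    if peaks.size == 0:
        record.reaction_time_min = None
        return None
    if peaks.min() < drug_arrival_s:
        record.spontaneously_active = True
        record.reaction_time_min = None
        return None
    rt = (peaks.min() - drug_arrival_s) / 60.0
    record.reaction_time_min = rt
    return rt


@dataclass
class CohortSummary:
    """Activity summary of one cohort of ROIs."""

    n_total: int
    n_active: int
    percent_active: float
    mean_dff_pct: float
    sem_dff_pct: float
    mean_reaction_time_min: float
    sem_reaction_time_min: float
    condition: str = ""

    def as_dict(self) -> dict[str, float | int | str]:
        return self.__dict__.copy()


def summarize_cohort(
    records: list[CalciumCellRecord], condition: str | None = None
) -> CohortSummary:
    """Counts, percentage active, ΔF/F and reaction-time summary.

    ``percent_active`` is 100·n_active/n_total over the (optionally
    condition-filtered) records; ΔF/F statistics are over the active
    cells' per-cell maxima; the reaction-time mean covers responders with
    a measured latency.
    """
    if condition is not None:
        records = [r for r in records if r.condition == condition]
    if not records:
        raise ParameterError("empty cohort")
    n_total = len(records)
    active = [r for r in records if r.label != "inactive"]
    n_active = len(active)

    maxima = np.array([r.max_dff_pct for r in active], dtype=float)
    rts = np.array(
        [r.reaction_time_min for r in records if r.reaction_time_min is not None],
        dtype=float,
    )

    def _sem(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")

    return CohortSummary(
        n_total=n_total,
        n_active=n_active,
        percent_active=100.0 * n_active / n_total,
        mean_dff_pct=float(maxima.mean()) if maxima.size else float("nan"),
        sem_dff_pct=_sem(maxima),
        mean_reaction_time_min=float(rts.mean()) if rts.size else float("nan"),
        sem_reaction_time_min=_sem(rts),
        condition=condition or "",
    )
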