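"""Excitability measures from current-clamp protocols.

Rheobase (linear 1 pA-increment search with 500 ms pulses, mirroring the
recording protocol), steady-state input resistance, resting membrane
potential, and two-group statistical comparison (two-tailed Student's
t-test or Mann-Whitney U).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synth.neuron import gen_cc_response
from .synth.params import CellModel
from .trace import ParameterError, Trace

#: Upward-crossing criterion for spike detection in current clamp, mV.
SPIKE_CRITERION_MV = -20.0


def detect_spikes(trace: Trace, criterion_mv: float = SPIKE_CRITERION_MV) -> np.ndarray:
    """Spike times (s) as upward crossings of a fixed voltage criterion."""
    if trace.units != "mV":
        raise ParameterError("spike detection expects a voltage trace in mV")
    above = trace.values >= criterion_mv
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if above.size and above[0]:
        crossings = np.concatenate([[0], crossings])
    return trace.t0 + crossings / trace.sample_rate


@dataclass
class ExcitabilityMeasures:
    """Per-cell excitability summary."""

    rheobase_pa: float | None
    input_resistance_mohm: float
    resting_potential_mv: float
    condition: str = "control"


def find_rheobase(
    cell_or_recordings: CellModel | list[tuple[float, Trace]],
    increment_pa: float = 1.0,
    pulse_ms: float = 500.0,
    max_amplitude_pa: float = 150.0,
    sample_rate: float = 20000.0,
    criterion_mv: float = SPIKE_CRITERION_MV,
) -> float | None:
    """Smallest step amplitude eliciting at least one spike.

    Accepts either a :class:`CellModel` (each amplitude is simulated with a
    single 500 ms pulse) or a pre-recorded ascending list of
    ``(amplitude_pA, voltage Trace)`` responses.  Returns ``None`` when no
    amplitude up to the protocol maximum reaches threshold ("not reached").
    """
    if isinstance(cell_or_recordings, CellModel):
        amp = increment_pa
        while amp <= max_amplitude_pa + 1e-9:
            trace, _ = gen_cc_response(
                cell_or_recordings,
                [(amp, pulse_ms, 0.0)],
                sample_rate=sample_rate,
            )
            if detect_spikes(trace, criterion_mv).size:
                return float(amp)
            amp += increment_pa
        return None
    for amp, trace in sorted(cell_or_recordings, key=lambda p: p[0]):
        if detect_spikes(trace, criterion_mv).size:
            return float(amp)
    return None


def measure_input_resistance(
    response: Trace,
    step_pa: float | None = None,
    plateau_fraction: float = 0.2,
    criterion_mv: float = SPIKE_CRITERION_MV,
) -> float:
    """Steady-state ΔV/ΔI (MΩ) from a subthreshold step response.

    The step window is read from the trace metadata (``steps``); the
    steady-state voltage is the mean over the last ``plateau_fraction`` of
    the pulse, referenced to the mean pre-step baseline.  A step that
    evokes spikes is an error.
    """
    steps = response.metadata.get("steps")
    if not steps:
        raise ParameterError("trace metadata carries no step window")
    step = steps[0]
    amp = float(step["amplitude_pa"]) if step_pa is None else float(step_pa)
    if amp == 0:
        raise ParameterError("step amplitude must be non-zero")
    if detect_spikes(response, criterion_mv).size:
        raise ParameterError("step evoked spikes; use a subthreshold step")

    start, end = step["start_s"], step["end_s"]
    plateau = response.slice_values(end - plateau_fraction * (end - start), end)
    base_lo = max(start - 0.05, response.t0)
    baseline = response.slice_values(base_lo, start)
    dv = float(np.mean(plateau) - np.mean(baseline))
    return dv / amp * 1000.0  # mV/pA = GΩ → MΩ


def measure_resting_potential(
    trace: Trace,
    epoch: tuple[float, float],
    criterion_mv: float = SPIKE_CRITERION_MV,
) -> float:
    """Mean membrane potential over a zero-current epoch (mV)."""
    seg = trace.slice_values(*epoch)
    if seg.size == 0:
        raise ParameterError("epoch contains no samples")
    if np.any(seg >= criterion_mv):
        raise ParameterError("epoch contains spikes")
    return float(np.mean(seg))


@dataclass
class GroupComparison:
    """Two-sample comparison of a measure between conditions."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    statistic: float
    p_value: float
    test: str

    def as_dict(self) -> dict[str, float | str]:
        return {
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "sem_a": self.sem_a,
            "sem_b": self.sem_b,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "test": self.test,
        }


def compare_groups(
    a, b, test: str = "t_two_tailed"
) -> GroupComparison:
    """Two-sided comparison of two samples.

    ``test`` is ``t_two_tailed`` (Student's t, equal variances — the test
    used for the electrophysiological measures) or ``mann_whitney`` (used
    for ΔF/F cohort comparisons).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each sample needs at least two values")
    if test == "t_two_tailed":
        res = stats.ttest_ind(a, b, equal_var=True)
        statistic, p = float(res.statistic), float(res.pvalue)
        if np.isnan(statistic) and np.isclose(a.mean(), b.mean()):
            statistic, p = 0.0, 1.0  # two identical constant samples
    elif test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ParameterError(f"unknown test {test!r}")
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(stats.sem(a)),
        sem_b=float(stats.sem(b)),
        statistic=statistic,
        p_value=p,
        test=test,
    )
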