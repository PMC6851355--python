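"""Kinetic classification of IPSCs and tonic-current quantification.

Decay time constants separate fast glycinergic events, slow GABAergic
events and the intermediate band attributed to glycine/GABA co-release.
Tonic currents are read from holding-current shifts: the dominant peak of
an all-points histogram, fitted with a Gaussian, estimates the holding
current of an epoch, and the antagonist-induced shift of that estimate is
the tonic current carried by the blocked receptor class.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .events import EventList
from .trace import ParameterError, Trace


class EstimateQualityWarning(UserWarning):
    """The all-points histogram had no dominant peak; estimate is flagged."""


@dataclass
class ClassBoundaries:
    """Decay-constant band (ms) assigned to co-released (mixed) events.

    The closed interval [mixed_low, mixed_high] is mixed; faster decays are
    glycinergic, slower ones GABAergic.
    """

    mixed_low_ms: float = 16.8
    mixed_high_ms: float = 35.7

    def __post_init__(self) -> None:
        if not 0 < self.mixed_low_ms < self.mixed_high_ms:
            raise ParameterError("require 0 < mixed_low < mixed_high")


KINETIC_CLASSES = ("glycinergic", "mixed", "gabaergic")


def classify_event_class(
    tau_decay_ms: float, boundaries: ClassBoundaries | None = None
) -> str:
    """Kinetic class of a decay constant (closed-interval mixed band)."""
    if boundaries is None:
        boundaries = ClassBoundaries()
    if not tau_decay_ms > 0:
        raise ParameterError("decay constant must be positive")
    if tau_decay_ms < boundaries.mixed_low_ms:
        return "glycinergic"
    if tau_decay_ms <= boundaries.mixed_high_ms:
        return "mixed"
    return "gabaergic"


def classify_events(
    events: EventList, boundaries: ClassBoundaries | None = None
) -> EventList:
    """Label every fitted event in place (unfitted ones stay unclassified)."""
    for e in events:
        if np.isfinite(e.tau_decay_ms) and e.tau_decay_ms > 0:
            e.class_label = classify_event_class(e.tau_decay_ms, boundaries)
        else:
            e.class_label = "unclassified"
    return events


def mixture_proportions(events: EventList) -> dict[str, float]:
    """Per-class fraction of classified events (sums to 1)."""
    counts = {cls: 0 for cls in KINETIC_CLASSES}
    for e in events:
        if e.class_label in counts:
            counts[e.class_label] += 1
    total = sum(counts.values())
    if total == 0:
        raise ParameterError("no classified events")
    return {cls: n / total for cls, n in counts.items()}


def _gaussian(x, a, mu, sd):
    return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def estimate_holding_current(
    trace: Trace,
    epoch: tuple[float, float],
    min_epoch_s: float = 5.0,
    min_peak_mass: float = 0.5,
) -> float:
    """Holding current of an epoch from its all-points histogram.

    A histogram (Freedman–Diaconis bins) of every sample in the epoch is
    built and a Gaussian is fitted to the dominant peak; the fitted mean is
    the holding current.  Synaptic events occupy the histogram's tail and
    barely move the peak.  If fewer than ``min_peak_mass`` of the samples
    fall within ±3 sd of the fitted peak the estimate is flagged with an
    :class:`EstimateQualityWarning`.
    """
    start, end = epoch
    if end - start < min_epoch_s:
        raise ParameterError(f"epoch must span at least {min_epoch_s} s")
    x = trace.slice_values(start, end)
    if x.size == 0:
        raise ParameterError("epoch contains no samples")
    if np.ptp(x) < 1e-12:
        return float(x[0])

    counts, edges = np.histogram(x, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = int(np.argmax(counts))

    # contiguous region around the mode above 20% of the peak count
    thr = 0.2 * counts[mode]
    lo = mode
    while lo > 0 and counts[lo - 1] >= thr:
        lo -= 1
    hi = mode
    while hi < counts.size - 1 and counts[hi + 1] >= thr:
        hi += 1
    # a very sharp peak can span fewer bins than the fit has parameters
    while hi - lo < 4 and (lo > 0 or hi < counts.size - 1):
        lo = max(lo - 1, 0)
        hi = min(hi + 1, counts.size - 1)
    sel = slice(lo, hi + 1)

    sd0 = max((edges[hi + 1] - edges[lo]) / 4.0, (edges[1] - edges[0]))
    try:
        popt, _ = optimize.curve_fit(
            _gaussian,
            centers[sel],
            counts[sel],
            p0=(counts[mode], centers[mode], sd0),
            maxfev=5000,
        )
        mu, sd = float(popt[1]), abs(float(popt[2]))
    except (RuntimeError, ValueError, TypeError):
        mu, sd = float(centers[mode]), sd0

    mass = float(np.mean(np.abs(x - mu) <= 3.0 * sd))
    if mass < min_peak_mass:
        warnings.warn(
            f"holding-current peak holds only {mass:.0%} of samples",
            EstimateQualityWarning,
            stacklevel=2,
        )
    return mu


def measure_tonic_shift(
    trace: Trace,
    epoch_pre: tuple[float, float],
    epoch_post: tuple[float, float],
    **kwargs,
) -> float:
    """Signed holding-current change, post − pre (pA).

    Blocking a tonic chloride conductance at a 0 mV hold removes outward
    current, so the shift is negative; its magnitude is the tonic current
    carried by the blocked receptors.
    """
    if epoch_pre[1] > epoch_post[0] and epoch_post[1] > epoch_pre[0]:
        raise ParameterError("pre and post epochs overlap")
    pre = estimate_holding_current(trace, epoch_pre, **kwargs)
    post = estimate_holding_current(trace, epoch_post, **kwargs)
    return post - pre


def blockade_fraction(freq_pre_hz: float, freq_post_hz: float) -> float:
    """Fractional event-frequency reduction produced by an antagonist."""
    if not freq_pre_hz > 0:
        raise ParameterError("pre-drug frequency must be positive")
    return (freq_pre_hz - freq_post_hz) / freq_pre_hz


@dataclass
class InhibitionProfile:
    """Kinetic and pharmacological decomposition of inhibitory input."""

    fraction_glycinergic: float
    fraction_gabaergic: float
    fraction_mixed: float
    tonic_glycine_pa: float      # magnitude of the strychnine shift
    tonic_gaba_pa: float         # magnitude of the bicuculline shift
    strychnine_block_fraction: float = float("nan")
    bicuculline_block_fraction: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "fraction_glycinergic": self.fraction_glycinergic,
            "fraction_gabaergic": self.fraction_gabaergic,
            "fraction_mixed": self.fraction_mixed,
            "tonic_glycine_pa": self.tonic_glycine_pa,
            "tonic_gaba_pa": self.tonic_gaba_pa,
            "strychnine_block_fraction": self.strychnine_block_fraction,
            "bicuculline_block_fraction": self.bicuculline_block_fraction,
        }
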