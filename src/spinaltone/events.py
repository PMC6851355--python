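"""Postsynaptic-current event detection and decay fitting.

Events are local extrema of the (lightly smoothed, baseline-subtracted)
current trace exceeding a multiple of the robust noise standard deviation.
Each detected event is then fitted with a single exponential from its peak,
yielding the decay time constant used downstream to separate glycinergic,
GABAergic and co-released IPSCs.  Overlapping events are handled by
subtracting the fitted tails of earlier events before fitting later ones.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, signal
from scipy.ndimage import uniform_filter1d

from .trace import ParameterError, Trace

_POLARITIES = ("inward", "outward")


@dataclass
class SynapticEvent:
    """One detected PSC with its fitted kinetics."""

    onset_s: float
    peak_time_s: float
    amplitude_pa: float          # signed (outward positive)
    tau_decay_ms: float = float("nan")
    fit_rss_pa2: float = float("nan")
    class_label: str = "unclassified"

    def __post_init__(self) -> None:
        if self.peak_time_s < self.onset_s:
            raise ParameterError("peak must not precede onset")


@dataclass
class EventList:
    """Ordered events from one trace."""

    events: list[SynapticEvent]
    trace_duration: float
    polarity: str

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset_s)
        for e in self.events:
            if not 0.0 <= e.onset_s <= self.trace_duration:
                raise ParameterError("event outside the trace")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [e.onset_s for e in self.events],
                "peak_time_s": [e.peak_time_s for e in self.events],
                "amplitude_pA": [e.amplitude_pa for e in self.events],
                "tau_ms": [e.tau_decay_ms for e in self.events],
                "class": [e.class_label for e in self.events],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def robust_noise_sd(values: np.ndarray, sample_rate: float) -> float:
    """Noise sd as 1.4826 × MAD of the high-pass residual.

    The residual removes structure slower than ~5 ms, so synaptic decays
    contaminate it only at onsets; the median absolute deviation is then
    insensitive to those sparse excursions.
    """
    win = max(int(round(0.005 * sample_rate)), 3)
    resid = values - uniform_filter1d(values, size=win)
    mad = np.median(np.abs(resid - np.median(resid)))
    # the residual of white noise after subtracting a w-point mean has
    # variance (1 + 1/w) relative to ... effectively ~1; no correction.
    return float(1.4826 * mad)


def _block_baseline(values: np.ndarray, sample_rate: float, block_s: float = 1.0) -> np.ndarray:
    """Slowly varying baseline via per-block medians, interpolated."""
    n = values.size
    block = max(int(round(block_s * sample_rate)), 1)
    n_blocks = max(n // block, 1)
    centers = np.empty(n_blocks)
    meds = np.empty(n_blocks)
    for b in range(n_blocks):
        lo = b * block
        hi = n if b == n_blocks - 1 else (b + 1) * block
        centers[b] = 0.5 * (lo + hi)
        meds[b] = np.median(values[lo:hi])
    if n_blocks == 1:
        return np.full(n, meds[0])
    return np.interp(np.arange(n), centers, meds)


def detect_events(
    trace: Trace,
    polarity: str,
    threshold_k: float = 4.0,
    min_separation_ms: float = 5.0,
    smooth_ms: float = 0.5,
) -> EventList:
    """Detect PSC events as suprathreshold local extrema.

    The trace is smoothed over ``smooth_ms``, a slowly varying baseline is
    subtracted, and peaks of the polarity-rectified signal exceeding
    ``threshold_k`` times the robust noise sd (estimated on the smoothed
    signal) and separated by at least ``min_separation_ms`` are kept.
    Onset is the last pre-peak crossing of 5% of the peak height.
    Detection is invariant to constant baseline shifts.
    """
    if trace.n_samples == 0:
        raise ParameterError("empty trace")
    if polarity not in _POLARITIES:
        raise ParameterError(f"unknown polarity {polarity!r}")
    if trace.units != "pA":
        raise ParameterError("detect_events expects a current trace in pA")
    fs = trace.sample_rate
    sign = 1.0 if polarity == "outward" else -1.0

    win = max(int(round(smooth_ms / 1000.0 * fs)), 1)
    smooth = uniform_filter1d(trace.values, size=win)
    baseline = _block_baseline(smooth, fs)
    d = (smooth - baseline) * sign

    sd = robust_noise_sd(trace.values, fs)
    if sd == 0.0:
        sd = 1e-12  # noiseless trace: any finite excursion is an event
    height = threshold_k * sd
    distance = max(int(round(min_separation_ms / 1000.0 * fs)), 1)
    # prominence keeps noise wiggles riding a slow decay tail from
    # registering as separate events; a real event's prominence is ≈ its
    # amplitude even when it starts on the tail of the previous one
    peaks, props = signal.find_peaks(
        d, height=height, prominence=height, distance=distance
    )

    # onset estimation runs on a 1 ms-smoothed copy so noise does not
    # scatter the back-walk crossing
    ds = uniform_filter1d(d, size=max(int(round(0.001 * fs)), 1))
    events = []
    for k, (p, h) in enumerate(zip(peaks, props["peak_heights"])):
        # onset: walk back to the 5% crossing of the rise *above the local
        # valley* between this peak and the previous one — for an event
        # riding the decay tail of its predecessor the relevant floor is
        # the tail level, not the resting baseline
        lo = max(p - int(0.02 * fs), 0)
        if k > 0:
            lo = max(lo, int(peaks[k - 1]) + 1)
        seg = d[lo : p + 1]
        valley = float(ds[lo : p + 1].min())
        if valley <= 0.1 * ds[p]:
            # event rises from the resting baseline: last 5%-of-peak crossing
            below = np.nonzero(seg <= 0.05 * d[p])[0]
            onset_rel = int(below[-1]) if below.size else 0
        else:
            # event rides a decay tail: anchor on the sharp mid-rise crossing
            # above the local valley, then refine to the 5% crossing within
            # the few ms just before it (a plain back-walk would descend the
            # predecessor's tail)
            rel = ds[lo : p + 1] - valley
            h_rel = float(rel[-1])
            i50 = np.nonzero(rel <= 0.5 * h_rel)[0]
            i50 = int(i50[-1]) if i50.size else 0
            win_lo = max(i50 - int(0.003 * fs), 0)
            sub = rel[win_lo : i50 + 1]
            i5 = np.nonzero(sub <= 0.05 * h_rel)[0]
            onset_rel = win_lo + (int(i5[-1]) if i5.size else int(np.argmin(sub)))
        onset_idx = lo + onset_rel
        events.append(
            SynapticEvent(
                onset_s=onset_idx / fs,
                peak_time_s=p / fs,
                amplitude_pa=float(sign * h),
            )
        )
    return EventList(events=events, trace_duration=trace.duration, polarity=polarity)


def _exp_model(t: np.ndarray, a: float, tau: float) -> np.ndarray:
    return a * np.exp(-t / tau)


def fit_event_decay(
    trace: Trace,
    event: SynapticEvent,
    fit_window_fraction: float = 0.1,
    next_onset_s: float | None = None,
    subtract_events: list[tuple[float, float, float]] | None = None,
    mask_intervals: list[tuple[float, float]] | None = None,
) -> SynapticEvent:
    """Fit a single exponential to the decay phase of one event.

    The fit runs from the peak to the first crossing of
    ``fit_window_fraction`` of the peak or to five times the initial τ
    guess, whichever comes first, truncated at ``next_onset_s`` if given.
    ``subtract_events`` lists ``(peak_time_s, amplitude_pa, tau_ms)`` of
    neighbouring events whose extrapolated exponential tails are removed
    first — a later event rides on the fitted tail of an earlier one —
    and ``mask_intervals`` (seconds) excludes samples (e.g. neighbouring
    rise phases) from the least-squares objective.  Non-convergence or a
    window shorter than three samples marks the event unclassified
    instead of raising.
    """
    fs = trace.sample_rate
    sign = 1.0 if event.amplitude_pa >= 0 else -1.0
    p = int(round(event.peak_time_s * fs))
    p = min(max(p, 0), trace.n_samples - 1)

    def _tails(idx: np.ndarray) -> np.ndarray:
        out = np.zeros(idx.size)
        for tp, a_prev, tau_prev in subtract_events or ():
            dt_ms = (idx / fs - tp) * 1000.0
            out += np.where(
                dt_ms > 0,
                a_prev * np.exp(-np.clip(dt_ms, 0.0, None) / max(tau_prev, 1e-6)),
                0.0,
            )
        return out

    # local baseline just before onset, with neighbour tails removed
    o = int(round(event.onset_s * fs))
    b_lo = max(o - int(0.005 * fs), 0)
    b_idx = np.arange(b_lo, max(o, b_lo + 1))
    baseline = float(np.median(trace.values[b_idx] - _tails(b_idx)))

    # candidate window: at most 500 ms past the peak (≫ 5× the slowest
    # physiological decay), truncated at the next onset when given
    end = min(trace.n_samples, p + int(0.5 * fs) + 1)
    if next_onset_s is not None:
        end = min(end, int(round(next_onset_s * fs)) - 1)
    idx_all = np.arange(p, max(end, p + 1))
    y_all = (trace.values[p:end] - _tails(idx_all[: end - p]) - baseline) * sign
    if y_all.size < 3 or y_all[0] <= 0:
        return replace(event, tau_decay_ms=float("nan"), class_label="unclassified")

    # crossing times for the window and the initial τ guess come from a
    # smoothed copy: on the raw signal the *first* noisy dip below a level
    # occurs far before the underlying decay reaches it, which would
    # systematically shorten the window and bias τ low.  Masked intervals
    # (neighbouring rise phases, where subtraction leaves a notch) are
    # bridged by linear interpolation so they cannot end the window early.
    y_work = y_all
    if mask_intervals:
        y_work = y_all.copy()
        for m_lo, m_hi in mask_intervals:
            i_lo = int(np.floor(m_lo * fs)) - p - 1
            i_hi = int(np.ceil(m_hi * fs)) - p + 1
            if i_hi <= 0 or i_lo >= y_work.size - 1:
                continue
            i_lo = max(i_lo, 0)
            i_hi = min(i_hi, y_work.size - 1)
            y_work[i_lo : i_hi + 1] = np.linspace(
                y_work[i_lo], y_work[i_hi], i_hi - i_lo + 1
            )
    smooth_n = max(int(round(0.003 * fs)), 1)
    y_ref = uniform_filter1d(y_work, size=smooth_n)
    peak_h = float(max(y_ref[0], y_all[0]))

    def _sustained_crossing(level: float) -> int | None:
        """First index from which y_ref stays below ``level`` for ≥1 ms."""
        hold = max(int(round(0.001 * fs)), 1)
        below = y_ref <= level
        run = uniform_filter1d(below.astype(float), size=hold, mode="nearest")
        hits = np.nonzero(run >= 1.0 - 1e-12)[0]
        return int(hits[0]) if hits.size else None

    cross_e = _sustained_crossing(peak_h / np.e)
    tau0_ms = (cross_e / fs * 1000.0) if cross_e is not None else 10.0
    tau0_ms = max(tau0_ms, 0.25)

    cross_frac = _sustained_crossing(fit_window_fraction * peak_h)
    n_frac = cross_frac + 1 if cross_frac is not None else y_all.size
    n_tau = int(round(5.0 * tau0_ms / 1000.0 * fs)) + 1
    n_fit = min(n_frac, n_tau, y_all.size)
    if n_fit < 3:
        return replace(event, tau_decay_ms=float("nan"), class_label="unclassified")

    t_ms = np.arange(n_fit) / fs * 1000.0
    y = y_all[:n_fit]
    keep = np.ones(n_fit, dtype=bool)
    for m_lo, m_hi in mask_intervals or ():
        lo_ms = (m_lo - p / fs) * 1000.0
        hi_ms = (m_hi - p / fs) * 1000.0
        keep &= ~((t_ms >= lo_ms) & (t_ms <= hi_ms))
    if keep.sum() < 3:
        return replace(event, tau_decay_ms=float("nan"), class_label="unclassified")
    t_fit, y_fit = t_ms[keep], y[keep]
    if t_fit.size > 600:
        # bin-average down to ~400 points: an exponential over tens of ms
        # does not need 20 kHz resolution and curve_fit cost drops 10-fold
        bins = t_fit.size // 400 + 1
        m = (t_fit.size // bins) * bins
        t_fit = t_fit[:m].reshape(-1, bins).mean(axis=1)
        y_fit = y_fit[:m].reshape(-1, bins).mean(axis=1)
    try:
        with np.errstate(divide="ignore", invalid="ignore"):
            popt, _ = optimize.curve_fit(
                _exp_model,
                t_fit,
                y_fit,
                p0=(peak_h, tau0_ms),
                bounds=([0.0, 0.05], [np.inf, 1000.0]),
                maxfev=2000,
            )
    except (RuntimeError, ValueError):
        return replace(event, tau_decay_ms=float("nan"), class_label="unclassified")
    a_fit, tau_fit = popt
    # a τ pinned at a bound or an amplitude far above the observed peak is a
    # degenerate fit (typically a residual spike after imperfect overlap
    # subtraction), not a credible decay constant
    if tau_fit <= 0.06 or tau_fit >= 990.0 or a_fit > 3.0 * peak_h:
        return replace(event, tau_decay_ms=float("nan"), class_label="unclassified")
    rss = float(np.sum((y_fit - _exp_model(t_fit, *popt)) ** 2))
    return replace(
        event,
        amplitude_pa=float(sign * a_fit),
        tau_decay_ms=float(tau_fit),
        fit_rss_pa2=rss,
    )


def fit_all_decays(
    trace: Trace,
    events: EventList,
    fit_window_fraction: float = 0.1,
    n_passes: int = 2,
) -> EventList:
    """Fit every event, decomposing overlaps iteratively.

    The first pass fits in onset order, subtracting the running tails of
    earlier events and truncating each window at the next onset.  Later
    passes refit each event over its full window with the fitted
    components of *all* neighbours (earlier tails and later events)
    subtracted and their rise phases masked, which removes the
    short-window bias that truncation alone would leave on traces with
    overlapping events.
    """
    evs = events.events
    fitted: list[SynapticEvent] = []
    prior: tuple[float, float, float] | None = None
    for i, ev in enumerate(evs):
        nxt = evs[i + 1].onset_s if i + 1 < len(evs) else None
        out = fit_event_decay(
            trace,
            ev,
            fit_window_fraction=fit_window_fraction,
            next_onset_s=nxt,
            subtract_events=[prior] if prior is not None else None,
        )
        fitted.append(out)
        if np.isfinite(out.tau_decay_ms):
            prior = (out.peak_time_s, out.amplitude_pa, out.tau_decay_ms)

    for _ in range(max(n_passes - 1, 0)):
        comps = [
            (e.peak_time_s, e.amplitude_pa, e.tau_decay_ms)
            if np.isfinite(e.tau_decay_ms)
            else None
            for e in fitted
        ]
        refit: list[SynapticEvent] = []
        for i, ev in enumerate(evs):
            lo, hi = max(i - 6, 0), min(i + 7, len(evs))
            neighbours = [
                comps[j] for j in range(lo, hi) if j != i and comps[j] is not None
            ]
            rises = [
                (evs[j].onset_s - 0.0005, evs[j].peak_time_s)
                for j in range(lo, hi)
                if j != i
            ]
            refit.append(
                fit_event_decay(
                    trace,
                    ev,
                    fit_window_fraction=fit_window_fraction,
                    subtract_events=neighbours,
                    mask_intervals=rises,
                )
            )
        fitted = refit

    return EventList(
        events=fitted, trace_duration=events.trace_duration, polarity=events.polarity
    )


def event_frequency(events: EventList, epoch: tuple[float, float]) -> float:
    """Event rate (Hz) within ``epoch = (start_s, end_s)``."""
    start, end = epoch
    if end <= start:
        raise ParameterError("epoch must have positive length")
    if start < 0 or end > events.trace_duration + 1e-9:
        raise ParameterError("epoch outside the trace")
    n = sum(1 for e in events if start <= e.onset_s < end)
    return n / (end - start)
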