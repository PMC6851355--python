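"""Voltage-clamp trace synthesis: phasic events plus tonic current."""
from __future__ import annotations

import numpy as np

from ..trace import ParameterError, Trace
from .params import (
    E_AMPA_MV,
    E_CHLORIDE_MV,
    REFERENCE_DRIVE_MV,
    GroundTruth,
    VCGenParams,
    apply_drug,
)

_CLASS_REVERSAL = {
    "ampa": E_AMPA_MV,
    "glycine": E_CHLORIDE_MV,
    "gaba": E_CHLORIDE_MV,
    "mixed": E_CHLORIDE_MV,
}


def psc_kernel(
    t_ms: np.ndarray, tau_rise_ms: float, tau_decay_ms: float
) -> np.ndarray:
    """Difference-of-exponentials synaptic kernel normalized to unit peak.

    ``exp(-t/τ_decay) − exp(-t/τ_rise)`` for t ≥ 0, scaled so its maximum
    is 1.  Degenerates gracefully when the two constants coincide.
    """
    if tau_decay_ms <= tau_rise_ms:
        tau_decay_ms = tau_rise_ms * 1.001
    t = np.asarray(t_ms, dtype=float)
    raw = np.where(
        t >= 0.0,
        np.exp(-np.clip(t, 0.0, None) / tau_decay_ms)
        - np.exp(-np.clip(t, 0.0, None) / tau_rise_ms),
        0.0,
    )
    t_peak = (
        tau_rise_ms
        * tau_decay_ms
        / (tau_decay_ms - tau_rise_ms)
        * np.log(tau_decay_ms / tau_rise_ms)
    )
    peak = np.exp(-t_peak / tau_decay_ms) - np.exp(-t_peak / tau_rise_ms)
    return raw / peak


def _draw_events(params: VCGenParams, rng: np.random.Generator) -> list[dict]:
    events: list[dict] = []
    for cls in ("ampa", "glycine", "gaba", "mixed"):
        rate = params.event_rate_per_class.get(cls, 0.0)
        if rate <= 0:
            continue
        n = rng.poisson(rate * params.duration)
        times = np.sort(rng.uniform(0.0, params.duration, size=n))
        mean_a, sd_a = params.amp_dist(cls)
        amps = np.abs(rng.normal(mean_a, sd_a, size=n))
        if cls == "mixed":
            mg, sg = params.tau_decay_dist_per_class["glycine"]
            mb, sb = params.tau_decay_dist_per_class["gaba"]
            taus_g = np.clip(rng.normal(mg, sg, size=n), 0.5, None)
            taus_b = np.clip(rng.normal(mb, sb, size=n), 0.5, None)
            for t, a, tg, tb in zip(times, amps, taus_g, taus_b):
                events.append(
                    {
                        "time_s": float(t),
                        "event_class": cls,
                        "amplitude_pa": float(a),
                        "tau_decay_ms": float(0.5 * (tg + tb)),
                        "tau_glycine_ms": float(tg),
                        "tau_gaba_ms": float(tb),
                    }
                )
        else:
            m, s = params.tau_decay_dist_per_class[cls]
            taus = np.clip(rng.normal(m, s, size=n), 0.5, None)
            for t, a, tau in zip(times, amps, taus):
                events.append(
                    {
                        "time_s": float(t),
                        "event_class": cls,
                        "amplitude_pa": float(a),
                        "tau_decay_ms": float(tau),
                    }
                )
    events.sort(key=lambda e: e["time_s"])
    return events


def _add_event(
    values: np.ndarray,
    params: VCGenParams,
    event: dict,
    drive_sign: dict[str, float],
) -> None:
    fs = params.sample_rate
    i0 = int(np.floor(event["time_s"] * fs))
    cls = event["event_class"]
    if cls == "mixed":
        w_gly, w_gaba = params.mixed_component_weights
        span_ms = 8.0 * max(event["tau_gaba_ms"], event["tau_glycine_ms"])
    else:
        span_ms = 8.0 * event["tau_decay_ms"]
    n = min(int(span_ms / 1000.0 * fs) + 1, values.size - i0)
    if n <= 0:
        return
    t_ms = (np.arange(n) / fs - (event["time_s"] - i0 / fs)) * 1000.0
    if cls == "mixed":
        kern = w_gly * psc_kernel(
            t_ms, params.tau_rise_ms, event["tau_glycine_ms"]
        ) + w_gaba * psc_kernel(t_ms, params.tau_rise_ms, event["tau_gaba_ms"])
    else:
        kern = psc_kernel(t_ms, params.tau_rise_ms, event["tau_decay_ms"])
    values[i0 : i0 + n] += drive_sign[cls] * event["amplitude_pa"] * kern


def gen_vc_trace(
    params: VCGenParams,
    seed: int | None = None,
    planted_events: list[dict] | None = None,
) -> tuple[Trace, GroundTruth]:
    """Synthesize a voltage-clamp current trace with its event ledger.

    The trace is ``baseline + g_tonic·(V_hold − E_tonic) + Σ event kernels
    + Gaussian noise``.  Event polarity follows the driving force at the
    holding potential: IPSCs recorded at 0 mV are outward (positive),
    EPSCs at −70 mV inward (negative); drawn amplitudes are expressed at
    the standard 70 mV driving force and scaled accordingly.

    ``planted_events`` replaces the Poisson draw with an explicit list of
    ``{time_s, event_class, amplitude_pa, tau_decay_ms}`` dicts (mixed
    events also need ``tau_glycine_ms``/``tau_gaba_ms``), for recovery
    tests against events at listed times.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    n_samples = int(round(params.duration * params.sample_rate))
    if n_samples <= 0:
        raise ParameterError("duration too short for one sample")

    tonic_pa = params.tonic_current_pa()
    values = np.full(n_samples, params.baseline_current + tonic_pa)

    drive_sign = {
        cls: (params.hold_voltage - erev) / REFERENCE_DRIVE_MV
        for cls, erev in _CLASS_REVERSAL.items()
    }
    if planted_events is not None:
        events = sorted((dict(e) for e in planted_events), key=lambda e: e["time_s"])
    else:
        events = _draw_events(params, rng)
    for ev in events:
        _add_event(values, params, ev, drive_sign)

    if params.noise_sd > 0:
        values += rng.normal(0.0, params.noise_sd, size=n_samples)

    trace = Trace(
        values=values,
        sample_rate=params.sample_rate,
        units="pA",
        metadata={"hold_voltage_mv": params.hold_voltage, "drug_epochs": []},
    )
    truth = GroundTruth(
        events=events,
        true_tonic_current_at_hold_pa=tonic_pa,
        extra={"baseline_current_pa": params.baseline_current},
    )
    return trace, truth


def gen_vc_sequence(
    params: VCGenParams,
    epochs: list[tuple[str, float, list[str]]],
    seed: int | None = None,
    responsive: bool = True,
) -> tuple[Trace, GroundTruth, list[VCGenParams]]:
    """Concatenate epochs of a pharmacology experiment into one trace.

    ``epochs`` is a list of ``(name, duration_s, drugs)`` where ``drugs``
    is the cumulative set applied during that epoch (e.g. ``[]``,
    ``["strychnine"]``, ``["strychnine", "bicuculline"]``).  The drug-epoch
    boundaries are recorded in the trace metadata; the ground truth carries
    the per-epoch tonic current and the concatenated event ledger.
    """
    if not epochs:
        raise ParameterError("at least one epoch is required")
    if seed is None:
        seed = params.seed
    seeds = np.random.SeedSequence(seed).generate_state(len(epochs))

    segments: list[np.ndarray] = []
    all_events: list[dict] = []
    epoch_meta = []
    epoch_params: list[VCGenParams] = []
    t_cursor = 0.0
    for (name, dur, drugs), sub_seed in zip(epochs, seeds):
        p = params.replace(duration=float(dur))
        for d in drugs:
            p = apply_drug(p, d, responsive=responsive)
        seg_trace, seg_truth = gen_vc_trace(p, seed=int(sub_seed % (2**31)))
        segments.append(seg_trace.values)
        for ev in seg_truth.events:
            ev = dict(ev)
            ev["time_s"] += t_cursor
            all_events.append(ev)
        epoch_meta.append(
            {
                "name": name,
                "start_s": t_cursor,
                "end_s": t_cursor + dur,
                "drugs": list(drugs),
                "tonic_current_pa": seg_truth.true_tonic_current_at_hold_pa,
                "baseline_current_pa": p.baseline_current,
            }
        )
        epoch_params.append(p)
        t_cursor += dur

    trace = Trace(
        values=np.concatenate(segments),
        sample_rate=params.sample_rate,
        units="pA",
        metadata={
            "hold_voltage_mv": params.hold_voltage,
            "drug_epochs": [
                {k: m[k] for k in ("name", "start_s", "end_s")} for m in epoch_meta
            ],
        },
    )
    truth = GroundTruth(
        events=all_events,
        true_tonic_current_at_hold_pa=epoch_meta[0]["tonic_current_pa"],
        extra={"epochs": epoch_meta},
    )
    return trace, truth, epoch_params
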