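"""Current-clamp simulation of the conductance-based LIF cell.

Integration uses fixed-step exponential Euler at the trace sample rate:
with piecewise-constant injected current the membrane equation
``C dV/dt = −gL(V−EL) − g_tonic(V−E_tonic) + I`` has the exact per-step
update ``V ← V∞ + (V − V∞)·exp(−dt/τ)``, which is unconditionally stable.
Spikes are threshold/reset events; the spike sample is written at a fixed
peak value so that downstream threshold-crossing detection sees it.
"""
from __future__ import annotations

import numpy as np

from ..trace import ParameterError, Trace
from .params import CellModel, GroundTruth

#: Closed-form rheobase shift produced by removing the tonic conductance:
#: g_tonic·(V_th − E_tonic), i.e. the tonic current at threshold voltage.
def rheobase_shift_pa(cell: CellModel) -> float:
    return cell.tonic_current_pa(cell.v_th_mv)


def gen_cc_response(
    cell: CellModel,
    protocol: list[tuple[float, float, float]],
    sample_rate: float = 20000.0,
    v_init_mv: float | None = None,
    pre_ms: float = 100.0,
) -> tuple[Trace, GroundTruth]:
    """Simulate a sequence of current steps in current clamp.

    ``protocol`` lists ``(amplitude_pA, duration_ms, interval_ms)`` pulses
    delivered in order, each preceded by its zero-current interval (the
    first pulse by ``pre_ms``).  Returns the voltage trace with per-step
    windows in its metadata, and the spike times / per-step spike counts
    in the ground truth.
    """
    if not protocol:
        raise ParameterError("protocol must contain at least one step")
    dt_ms = 1000.0 / sample_rate
    if dt_ms > cell.tau_m_ms:
        raise ParameterError(
            "integration step exceeds the membrane time constant; "
            "raise sample_rate"
        )

    # Build the injected-current waveform and step windows.
    chunks: list[np.ndarray] = [np.zeros(int(round(pre_ms / dt_ms)))]
    steps_meta = []
    t_ms = pre_ms
    for amp, dur_ms, interval_ms in protocol:
        n_pulse = int(round(dur_ms / dt_ms))
        chunks.append(np.full(n_pulse, float(amp)))
        steps_meta.append(
            {
                "amplitude_pa": float(amp),
                "start_s": t_ms / 1000.0,
                "end_s": (t_ms + dur_ms) / 1000.0,
            }
        )
        t_ms += dur_ms
        n_gap = int(round(interval_ms / dt_ms))
        chunks.append(np.zeros(n_gap))
        t_ms += interval_ms
    current = np.concatenate(chunks)

    g_tot = cell.total_conductance_ns
    tau = cell.tau_m_ms
    decay = np.exp(-dt_ms / tau)
    v_rest = cell.v_rest_mv()
    v = v_rest if v_init_mv is None else float(v_init_mv)
    refr_steps = int(round(cell.refractory_ms / dt_ms))

    volt = np.empty_like(current)
    spikes: list[float] = []
    refr = 0
    for i, inj in enumerate(current):
        if refr > 0:
            refr -= 1
            v = cell.v_reset_mv
            volt[i] = v
            continue
        v_inf = v_rest + inj / g_tot
        v = v_inf + (v - v_inf) * decay
        if v >= cell.v_th_mv:
            spikes.append(i * dt_ms / 1000.0)
            volt[i] = cell.spike_peak_mv
            v = cell.v_reset_mv
            refr = refr_steps
        else:
            volt[i] = v

    spikes_per_step = [
        sum(1 for s in spikes if m["start_s"] <= s < m["end_s"]) for m in steps_meta
    ]
    trace = Trace(
        values=volt,
        sample_rate=sample_rate,
        units="mV",
        metadata={"steps": steps_meta, "protocol": "current_steps"},
    )
    truth = GroundTruth(
        spike_times_s=spikes,
        spikes_per_step=spikes_per_step,
        extra={"v_rest_mv": v_rest},
    )
    return trace, truth
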