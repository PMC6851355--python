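"""Study-condition presets for the synthetic recording engine.

The ``study_cell`` LIF preset is derived in closed form from the reported
group means: the control and antagonist-treated input resistances fix the
leak and tonic conductances, the control resting potential and rheobase fix
the spike threshold, and the rheobase difference fixes the tonic reversal
(so the blocked rheobase follows automatically).  The voltage-clamp presets
plant the reported tonic-current shares and the IPSC kinetic mixture; the
calibration preset pairs the LIF with the GCaMP6f kernel under the 8-step
current protocol.
"""
from __future__ import annotations

import dataclasses
from typing import Any

from ..trace import ParameterError
from .calcium import GCAMP_KERNEL
from .params import (
    E_CHLORIDE_MV,
    TONIC_GABA_PA,
    TONIC_GLYCINE_PA,
    CellModel,
    VCGenParams,
)

# Group means reported for GRPR neurons (excitability, Fig-3-style panel).
CONTROL_RHEOBASE_PA = 39.8
BLOCKED_RHEOBASE_PA = 7.4
CONTROL_RIN_MOHM = 911.9
BLOCKED_RIN_MOHM = 2920.0
CONTROL_VREST_MV = -56.96

# IPSC kinetic mixture: glycinergic / GABAergic / co-release fractions.
KINETIC_FRACTIONS = {"glycine": 0.34, "gaba": 0.25, "mixed": 0.41}
#: Total spontaneous IPSC rate used for synthetic recordings, Hz.
TOTAL_IPSC_RATE_HZ = 5.0


def _derive_study_cell() -> CellModel:
    g_total = 1000.0 / CONTROL_RIN_MOHM          # nS
    gl = 1000.0 / BLOCKED_RIN_MOHM               # nS
    g_tonic = g_total - gl
    v_th = CONTROL_VREST_MV + CONTROL_RHEOBASE_PA / g_total
    delta_rheo = CONTROL_RHEOBASE_PA - BLOCKED_RHEOBASE_PA
    e_tonic = v_th - delta_rheo / g_tonic
    el = (CONTROL_VREST_MV * g_total - g_tonic * e_tonic) / gl
    return CellModel(
        gl_ns=gl,
        el_mv=el,
        c_pf=22.0,                               # τ_m ≈ 20 ms in control
        v_th_mv=v_th,
        v_reset_mv=-55.0,
        g_tonic_ns=g_tonic,
        e_tonic_mv=e_tonic,
        refractory_ms=2.0,
    )


def _ipsc_params() -> VCGenParams:
    return VCGenParams(
        duration=60.0,
        hold_voltage=0.0,
        event_rate_per_class={
            cls: TOTAL_IPSC_RATE_HZ * frac for cls, frac in KINETIC_FRACTIONS.items()
        },
        amp_dist_per_class={
            "glycine": (20.0, 5.0),
            "gaba": (20.0, 5.0),
            "mixed": (20.0, 5.0),
        },
        tonic_conductance_ns={
            "glycine": TONIC_GLYCINE_PA / (0.0 - E_CHLORIDE_MV),
            "gaba": TONIC_GABA_PA / (0.0 - E_CHLORIDE_MV),
        },
        baseline_current=5.0,
        noise_sd=2.0,
    )


def _epsc_params() -> VCGenParams:
    return VCGenParams(
        duration=60.0,
        hold_voltage=E_CHLORIDE_MV,
        event_rate_per_class={"ampa": 4.0},
        amp_dist_per_class={"ampa": (20.0, 5.0)},
        tonic_conductance_ns={},
        baseline_current=-20.0,
        noise_sd=2.0,
    )


#: 8-step calibration protocol: 10–80 pA, 10 pA increments, 500 ms pulses
#: separated by 1000 ms.
CALIBRATION_PROTOCOL = [(float(a), 500.0, 1000.0) for a in range(10, 90, 10)]


def _calibration_cell() -> CellModel:
    # A long refractory period caps the firing rate (standing in for spike
    # -frequency adaptation) so that spike counts at 30/80 pA land near the
    # calibration pairing rather than at the raw LIF f-I rate.
    return CellModel(
        gl_ns=1.0,
        el_mv=-60.0,
        c_pf=20.0,
        v_th_mv=-35.0,
        v_reset_mv=-65.0,
        g_tonic_ns=0.0,
        refractory_ms=20.0,
    )


_PRESETS = {
    "study_vc_ipsc": _ipsc_params,
    "study_vc_epsc": _epsc_params,
    "study_cell": _derive_study_cell,
    "study_cell_blocked": lambda: _derive_study_cell().without_tonic(),
    "study_calibration": _calibration_cell,
}


def get_preset(name: str) -> VCGenParams | CellModel:
    """Return a fresh preset object by name."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


def preset_config(name: str) -> dict[str, Any]:
    """JSON-able form of a preset (for config files and provenance)."""
    obj = get_preset(name)
    d = dataclasses.asdict(obj)
    d["preset"] = name
    d["type"] = type(obj).__name__
    return d
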