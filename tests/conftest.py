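import numpy as np
import pytest

from spinaltone.synth import VCGenParams, get_preset


@pytest.fixture
def quiet_params():
    """No events, no tonic, no noise: a flat −20 pA hold."""
    return VCGenParams(
        duration=2.0,
        hold_voltage=0.0,
        event_rate_per_class={},
        tonic_conductance_ns={},
        baseline_current=-20.0,
        noise_sd=0.0,
    )


@pytest.fixture
def ipsc_params():
    return get_preset("study_vc_ipsc")


@pytest.fixture
def study_cell():
    return get_preset("study_cell")


def plant_glycine(times, amp=20.0, tau=6.2):
    """Event dicts for glycinergic events at listed times."""
    return [
        {
            "time_s": float(t),
            "event_class": "glycine",
            "amplitude_pa": float(amp),
            "tau_decay_ms": float(tau),
        }
        for t in times
    ]
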