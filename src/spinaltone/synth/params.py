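"""Parameter objects and pharmacology for the synthetic recording engine.

The voltage-clamp generator superimposes Poisson trains of postsynaptic
currents — AMPA-mediated EPSCs and glycinergic, GABAergic or co-released
(mixed) IPSCs — on a baseline that includes a persistent (tonic) chloride
conductance.  Bath-applied antagonists are modeled as parameter transforms:
strychnine removes the glycinergic phasic and tonic components, bicuculline
the GABAergic ones, CNQX/NBQX block ~90% of AMPA events (CNQX additionally
shifts the holding current), and GRP depolarizes responsive cells only.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

from ..trace import ParameterError

#: Synaptic event classes recognized by the generator.
EVENT_CLASSES = ("ampa", "glycine", "gaba", "mixed")

#: Reversal potential of chloride-mediated currents, mV (IPSC reversal;
#: EPSCs are recorded while holding at this potential).
E_CHLORIDE_MV = -70.0
#: Reversal potential of AMPA-mediated currents, mV (EPSC reversal; IPSCs
#: are recorded while holding here).
E_AMPA_MV = 0.0
#: Driving force (mV) at which drawn amplitudes are expressed: both standard
#: holds sit 70 mV from the opposing reversal.
REFERENCE_DRIVE_MV = 70.0

#: Mean tonic current carried by each receptor class at a 0 mV hold, pA.
TONIC_GLYCINE_PA = 10.25
TONIC_GABA_PA = 22.5

_DRUGS = ("strychnine", "bicuculline", "cnqx", "nbqx", "grp")


@dataclass
class VCGenParams:
    """Voltage-clamp generator settings.

    Rates are per-class Poisson rates in Hz; amplitude and decay
    distributions are (mean, sd) pairs in pA and ms.  Tonic conductance is
    split by receptor class (nS); its current at the hold is
    ``g * (hold_voltage - tonic_reversal)``.
    """

    duration: float = 60.0
    sample_rate: float = 20000.0
    hold_voltage: float = 0.0
    event_rate_per_class: dict[str, float] = field(default_factory=dict)
    amp_dist_per_class: dict[str, tuple[float, float]] = field(default_factory=dict)
    tau_rise_ms: float = 0.7
    tau_decay_dist_per_class: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ampa": (2.5, 0.8),
            "glycine": (6.2, 2.2),
            "gaba": (42.0, 6.0),
        }
    )
    mixed_component_weights: tuple[float, float] = (0.5, 0.5)
    tonic_conductance_ns: dict[str, float] = field(default_factory=dict)
    tonic_reversal: float = E_CHLORIDE_MV
    baseline_current: float = 0.0
    noise_sd: float = 2.0
    cnqx_block_fraction: float = 0.9
    cnqx_shift_pa: float = 11.5
    grp_shift_pa: float = 12.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ParameterError("duration must be positive")
        if not self.sample_rate > 0:
            raise ParameterError("sample_rate must be positive")
        if not self.tau_rise_ms > 0:
            raise ParameterError("tau_rise_ms must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        for cls, rate in self.event_rate_per_class.items():
            if cls not in EVENT_CLASSES:
                raise ParameterError(f"unknown event class {cls!r}")
            if rate < 0:
                raise ParameterError(f"negative event rate for class {cls!r}")
        for cls, (mean, sd) in self.amp_dist_per_class.items():
            if cls not in EVENT_CLASSES:
                raise ParameterError(f"unknown event class {cls!r}")
            if sd < 0:
                raise ParameterError(f"negative amplitude sd for class {cls!r}")
        for cls, (mean, sd) in self.tau_decay_dist_per_class.items():
            if mean <= 0 or sd < 0:
                raise ParameterError(f"invalid decay distribution for {cls!r}")
        for cls, g in self.tonic_conductance_ns.items():
            if g < 0:
                raise ParameterError(f"negative tonic conductance for {cls!r}")

    @property
    def total_tonic_conductance_ns(self) -> float:
        return float(sum(self.tonic_conductance_ns.values()))

    def tonic_current_pa(self) -> float:
        """Tonic current at the holding potential (pA; outward positive)."""
        return self.total_tonic_conductance_ns * (
            self.hold_voltage - self.tonic_reversal
        )

    def amp_dist(self, cls: str) -> tuple[float, float]:
        return self.amp_dist_per_class.get(cls, (20.0, 5.0))

    def replace(self, **changes: Any) -> "VCGenParams":
        return dataclasses.replace(self, **changes)


@dataclass
class CellModel:
    """Conductance-based leaky integrate-and-fire neuron.

    Units: conductances nS, voltages mV, capacitance pF, times ms; currents
    therefore come out in pA and the membrane time constant in ms.  The
    tonic chloride conductance ``g_tonic_ns`` can be removed (antagonists)
    to reproduce the excitability shift of disinhibited cells.
    """

    gl_ns: float
    el_mv: float
    c_pf: float
    v_th_mv: float
    v_reset_mv: float
    g_tonic_ns: float = 0.0
    e_tonic_mv: float = E_CHLORIDE_MV
    refractory_ms: float = 2.0
    #: Fraction of the tonic conductance carried by glycine receptors
    #: (the remainder is GABAergic); used by the pharmacology transforms.
    tonic_glycine_fraction: float = TONIC_GLYCINE_PA / (TONIC_GLYCINE_PA + TONIC_GABA_PA)
    #: Voltage value written into the trace at a spike sample, mV.
    spike_peak_mv: float = 20.0

    def __post_init__(self) -> None:
        if not self.gl_ns > 0:
            raise ParameterError("leak conductance must be positive")
        if not self.c_pf > 0:
            raise ParameterError("capacitance must be positive")
        if self.g_tonic_ns < 0:
            raise ParameterError("tonic conductance must be non-negative")
        if not self.v_th_mv > self.el_mv:
            raise ParameterError("spike threshold must exceed the leak reversal")
        if not 0.0 <= self.tonic_glycine_fraction <= 1.0:
            raise ParameterError("tonic_glycine_fraction must lie in [0, 1]")

    @property
    def total_conductance_ns(self) -> float:
        return self.gl_ns + self.g_tonic_ns

    @property
    def tau_m_ms(self) -> float:
        """Membrane time constant C / g_total."""
        return self.c_pf / self.total_conductance_ns

    def v_rest_mv(self) -> float:
        """Resting potential (gL·EL + g_tonic·E_tonic) / (gL + g_tonic)."""
        return (
            self.gl_ns * self.el_mv + self.g_tonic_ns * self.e_tonic_mv
        ) / self.total_conductance_ns

    def input_resistance_mohm(self) -> float:
        """Steady-state input resistance 1/(gL + g_tonic), in MΩ."""
        return 1000.0 / self.total_conductance_ns

    def rheobase_analytic_pa(self) -> float:
        """Steady-state rheobase (V_th − V_rest)·(gL + g_tonic)."""
        return (self.v_th_mv - self.v_rest_mv()) * self.total_conductance_ns

    def tonic_current_pa(self, v_mv: float) -> float:
        """Current through the tonic conductance at membrane potential v."""
        return self.g_tonic_ns * (v_mv - self.e_tonic_mv)

    def without_tonic(self) -> "CellModel":
        """The same cell with the tonic conductance fully antagonized."""
        return dataclasses.replace(self, g_tonic_ns=0.0)

    def replace(self, **changes: Any) -> "CellModel":
        return dataclasses.replace(self, **changes)


def apply_drug(
    params: VCGenParams | CellModel, drug: str, responsive: bool = True
) -> VCGenParams | CellModel:
    """Transform generator or cell parameters for a bath-applied drug.

    Strychnine (glycine-receptor antagonist) zeroes the glycinergic event
    rate, the glycine component of mixed events and the glycine tonic
    share; bicuculline does the same for GABA.  CNQX and NBQX multiply the
    AMPA event rate by the block fraction; CNQX additionally shifts the
    baseline current in the depolarizing (inward) direction while NBQX does
    not.  GRP shifts the baseline only for responsive cells.
    """
    if drug not in _DRUGS:
        raise ParameterError(f"unknown drug {drug!r}; expected one of {_DRUGS}")

    if isinstance(params, CellModel):
        if drug == "strychnine":
            g = params.g_tonic_ns * (1.0 - params.tonic_glycine_fraction)
            frac = 0.0
            return params.replace(g_tonic_ns=g, tonic_glycine_fraction=frac)
        if drug == "bicuculline":
            g = params.g_tonic_ns * params.tonic_glycine_fraction
            frac = 1.0 if g > 0 else 0.0
            return params.replace(g_tonic_ns=g, tonic_glycine_fraction=frac)
        # AMPA antagonists and GRP act on synaptic events / holding current
        # only; the intrinsic cell model is unchanged.
        return params.replace()

    rates = dict(params.event_rate_per_class)
    tonic = dict(params.tonic_conductance_ns)
    weights = params.mixed_component_weights
    baseline = params.baseline_current

    if drug == "strychnine":
        rates["glycine"] = 0.0
        weights = (0.0, weights[1])
        tonic["glycine"] = 0.0
    elif drug == "bicuculline":
        rates["gaba"] = 0.0
        weights = (weights[0], 0.0)
        tonic["gaba"] = 0.0
    elif drug in ("cnqx", "nbqx"):
        rates["ampa"] = rates.get("ampa", 0.0) * (1.0 - params.cnqx_block_fraction)
        if drug == "cnqx":
            baseline -= params.cnqx_shift_pa  # depolarizing = inward
    elif drug == "grp":
        if responsive:
            baseline -= params.grp_shift_pa

    return params.replace(
        event_rate_per_class=rates,
        tonic_conductance_ns=tonic,
        mixed_component_weights=weights,
        baseline_current=baseline,
    )


@dataclass
class GroundTruth:
    """Generator ledger retained for recovery tests.

    ``events`` lists dicts with ``time_s``, ``event_class``, ``amplitude_pa``
    and ``tau_decay_ms``; the remaining fields are filled by whichever
    generator produced the artifact.
    """

    events: list[dict[str, Any]] = field(default_factory=list)
    true_tonic_current_at_hold_pa: float = 0.0
    spike_times_s: list[float] = field(default_factory=list)
    spikes_per_step: list[int] = field(default_factory=list)
    planted_prevalence: dict[str, float] = field(default_factory=dict)
    extra: dict[str, Any] = field(default_factory=dict)
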