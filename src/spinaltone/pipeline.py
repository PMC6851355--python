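"""End-to-end experiment drivers producing a JSON-able report.

Each experiment strings the synthetic-data engine and the analysis stages
together the way the corresponding recording session would: IPSC profiling
with sequential strychnine/bicuculline application, EPSC profiling with
CNQX/NBQX and the GRP positive control, excitability before/after
antagonists, somatostatin calcium-imaging cohorts, and single-cell
prevalence profiling.  Reports are pure functions of (config, seed).
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .calcium import (
    CalciumCellRecord,
    classify_cell_activity,
    compute_dff,
    measure_reaction_time,
    summarize_cohort,
)
from .config import ConfigError, PipelineConfig
from .events import detect_events, event_frequency, fit_all_decays
from .excitability import (
    compare_groups,
    find_rheobase,
    measure_input_resistance,
    measure_resting_potential,
)
from .inhibition import (
    ClassBoundaries,
    InhibitionProfile,
    classify_events,
    estimate_holding_current,
    mixture_proportions,
)
from .scrna import gene_prevalence, normalize_and_log, select_population
from .synth import (
    apply_drug,
    gen_calcium_cohort,
    gen_cc_response,
    gen_count_matrix,
    gen_vc_sequence,
    get_preset,
)
from .trace import ParameterError

log = logging.getLogger("spinaltone")

EXPERIMENTS = (
    "ipsc_profile",
    "epsc_profile",
    "excitability",
    "calcium_cohort",
    "scrna",
)

#: Prevalences planted in the synthetic count matrix: the study's marker
#: and receptor-subunit panel values for the Grpr population.
PLANTED_PANEL = {
    "Grpr": 0.0667,  # ≈103 of 1545 cells
    "Slc17a6": 0.942,
    "Slc32a1": 0.087,
    "Pax2": 0.019,
    "Tlx3": 0.029,
    "Ebf2": 0.641,
    "Gria1": 0.621,
    "Gria2": 1.0,
    "Gria3": 0.612,
    "Gria4": 0.388,
    "Gabra1": 0.146,
    "Gabra2": 0.233,
    "Gabra3": 0.447,
    "Gabra4": 0.136,
    "Gabra5": 0.272,
    "Gabra6": 0.01,
    "Glra1": 0.029,
    "Glra2": 0.049,
    "Glra3": 0.049,
    "Glra4": 0.019,
    "Glrb": 0.786,
}


def _epoch_core(meta: dict, margin_s: float = 2.0) -> tuple[float, float]:
    """Analysis window of a drug epoch, trimmed clear of the wash-in edges."""
    return meta["start_s"] + margin_s, meta["end_s"] - margin_s


def _ipsc_profile(config: PipelineConfig, rng: np.random.Generator) -> dict[str, Any]:
    params = get_preset(config.generator_preset)
    epoch_s = 60.0
    trace, truth, _ = gen_vc_sequence(
        params,
        [
            ("control", epoch_s, []),
            ("strychnine", epoch_s, ["strychnine"]),
            ("strychnine+bicuculline", epoch_s, ["strychnine", "bicuculline"]),
        ],
        seed=int(rng.integers(2**31)),
    )
    epochs = trace.metadata["drug_epochs"]
    det = config.detection
    events = detect_events(
        trace,
        polarity="outward",
        threshold_k=det.threshold_k,
        min_separation_ms=det.min_separation_ms,
    )
    events = fit_all_decays(trace, events, det.fit_window_fraction)
    boundaries = ClassBoundaries(
        config.boundaries.mixed_low_ms, config.boundaries.mixed_high_ms
    )
    classify_events(events, boundaries)

    ctrl = _epoch_core(epochs[0])
    stry = _epoch_core(epochs[1])
    both = _epoch_core(epochs[2])

    from .events import EventList

    ctrl_events = EventList(
        events=[e for e in events if ctrl[0] <= e.onset_s < ctrl[1]],
        trace_duration=trace.duration,
        polarity="outward",
    )
    fractions = mixture_proportions(ctrl_events)

    f_ctrl = event_frequency(events, ctrl)
    f_stry = event_frequency(events, stry)
    f_both = event_frequency(events, both)

    h_ctrl = estimate_holding_current(trace, ctrl)
    h_stry = estimate_holding_current(trace, stry)
    h_both = estimate_holding_current(trace, both)

    profile = InhibitionProfile(
        fraction_glycinergic=fractions["glycinergic"],
        fraction_gabaergic=fractions["gabaergic"],
        fraction_mixed=fractions["mixed"],
        tonic_glycine_pa=abs(h_stry - h_ctrl),
        tonic_gaba_pa=abs(h_both - h_stry),
        strychnine_block_fraction=(f_ctrl - f_stry) / f_ctrl if f_ctrl > 0 else float("nan"),
        bicuculline_block_fraction=(f_stry - f_both) / f_stry if f_stry > 0 else float("nan"),
    )
    return {
        "n_events_detected": {"value": len(events), "units": "count"},
        "control_frequency": {"value": f_ctrl, "units": "Hz"},
        "post_strychnine_frequency": {"value": f_stry, "units": "Hz"},
        "post_both_frequency": {"value": f_both, "units": "Hz"},
        "kinetic_fractions": {
            "value": fractions,
            "units": "fraction of classified control events",
        },
        "tonic_glycine": {"value": profile.tonic_glycine_pa, "units": "pA"},
        "tonic_gaba": {"value": profile.tonic_gaba_pa, "units": "pA"},
        "tonic_total": {
            "value": profile.tonic_glycine_pa + profile.tonic_gaba_pa,
            "units": "pA",
        },
        "blockade_fractions": {
            "value": {
                "strychnine": profile.strychnine_block_fraction,
                "bicuculline": profile.bicuculline_block_fraction,
            },
            "units": "fraction of pre-drug frequency",
        },
        "planted_tonic": {
            "value": truth.extra["epochs"][0]["tonic_current_pa"],
            "units": "pA",
        },
    }


def _epsc_profile(config: PipelineConfig, rng: np.random.Generator) -> dict[str, Any]:
    params = get_preset("study_vc_epsc")
    epoch_s = 60.0
    trace, truth, _ = gen_vc_sequence(
        params,
        [("control", epoch_s, []), ("cnqx", epoch_s, ["cnqx"]),
         ("grp", epoch_s, ["cnqx", "grp"])],
        seed=int(rng.integers(2**31)),
    )
    epochs = trace.metadata["drug_epochs"]
    det = config.detection
    events = detect_events(
        trace,
        polarity="inward",
        threshold_k=det.threshold_k,
        min_separation_ms=det.min_separation_ms,
    )
    ctrl = _epoch_core(epochs[0])
    cnqx = _epoch_core(epochs[1])
    grp = _epoch_core(epochs[2])
    f_ctrl = event_frequency(events, ctrl)
    f_cnqx = event_frequency(events, cnqx)
    h_ctrl = estimate_holding_current(trace, ctrl)
    h_cnqx = estimate_holding_current(trace, cnqx)
    h_grp = estimate_holding_current(trace, grp)
    return {
        "control_frequency": {"value": f_ctrl, "units": "Hz"},
        "post_cnqx_frequency": {"value": f_cnqx, "units": "Hz"},
        "cnqx_block_fraction": {
            "value": (f_ctrl - f_cnqx) / f_ctrl if f_ctrl > 0 else float("nan"),
            "units": "fraction",
        },
        "cnqx_shift": {"value": abs(h_cnqx - h_ctrl), "units": "pA"},
        "grp_shift": {"value": abs(h_grp - h_cnqx), "units": "pA"},
    }


def _excitability(config: PipelineConfig, rng: np.random.Generator) -> dict[str, Any]:
    cell = get_preset(config.cell_preset)
    blocked = apply_drug(apply_drug(cell, "strychnine"), "bicuculline")

    def cohort(base, n, jitter=0.15):
        cells = []
        for _ in range(n):
            f = rng.lognormal(0.0, jitter, size=3)
            cells.append(
                base.replace(
                    gl_ns=base.gl_ns * f[0],
                    g_tonic_ns=base.g_tonic_ns * f[1],
                    c_pf=base.c_pf * f[2],
                )
            )
        return cells

    controls = cohort(cell, 15)
    treated = cohort(blocked, 5)

    def measures(c):
        rheo = find_rheobase(c, sample_rate=5000.0)
        step = -5.0
        resp, _ = gen_cc_response(c, [(step, 500.0, 0.0)], sample_rate=5000.0)
        rin = measure_input_resistance(resp, step)
        rest, _ = gen_cc_response(c, [(0.0, 500.0, 0.0)], sample_rate=5000.0)
        vrest = measure_resting_potential(rest, (0.05, rest.duration))
        return rheo, rin, vrest

    ctrl_vals = [measures(c) for c in controls]
    trt_vals = [measures(c) for c in treated]
    out: dict[str, Any] = {}
    for i, (name, unit) in enumerate(
        [("rheobase", "pA"), ("input_resistance", "MOhm"), ("resting_potential", "mV")]
    ):
        a = [v[i] for v in ctrl_vals if v[i] is not None]
        b = [v[i] for v in trt_vals if v[i] is not None]
        cmp = compare_groups(a, b, test="t_two_tailed")
        out[name] = {
            "value": {
                "control_mean": cmp.mean_a,
                "control_sem": cmp.sem_a,
                "treated_mean": cmp.mean_b,
                "treated_sem": cmp.sem_b,
                "p_value": cmp.p_value,
            },
            "units": unit,
        }
    out["analytic"] = {
        "value": {
            "control_rheobase": cell.rheobase_analytic_pa(),
            "blocked_rheobase": blocked.rheobase_analytic_pa(),
            "rheobase_shift": cell.rheobase_analytic_pa() - blocked.rheobase_analytic_pa(),
            "tonic_current_at_threshold": cell.tonic_current_pa(cell.v_th_mv),
        },
        "units": "pA",
    }
    return out


def _calcium_cohort(config: PipelineConfig, rng: np.random.Generator) -> dict[str, Any]:
    cal = config.calcium
    traces, truth = gen_calcium_cohort(
        n_cells=74,
        responder_fraction=0.338,
        condition="somatostatin",
        duration_s=900.0,
        drug_arrival_s=cal.drug_arrival_s,
        seed=int(rng.integers(2**31)),
    )
    records = []
    for tr in traces:
        dff = compute_dff(tr, (0.0, cal.drug_baseline_s))
        rec = CalciumCellRecord(
            dff=dff, condition="somatostatin", preparation=tr.metadata["preparation"]
        )
        classify_cell_activity(
            rec,
            threshold_pct=cal.threshold_pct,
            window_s=cal.burst_window_s,
            burst_min_peaks=cal.burst_min_peaks,
            min_separation_s=cal.min_separation_s,
        )
        measure_reaction_time(rec, cal.drug_arrival_s)
        records.append(rec)
    summary = summarize_cohort(records, condition="somatostatin")

    ctrl_traces, _ = gen_calcium_cohort(
        n_cells=74,
        responder_fraction=0.0,
        spontaneous_fraction=0.055,
        condition="control",
        duration_s=300.0,
        drug_arrival_s=300.0,
        seed=int(rng.integers(2**31)),
    )
    ctrl_records = []
    for tr in ctrl_traces:
        dff = compute_dff(tr, (0.0, cal.control_baseline_s))
        rec = CalciumCellRecord(dff=dff, condition="control")
        classify_cell_activity(rec, threshold_pct=cal.threshold_pct)
        ctrl_records.append(rec)
    ctrl_summary = summarize_cohort(ctrl_records, condition="control")

    a = [r.max_dff_pct for r in records if r.label != "inactive"]
    b = [r.max_dff_pct for r in ctrl_records if r.label != "inactive"]
    dff_cmp = (
        compare_groups(a, b, test="mann_whitney").as_dict()
        if len(a) >= 2 and len(b) >= 2
        else None
    )
    return {
        "somatostatin": {"value": summary.as_dict(), "units": "see keys"},
        "control": {"value": ctrl_summary.as_dict(), "units": "see keys"},
        "dff_comparison": {"value": dff_cmp, "units": "percent ΔF/F"},
        "planted_responder_fraction": {"value": 0.338, "units": "fraction"},
    }


def _scrna(config: PipelineConfig, rng: np.random.Generator) -> dict[str, Any]:
    cm, truth = gen_count_matrix(
        n_genes=200,
        n_cells=1545,
        planted_prevalence=PLANTED_PANEL,
        seed=int(rng.integers(2**31)),
    )
    norm = normalize_and_log(cm)
    sc_cfg = config.scrna
    pop = select_population(
        norm,
        gene=sc_cfg.population_gene,
        threshold=sc_cfg.threshold,
        direction=sc_cfg.direction,
    )
    panel = [g for g in PLANTED_PANEL if g != "Grpr"]
    prev = gene_prevalence(pop, panel=panel, threshold=sc_cfg.threshold)
    return {
        "population_size": {"value": prev.population_size, "units": "cells"},
        "prevalence": {"value": prev.prevalence_pct, "units": "percent"},
        "planted_prevalence": {
            "value": {g: 100.0 * p for g, p in truth.planted_prevalence.items() if g in panel},
            "units": "percent",
        },
    }


_RUNNERS = {
    "ipsc_profile": _ipsc_profile,
    "epsc_profile": _epsc_profile,
    "excitability": _excitability,
    "calcium_cohort": _calcium_cohort,
    "scrna": _scrna,
}


def run_pipeline(config: PipelineConfig, experiment: str) -> dict[str, Any]:
    """Run one experiment end to end; deterministic given the config seed."""
    if experiment not in _RUNNERS:
        raise ConfigError(
            f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}"
        )
    rng = np.random.default_rng(config.seed)
    log.info("running experiment %s (seed %d)", experiment, config.seed)
    try:
        results = _RUNNERS[experiment](config, rng)
    except ParameterError as exc:
        raise ParameterError(f"stage {experiment!r} failed: {exc}") from exc
    return {
        "experiment": experiment,
        "results": results,
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "version": __version__,
        },
        "warnings": [],
    }


def write_report(report: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))
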