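"""Scenario orchestration: generate → simulate → assign → extract → test.

Each named scenario reproduces one of the study's analyses end-to-end on
synthetic data and returns a :class:`ScenarioReport` whose headline
numbers are all recomputed at run time.  Scenarios are deterministic
given (config, seed); all randomness flows from the single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import cellcycle as cc
from . import kinetics as kin
from . import stats_quant as sq
from . import synthetic_data as sd
from . import trace_features as tf
from . import virtual_sync as vs

__all__ = ["ScenarioReport", "SCENARIOS", "load_config", "run_scenario"]

SCENARIOS = ("fig3_cycle_effects", "fig2_phase_response", "fig6_refractory",
             "fig8_alignment", "fccs_kd", "fcs_counting")

_CONFIG_FOR = {
    "fig3_cycle_effects": "fig3_default.yaml",
    "fig2_phase_response": "fig2_default.yaml",
    "fig6_refractory": "fig6_default.yaml",
    "fig8_alignment": "fig8_default.yaml",
    "fccs_kd": "fccs_default.yaml",
    "fcs_counting": "fcs_rela_default.yaml",
}


@dataclass
class ScenarioReport:
    scenario: str
    seed: int
    config: dict
    headline: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)   # stage -> file path

    def to_json(self) -> str:
        def clean(o):
            if isinstance(o, dict):
                return {k: clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return o
        return json.dumps(clean(asdict(self)), indent=1, sort_keys=True)


def load_config(name_or_path) -> dict:
    """Load a scenario YAML: a packaged default name or a file path."""
    p = Path(str(name_or_path))
    if p.exists():
        return yaml.safe_load(p.read_text()) or {}
    ref = resources.files("nfkbe2f.configs") / str(name_or_path)
    if ref.is_file():
        return yaml.safe_load(ref.read_text()) or {}
    raise FileNotFoundError(f"no config file or packaged config {name_or_path!r}")


def _population_config(block: dict, seed: int) -> sd.PopulationConfig:
    block = dict(block or {})
    prog_kw = block.pop("program", {})
    program = cc.CycleProgram(**prog_kw)
    overrides = block.pop("param_overrides", None)
    kw = dict(block)
    kw["program"] = program
    if overrides is not None:
        kw["param_overrides"] = tuple((k, float(v)) for k, v in overrides.items())
    if "heterogeneity_cv" in kw:
        kw["heterogeneity_cv"] = tuple(
            (k, float(v)) for k, v in kw["heterogeneity_cv"].items())
    if "cycle_effect" in kw:
        kw["cycle_effect"] = sd.CycleEffect(**kw["cycle_effect"])
    return sd.PopulationConfig(seed=seed, **kw)


def _sub_seeds(seed: int, n: int):
    return [int(s) for s in
            np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


def _spanning_durations(traces):
    """Duration of the mitosis-to-mitosis cycle containing treatment, per
    cell; cells without both bracketing mitoses are excluded (counted)."""
    durations, phases, excluded = [], [], 0
    for tr in traces:
        t_h = tr.treatment_time_min / 60.0
        before = [m for m in tr.mitosis_times_h if m <= t_h]
        after = [m for m in tr.mitosis_times_h if m > t_h]
        if not before or not after:
            excluded += 1
            continue
        durations.append(min(after) - max(before))
        phases.append(tr.ground_truth["phase_at_treatment"]
                      if tr.ground_truth else None)
    return np.asarray(durations), phases, excluded


# ---------------------------------------------------------------- scenarios

def _run_fig3(config, seed):
    # the two arms share one seed (matched populations): base durations and
    # treatment phases coincide, so the contrast isolates the TNFα effect
    s_pop, s_boot = _sub_seeds(seed, 2)
    pop = config.get("population", {})
    cfg_u = _population_config({**pop, "dose_scale": 0.0}, s_pop)
    cfg_t = _population_config({**pop, "dose_scale": pop.get("dose_scale", 1.0)
                                if pop.get("dose_scale", 1.0) > 0 else 1.0},
                               s_pop)
    untreated = sd.generate_population(cfg_u)
    treated = sd.generate_population(cfg_t)
    dur_u, _, excl_u = _spanning_durations(untreated)
    dur_t, ph_t, excl_t = _spanning_durations(treated)
    summary = sq.cycle_effect_summary(dur_u, dur_t, ph_t, seed=s_boot,
                                      n_boot=config.get("n_boot", 2000))
    summary["excluded_untreated"] = excl_u
    summary["excluded_treated"] = excl_t
    return {"cycle_effect": summary}, {"untreated": untreated,
                                       "treated": treated}


def _phase_groups(traces, program, method="mitosis"):
    feats = tf.features_table(traces)
    if method == "mitosis":
        assigns = [vs.assign_phase_from_mitosis(tr, program, duration="mean")
                   for tr in traces]
    else:
        assigns = vs.assign_phase_from_e2f1(traces, program)
    return feats, assigns, vs.group_by_phase(feats, assigns)


def _dunn_contrast(grouped, alpha=0.05):
    labels = [l for l in ("G1", "G1/S", "S", "G2") if l in grouped["groups"]]
    res = sq.kruskal_dunn([grouped["groups"][l] for l in labels],
                          labels=labels, alpha=alpha)
    pair = res.pairwise
    row = pair[((pair.group_a == "G1/S") & (pair.group_b == "S"))
               | ((pair.group_a == "S") & (pair.group_b == "G1/S"))]
    contrast = row.iloc[0].to_dict() if len(row) else None
    return res, contrast


def _run_fig2(config, seed):
    pop = config.get("population", {})
    cfg = _population_config(pop, _sub_seeds(seed, 1)[0])
    traces = sd.generate_population(cfg)
    feats, assigns, grouped = _phase_groups(traces, cfg.program,
                                            config.get("method", "mitosis"))
    res, contrast = _dunn_contrast(grouped)
    means = {k: float(v.mean()) for k, v in grouped["groups"].items()}
    return {
        "group_ns": grouped["ns"],
        "group_means": means,
        "excluded": {k: v for k, v in grouped["excluded"].items()
                     if k != "id_mismatch"},
        "kruskal_H": res.statistic, "kruskal_p": res.p_value,
        "g1s_vs_s": contrast,
    }, {"traces": traces, "features": feats, "groups": grouped}


def _run_fig6(config, seed):
    n = config.get("n_cells_per_arm", 20)
    cv = config.get("heterogeneity_cv", 0.03)
    e2f1_pool = config.get("e2f1_pool_nM", 150.0)
    grid = np.arange(0.0, config.get("t_end_min", 1500.0) + 1,
                     config.get("dt_min", 2.0))
    rng = np.random.default_rng(_sub_seeds(seed, 1)[0])
    base_defaults = kin.default_params("base")

    delays, intervals = [], []
    for _ in range(n):
        ov = {"k_ikk_act": base_defaults["k_ikk_act"]
              * float(np.exp(rng.normal(0, cv))),
              "k_tikba_max": base_defaults["k_tikba_max"]
              * float(np.exp(rng.normal(0, cv)))}
        m = kin.build_model("revised", ov)
        y0 = np.zeros(len(m.species))
        ix = m.index
        y0[ix["NFkB_E2F1_n"]] = 0.95 * m.params["NFkB_total"]
        y0[ix["NFkB_IkBa_c"]] = 0.05 * m.params["NFkB_total"]
        y0[ix["E2F1_n"]] = e2f1_pool
        y0[ix["IKKn"]] = m.params["IKK_total"]
        traj = kin.simulate_cell(m, y0, kin.StimulusProtocol(0, np.inf, 1.0),
                                 grid, rtol=1e-6, atol=1e-8)
        delays.append(tf.refractory_delay(grid, traj.nc, 0.0))
    for _ in range(n):
        ov = {"k_ikk_act": base_defaults["k_ikk_act"]
              * float(np.exp(rng.normal(0, cv))),
              "k_tikba_max": base_defaults["k_tikba_max"]
              * float(np.exp(rng.normal(0, cv)))}
        m = kin.build_model("base", ov)
        eq = kin.equilibrate(m, tol=1e-6)
        traj = kin.simulate_cell(m, eq, kin.StimulusProtocol(0, np.inf, 1.0),
                                 np.arange(0.0, 601.0, 2.0),
                                 rtol=1e-6, atol=1e-8)
        pt, _ = tf.detect_peaks(traj.t, traj.nc)
        intervals.append(pt[1] - pt[0] if len(pt) >= 2 else np.nan)
    delays = np.asarray(delays)
    intervals = np.asarray(intervals)
    mean_delay = float(np.nanmean(delays))
    mean_interval = float(np.nanmean(intervals))
    return {
        "n_per_arm": n,
        "mean_refractory_delay_min": mean_delay,
        "censored_delays": int(np.isnan(delays).sum()),
        "mean_peak1_peak2_interval_min": mean_interval,
        "censored_intervals": int(np.isnan(intervals).sum()),
        "delay_ratio": mean_delay / mean_interval,
    }, {"delays": delays, "intervals": intervals}


def _run_fig8(config, seed):
    pop = config.get("population", {})
    cfg = _population_config(pop, _sub_seeds(seed, 1)[0])
    traces = sd.generate_population(cfg)
    aligned = vs.align_to_e2f1_peak(traces, cfg.program)
    feats, assigns, grouped = _phase_groups(traces, cfg.program,
                                            method="e2f1")
    res, contrast = _dunn_contrast(grouped)
    spline_vals = {}
    if aligned.spline is not None:
        for h in (-5.0, 0.0, 5.0):
            spline_vals[f"spline_at_{h:+.0f}h"] = float(aligned.spline(h))
    return {
        "n_aligned": len(aligned.table),
        "n_excluded_no_peak": aligned.n_excluded,
        "group_ns": grouped["ns"],
        "group_means": {k: float(v.mean())
                        for k, v in grouped["groups"].items()},
        "kruskal_H": res.statistic, "kruskal_p": res.p_value,
        "g1s_vs_s": contrast,
        **spline_vals,
    }, {"traces": traces, "aligned": aligned}


def _run_fccs(config, seed):
    kd = config.get("true_kd_nM", 12.0)
    trips = sd.generate_fccs_set(
        true_kd_nM=kd, n=config.get("n", 46),
        abundance_range=tuple(config.get("abundance_range_nM", (5.0, 200.0))),
        noise_sd=config.get("noise_sd", 0.10),
        seed=_sub_seeds(seed, 1)[0])
    est = sq.estimate_kd(trips)
    return {
        "true_kd_nM": kd, "estimated_kd_nM": est.kd_nM,
        "ci_nM": [est.ci_low_nM, est.ci_high_nM], "n": est.n,
        "relative_error": abs(est.kd_nM - kd) / kd,
    }, {"triplets": trips}


def _run_fcs(config, seed):
    target = config.get("target_total_molecules", 310_000)
    frac = config.get("nuclear_fraction", 0.08)
    n_rep = config.get("n_replicates", 20)
    seeds = _sub_seeds(seed, n_rep)
    counts = []
    for s in seeds:
        inp = sd.generate_fcs_input(target, nuclear_fraction=frac,
                                    v_conf_fL=config.get("v_conf_fL", 0.59),
                                    v_nuc_fL=config.get("v_nuc_fL", 1420.0),
                                    v_cyt_fL=config.get("v_cyt_fL", 6110.0),
                                    seed=s)
        counts.append(sq.molecules_per_cell(inp))
    counts = np.asarray(counts)
    return {
        "target_total_molecules": target,
        "mean_count": float(counts.mean()),
        "sd_count": float(counts.std(ddof=1)),
        "n_replicates": n_rep,
    }, {"counts": counts}


_RUNNERS = {
    "fig3_cycle_effects": _run_fig3,
    "fig2_phase_response": _run_fig2,
    "fig6_refractory": _run_fig6,
    "fig8_alignment": _run_fig8,
    "fccs_kd": _run_fccs,
    "fcs_counting": _run_fcs,
}


def run_scenario(name: str, config: dict | str | None = None, seed: int = 0,
                 out_dir=None) -> ScenarioReport:
    """Run a named scenario; optionally persist report and intermediates.

    ``config`` may be a dict, a YAML path, or None (packaged default).
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    if config is None:
        config = load_config(_CONFIG_FOR[name])
    elif not isinstance(config, dict):
        config = load_config(config)
    headline, artifacts = _RUNNERS[name](config, seed)
    report = ScenarioReport(scenario=name, seed=seed, config=config,
                            headline=headline)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key in ("untreated", "treated", "traces"):
            if key in artifacts:
                sd.write_traces(artifacts[key], out / f"{name}_{key}")
                report.outputs[key] = str(out / f"{name}_{key}.csv")
        rp = out / f"{name}_report.json"
        rp.write_text(report.to_json())
        report.outputs["report"] = str(rp)
    return report
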