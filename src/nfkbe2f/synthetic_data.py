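"""Seeded synthetic inputs emulating the study's imaging and spectroscopy data.

``generate_population`` builds single-cell fluorescence traces with the
statistical structure the downstream analysis assumes: each cell runs the
``revised`` NF-κB/E2F model on its own cell-cycle clock (E2F synthesis
gated by cycle position), with log-normal cell-to-cell kinetic
heterogeneity, multiplicative measurement noise, FUCCI-like reporter
channels, mitosis events that halve reported intensities, and — for cells
stimulated in the susceptible late-G1/G1-S window — a programmed cycle
lengthening.  Ground truth (realized phase at treatment, realized
durations, kinetic multipliers, applied lengthening) travels in a sidecar,
never in the trace CSV, so the analysis pipeline can be run blind.

``generate_fccs_set`` and ``generate_fcs_input`` produce the spectroscopy
inputs (mass-action-consistent concentration triplets for Kd estimation;
compartment particle numbers that invert the molecule-counting formula).

Everything is deterministic given its seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinetics as kin
from . import cellcycle as cc

__all__ = [
    "CycleEffect",
    "PopulationConfig",
    "CellTrace",
    "FccsTriplet",
    "FcsInput",
    "generate_population",
    "generate_fccs_set",
    "generate_fcs_input",
    "write_traces",
    "read_traces",
]


@dataclass(frozen=True)
class CycleEffect:
    """Programmed TNFα effect on cycle timing.

    Cells stimulated with cycle-clock fraction inside
    [susceptible_lo, susceptible_hi) — late G1 through the G1/S band —
    have the treatment-spanning cycle lengthened by a truncated-normal
    additive delay.  Defaults encode the reported population effects:
    a +1.9 h mean shift, ~2-fold SD inflation, and ~1/3 lengthening of the
    G1/S-treated subset, at the reported group-size regime.
    """

    susceptible_lo: float = 0.22
    susceptible_hi: float = 0.50
    lengthening_mean_h: float = 6.8
    lengthening_sd_h: float = 3.0


@dataclass(frozen=True)
class PopulationConfig:
    n_cells: int = 100
    program: cc.CycleProgram = field(default_factory=cc.CycleProgram)
    treatment_time_h: float = 30.0
    dose_scale: float = 1.0          # 0 => untreated arm
    record_h: float = 50.0
    dt_min: float = 5.0
    heterogeneity_cv: tuple = (("k_ikk_act", 0.1), ("k_tikba_max", 0.1))
    expression_cv: float = 0.15      # log-normal scatter of reporter scale
    noise_sd: float = 0.05           # multiplicative measurement noise
    e2f1_gain: float = 8.0           # peak multiplier on E2F-1 synthesis
    e2f4_gain: float = 5.0           # peak multiplier on E2F-4 synthesis
    cycle_effect: CycleEffect = field(default_factory=CycleEffect)
    variant: str = "revised"
    # imaging-line calibration: partial first translocation and G1/S-band
    # IkBa repression, so the response amplitude is cycle-phase sensitive
    param_overrides: tuple = (("k_complex_deg_ikk", 0.002),
                              ("K_rep_ikba", 12.0),
                              ("kf_nfkb_e2f1", 0.01))
    simulate: bool = True            # False: timing-only traces (no ODE)
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0 or self.dt_min <= 0 or self.noise_sd < 0:
            raise ValueError("invalid population config")
        for _, cv in self.heterogeneity_cv:
            if cv < 0:
                raise ValueError("heterogeneity CVs must be >= 0")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class CellTrace:
    """One cell's sampled channels with event annotations."""

    cell_id: str
    time_min: np.ndarray
    nuc_mean: np.ndarray
    cyt_mean: np.ndarray
    e2f1: np.ndarray
    fucci_red: np.ndarray
    fucci_green: np.ndarray
    mitosis_times_h: list
    treatment_time_min: float
    dose_scale: float = 1.0
    ground_truth: dict | None = None   # synthetic traces only

    @property
    def nc(self) -> np.ndarray:
        return self.nuc_mean / self.cyt_mean


@dataclass(frozen=True)
class FccsTriplet:
    free_a_nM: float
    free_b_nM: float
    complex_nM: float


@dataclass(frozen=True)
class FcsInput:
    n_nuc: float
    n_cyt: float
    v_conf_fL: float = 0.59
    v_nuc_fL: float = 1420.0
    v_cyt_fL: float = 6110.0


# intensity model: reported channel = scale * concentration + background.
# The background keeps measured N:C ratios in the imaging range (rest ~0.3,
# peaks ~2-4) the way cellular autofluorescence does.
_BG_FRACTION = 0.5      # background as a fraction of scale * total RelA
_E2F_BG = 2.0           # E2F reporter background, intensity units


@dataclass
class _CycleSchedule:
    """Realized mitosis schedule with an optional G1/S pause.

    A cell stimulated inside the susceptible window pauses at the S-phase
    entry boundary for ``delay_h`` before resuming its programmed cycle, so
    its mitosis-to-mitosis duration lengthens additively while its phase
    position at treatment is untouched.
    """

    mitoses: list          # shifted mitosis times (h); mitoses[0] < 0
    base_durations: list   # pre-pause cycle durations (h)
    pause_cycle: int | None
    pause_frac: float      # cycle fraction at which the pause is inserted
    delay_h: float

    def position(self, t_h: float) -> tuple[float, float]:
        """(time within programmed cycle, programmed duration) at time t."""
        k = max(int(np.searchsorted(self.mitoses, t_h, side="right") - 1), 0)
        ts = t_h - self.mitoses[k]
        T = self.base_durations[k]
        if k == self.pause_cycle:
            p = self.pause_frac * T
            if ts >= p + self.delay_h:
                ts -= self.delay_h
            elif ts >= p:
                ts = p
        return min(max(ts, 0.0), T * (1.0 - 1e-9)), T


def _realize_cycle(rng, program, record_h, t_treat_h, dose,
                   effect) -> tuple[_CycleSchedule, float]:
    """Mitosis schedule, pause bookkeeping and the phase fraction at
    treatment (on the programmed, pre-pause clock)."""
    mu = np.log(program.t_mean_h**2 /
                np.sqrt(program.t_mean_h**2 + program.t_sd_h**2))
    sig = np.sqrt(np.log(1.0 + (program.t_sd_h / program.t_mean_h) ** 2))
    durations = list(np.exp(rng.normal(mu, sig, size=10)))
    m0 = -float(rng.uniform(0.0, durations[0]))   # asynchronous start
    mitoses = [m0]
    while mitoses[-1] < record_h + 1.0 and len(mitoses) < len(durations):
        mitoses.append(mitoses[-1] + durations[len(mitoses) - 1])
    k = int(np.searchsorted(mitoses, t_treat_h, side="right") - 1)
    phase_frac = (t_treat_h - mitoses[k]) / durations[k]
    pause_cycle, delay = None, 0.0
    if (dose > 0 and effect.susceptible_lo <= phase_frac
            < effect.susceptible_hi):
        raw = rng.normal(effect.lengthening_mean_h, effect.lengthening_sd_h)
        delay = float(max(0.0, raw))
        pause_cycle = k
        for j in range(k + 1, len(mitoses)):
            mitoses[j] += delay
    return _CycleSchedule(mitoses, durations, pause_cycle,
                          program.s_start, delay), phase_frac


def _simulate_segments(model, y0, protocol, seg_edges, grid, rtol, atol):
    """Integrate across segments (mitoses) restarting the drive clock."""
    y = np.empty((len(model.species), len(grid)))
    y_cur = np.asarray(y0, float)
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        mask = (grid >= a) & (grid < b) if b < seg_edges[-1] else (grid >= a)
        pts = np.unique(np.concatenate([[a], grid[mask], [b]]))
        traj = kin.simulate_cell(model, y_cur, protocol, pts,
                                 rtol=rtol, atol=atol)
        sel = np.isin(pts, grid[mask])
        y[:, mask] = traj.y[:, sel]
        y_cur = traj.y[:, -1]
    return y


def _cell_trace(cell_id, cfg, rng) -> CellTrace:
    program = cfg.program
    t_treat_h = cfg.treatment_time_h
    sched, phase_frac = _realize_cycle(
        rng, program, cfg.record_h, t_treat_h, cfg.dose_scale,
        cfg.cycle_effect)
    mitoses = sched.mitoses

    mults = {name: float(np.exp(rng.normal(0.0, cv)))
             for name, cv in cfg.heterogeneity_cv}
    amp_mult = float(np.exp(rng.normal(0.0, cfg.expression_cv)))
    base = kin.default_params(cfg.variant)
    overrides = dict(cfg.param_overrides)
    for k, m in mults.items():
        overrides[k] = overrides.get(k, base[k]) * m
    model = kin.build_model(cfg.variant, overrides)

    def drive1(t_min):
        ts, d = sched.position(t_min / 60.0)
        return cfg.e2f1_gain * cc.e2f_drive(ts, program, d)[0]

    def drive4(t_min):
        ts, d = sched.position(t_min / 60.0)
        return cfg.e2f4_gain * cc.e2f_drive(ts, program, d)[1]

    model = model.with_drive(e2f1=drive1,
                             e2f4=drive4 if cfg.variant == "revised" else None)

    grid = np.arange(0.0, cfg.record_h * 60.0 + 0.5 * cfg.dt_min, cfg.dt_min)
    if cfg.simulate:
        eq = kin.equilibrate(kin.build_model(cfg.variant, overrides),
                             horizon=20000.0, tol=1e-5, rtol=1e-8, atol=1e-10)
        t0_min = mitoses[0] * 60.0
        full_grid = np.unique(np.concatenate([[t0_min], grid]))
        protocol = kin.StimulusProtocol(t_treat_h * 60.0, np.inf,
                                        cfg.dose_scale) \
            if cfg.dose_scale > 0 else kin.NO_STIMULUS
        seg_edges = [t0_min] + [m * 60.0 for m in mitoses
                                if t0_min < m * 60.0 < full_grid[-1]] \
            + [full_grid[-1]]
        y = _simulate_segments(model, eq, protocol, seg_edges, full_grid,
                               rtol=1e-6, atol=1e-8)
        keep = np.isin(full_grid, grid)
        t = full_grid[keep]
        y = y[:, keep]
        ix = model.index
        nuc_conc = sum(y[ix[s]] for s in ("NFkB_n", "NFkB_IkBa_n",
                                          "NFkB_E2F1_n") if s in ix)
        cyt_conc = sum(y[ix[s]] for s in ("NFkB_c", "NFkB_IkBa_c",
                                          "NFkB_IkBa_E2F4_c") if s in ix)
        e2f1_conc = sum(y[ix[s]] for s in ("E2F1_n", "NFkB_E2F1_n")
                        if s in ix)
    else:
        # timing-only mode for duration analyses: flat reporter channels
        t = grid
        nuc_conc = np.zeros_like(t)
        cyt_conc = np.full_like(t, model.params["NFkB_total"])
        e2f1_conc = np.zeros_like(t)

    # reported intensities: per-cell scale, halving at each division
    n_div = np.searchsorted([m for m in mitoses if m > 0], t / 60.0,
                            side="right")
    scale = amp_mult * 0.5 ** n_div
    bg = _BG_FRACTION * model.params["NFkB_total"]
    nuc = scale * (nuc_conc + bg)
    cyt = scale * (cyt_conc + bg)
    e2f = scale * e2f1_conc + _E2F_BG

    # FUCCI-like channels: red declines through the cycle, green rises so
    # they cross at the program's G1/S transition fraction
    f_cross = 0.5 * (program.g1s_start + program.s_start)
    frac = np.empty_like(t)
    for i, tm in enumerate(t):
        ts, d = sched.position(tm / 60.0)
        frac[i] = ts / d
    red = np.clip(1.0 - frac, 0.0, None)
    green = frac * (1.0 - f_cross) / f_cross

    if cfg.noise_sd > 0:
        def noisy(x):
            return np.clip(x * (1.0 + rng.normal(0.0, cfg.noise_sd, x.shape)),
                           0.0, None)
        nuc, cyt, e2f = noisy(nuc), noisy(cyt), noisy(e2f)
        red = np.clip(red + rng.normal(0.0, cfg.noise_sd, red.shape), 0.0, None)
        green = np.clip(green + rng.normal(0.0, cfg.noise_sd, green.shape),
                        0.0, None)

    # ground-truth phase on the programmed (pre-pause) clock
    gt_phase = cc.phase_label(phase_frac * program.t_mean_h, program)
    return CellTrace(
        cell_id=cell_id,
        time_min=t,
        nuc_mean=nuc, cyt_mean=cyt, e2f1=e2f,
        fucci_red=red, fucci_green=green,
        mitosis_times_h=[float(m) for m in mitoses if 0.0 <= m
                         <= cfg.record_h],
        treatment_time_min=t_treat_h * 60.0,
        dose_scale=cfg.dose_scale,
        ground_truth={
            "phase_at_treatment": gt_phase.value,
            "phase_fraction_at_treatment": float(phase_frac),
            "base_durations_h": [float(d) for d in sched.base_durations[:4]],
            "mitosis_times_h": [float(m) for m in mitoses],
            "kinetic_multipliers": mults,
            "applied_lengthening_h": sched.delay_h,
        },
    )


def generate_population(config: PopulationConfig) -> list[CellTrace]:
    """Generate a seeded synthetic cell population (bit-reproducible)."""
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=max(config.n_cells, 1))
    traces = []
    for i in range(config.n_cells):
        rng = np.random.default_rng(seeds[i])
        traces.append(_cell_trace(f"cell{i:04d}", config, rng))
    return traces


def generate_fccs_set(true_kd_nM: float, n: int = 46,
                      abundance_range=(5.0, 200.0), noise_sd: float = 0.10,
                      seed: int = 0) -> list[FccsTriplet]:
    """Concentration triplets satisfying freeA·freeB = Kd·complex pre-noise."""
    if true_kd_nM <= 0 or n < 2:
        raise ValueError("need a positive Kd and n >= 2")
    rng = np.random.default_rng(seed)
    lo, hi = abundance_range
    out = []
    for _ in range(n):
        free_a = float(rng.uniform(lo, hi))
        free_b = float(rng.uniform(lo, hi))
        cplx = free_a * free_b / true_kd_nM
        trip = np.array([free_a, free_b, cplx])
        if noise_sd > 0:
            trip = np.clip(trip * (1.0 + rng.normal(0.0, noise_sd, 3)),
                           0.0, None)
        out.append(FccsTriplet(*map(float, trip)))
    return out


def generate_fcs_input(target_total_molecules: float,
                       nuclear_fraction: float = 0.05,
                       v_conf_fL: float = 0.59, v_nuc_fL: float = 1420.0,
                       v_cyt_fL: float = 6110.0, poisson_noise: bool = True,
                       n_runs: int = 10, seed: int = 0) -> FcsInput:
    """Compartment particle numbers that invert the counting formula.

    Pre-noise, ``molecules_per_cell`` applied to the result returns exactly
    the target.  With noise on, each compartment's particle number is the
    mean of ``n_runs`` Poisson draws (the instrument averages repeated
    runs), which keeps the count unbiased.
    """
    if min(v_conf_fL, v_nuc_fL, v_cyt_fL) <= 0:
        raise ValueError("volumes must be positive")
    if not 0.0 <= nuclear_fraction <= 1.0:
        raise ValueError("nuclear fraction must lie in [0, 1]")
    n_nuc = target_total_molecules * nuclear_fraction / (v_nuc_fL / v_conf_fL)
    n_cyt = (target_total_molecules * (1.0 - nuclear_fraction)
             / (v_cyt_fL / v_conf_fL))
    if poisson_noise and target_total_molecules > 0:
        rng = np.random.default_rng(seed)
        n_nuc = rng.poisson(n_nuc * n_runs) / n_runs
        n_cyt = rng.poisson(n_cyt * n_runs) / n_runs
    return FcsInput(n_nuc=float(n_nuc), n_cyt=float(n_cyt),
                    v_conf_fL=v_conf_fL, v_nuc_fL=v_nuc_fL, v_cyt_fL=v_cyt_fL)


_TRACE_COLUMNS = ["cell_id", "time_min", "nuc_mean", "cyt_mean", "e2f1",
                  "fucci_red", "fucci_green", "mitosis_flag"]


def write_traces(traces, path, config: PopulationConfig | None = None) -> None:
    """Serialize a population to ``<path>.csv`` + ``<path>.json`` sidecar."""
    path = Path(path)
    frames = []
    sidecar = {"traces": {}}
    if config is not None:
        sidecar.update({"seed": config.seed,
                        "config_hash": config.config_hash()})
    for tr in traces:
        mit_min = np.array(tr.mitosis_times_h) * 60.0
        flag = np.zeros(len(tr.time_min), dtype=int)
        for m in mit_min:
            flag[int(np.argmin(np.abs(tr.time_min - m)))] = 1
        frames.append(pd.DataFrame({
            "cell_id": tr.cell_id, "time_min": tr.time_min,
            "nuc_mean": tr.nuc_mean, "cyt_mean": tr.cyt_mean,
            "e2f1": tr.e2f1, "fucci_red": tr.fucci_red,
            "fucci_green": tr.fucci_green, "mitosis_flag": flag,
        }))
        sidecar["traces"][tr.cell_id] = {
            "treatment_time_min": tr.treatment_time_min,
            "dose_scale": tr.dose_scale,
            "mitosis_times_h": list(map(float, tr.mitosis_times_h)),
            "ground_truth": tr.ground_truth,
        }
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=_TRACE_COLUMNS))
    df.to_csv(path.with_suffix(".csv"), index=False, float_format="%.10g")
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_traces(path) -> list[CellTrace]:
    """Load traces written by :func:`write_traces` (or conforming CSVs)."""
    path = Path(path)
    df = pd.read_csv(path.with_suffix(".csv"))
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing required column(s): "
                         f"{', '.join(missing)}")
    side = json.loads(path.with_suffix(".json").read_text()) \
        if path.with_suffix(".json").exists() else {"traces": {}}
    traces = []
    for cid, sub in df.groupby("cell_id", sort=False):
        meta = side["traces"].get(str(cid), {})
        mit = meta.get("mitosis_times_h")
        if mit is None:
            mit = list(sub.loc[sub["mitosis_flag"] == 1, "time_min"] / 60.0)
        traces.append(CellTrace(
            cell_id=str(cid),
            time_min=sub["time_min"].to_numpy(float),
            nuc_mean=sub["nuc_mean"].to_numpy(float),
            cyt_mean=sub["cyt_mean"].to_numpy(float),
            e2f1=sub["e2f1"].to_numpy(float),
            fucci_red=sub["fucci_red"].to_numpy(float),
            fucci_green=sub["fucci_green"].to_numpy(float),
            mitosis_times_h=list(map(float, mit)),
            treatment_time_min=float(meta.get("treatment_time_min", np.nan)),
            dose_scale=float(meta.get("dose_scale", np.nan)),
            ground_truth=meta.get("ground_truth"),
        ))
    return traces
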