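"""Virtual synchronization: cell-cycle phase assignment without arrest.

Two procedures infer each cell's cycle phase at the moment of TNFα
treatment from its own recording instead of chemical synchronization:

* mitosis timing — the interval from the last pre-treatment mitosis to
  treatment, mapped through a :class:`~nfkbe2f.cellcycle.CycleProgram`
  (using either the cell's observed mitosis-to-mitosis duration or the
  program's mean duration);
* E2F-1 peak alignment — cells are registered on the time of their peak
  E2F-1 reporter expression (a late-G1 landmark), and treatment time is
  expressed relative to that peak, with phase bands composed from the
  program's boundaries around the registered peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from . import cellcycle as cc

__all__ = [
    "PhaseAssignment",
    "AlignedPopulation",
    "assign_phase_from_mitosis",
    "align_to_e2f1_peak",
    "group_by_phase",
]


@dataclass
class PhaseAssignment:
    cell_id: str
    method: str                    # mitosis | e2f1_peak | fucci
    phase: cc.Phase | None
    evidence_h: float              # mitosis->treatment or treatment-vs-peak
    boundary_flag: bool = False
    assignable: bool = True
    reason: str = ""


@dataclass
class AlignedPopulation:
    table: pd.DataFrame            # cell_id, rel_time_h, norm_level
    spline: object                 # callable rel_time_h -> E2F-1 level
    n_excluded: int
    peak_phase_frac: float         # cycle fraction assigned to the peak


def assign_phase_from_mitosis(trace, program: cc.CycleProgram,
                              duration: str = "realized",
                              boundary_margin: float = 0.02
                              ) -> PhaseAssignment:
    """Phase at treatment from the last pre-treatment mitosis.

    ``duration='realized'`` maps the mitosis-to-treatment interval through
    the cell's own observed mitosis-to-mitosis duration spanning treatment
    (falling back to the program mean when the next mitosis was not
    recorded); ``duration='mean'`` always uses the program mean.
    Assignments within ``boundary_margin`` (fraction of the duration used)
    of a phase boundary are flagged boundary-adjacent.
    """
    t_treat_h = trace.treatment_time_min / 60.0
    mitoses = [m for m in trace.mitosis_times_h if m <= t_treat_h]
    if not mitoses:
        return PhaseAssignment(trace.cell_id, "mitosis", None, np.nan,
                               assignable=False,
                               reason="no pre-treatment mitosis recorded")
    last = max(mitoses)
    evidence = t_treat_h - last
    if duration == "mean":
        T = program.t_mean_h
    elif duration == "realized":
        after = [m for m in trace.mitosis_times_h if m > t_treat_h]
        T = (min(after) - last) if after else program.t_mean_h
    else:
        raise ValueError("duration must be 'realized' or 'mean'")
    if evidence >= T:
        return PhaseAssignment(trace.cell_id, "mitosis", None, evidence,
                               assignable=False,
                               reason="mitosis-to-treatment exceeds duration")
    phase = cc.phase_label(evidence, program, T)
    frac = evidence / T
    bounds = (program.g1s_start, program.s_start, program.g2_start)
    flag = any(abs(frac - b) < boundary_margin for b in bounds)
    return PhaseAssignment(trace.cell_id, "mitosis", phase, evidence, flag)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    k = np.ones(window) / window
    pad = window // 2
    return np.convolve(np.pad(x, pad, mode="edge"), k, mode="valid")[:len(x)]


def align_to_e2f1_peak(traces, program: cc.CycleProgram | None = None,
                       smooth_window: int = 5,
                       spline_lam: float | None = None) -> AlignedPopulation:
    """Register cells on their E2F-1 reporter maximum.

    Traces whose (smoothed) E2F-1 channel peaks at either recording
    boundary are excluded (no interior maximum) and counted.  Returns
    per-cell treatment time relative to the peak (h; negative = before),
    the peak-normalized E2F-1 level at treatment, and a cubic smoothing
    spline of level against relative time across the pooled population.
    The registered peak is placed at the midpoint of the program's G1/S
    band for phase banding.
    """
    program = program or cc.CycleProgram()
    rows = []
    n_excluded = 0
    for tr in traces:
        e = _smooth(np.asarray(tr.e2f1, float), smooth_window)
        t = np.asarray(tr.time_min, float)
        # the recording of interest is the treatment-spanning cycle: restrict
        # the peak search to it when mitosis annotations are available
        lo, hi = 0, len(e) - 1
        mit = sorted(getattr(tr, "mitosis_times_h", []) or [])
        t_treat_h = tr.treatment_time_min / 60.0
        before = [m for m in mit if m <= t_treat_h]
        after = [m for m in mit if m > t_treat_h]
        if before:
            lo = int(np.searchsorted(t, before[-1] * 60.0))
        if after:
            hi = int(np.searchsorted(t, after[0] * 60.0)) - 1
        if hi - lo < 3:
            n_excluded += 1
            continue
        i = lo + int(np.argmax(e[lo:hi + 1]))  # ties -> earliest time
        if i == lo or i == hi:
            n_excluded += 1
            continue
        t_peak = tr.time_min[i]
        level = float(np.interp(tr.treatment_time_min, tr.time_min, e)
                      / e[i])
        rows.append({"cell_id": tr.cell_id,
                     "rel_time_h": (tr.treatment_time_min - t_peak) / 60.0,
                     "norm_level": min(level, 1.0)})
    table = pd.DataFrame(rows, columns=["cell_id", "rel_time_h", "norm_level"])
    if len(table) == 0:
        return AlignedPopulation(table, None, n_excluded,
                                 0.5 * (program.g1s_start + program.s_start))
    order = np.argsort(table["rel_time_h"].to_numpy())
    x = table["rel_time_h"].to_numpy()[order]
    y = table["norm_level"].to_numpy()[order]
    # strictly increasing x for the spline; average duplicated times
    ux, inv = np.unique(np.round(x, 9), return_inverse=True)
    uy = np.bincount(inv, weights=y) / np.bincount(inv)
    spline = (make_smoothing_spline(ux, uy, lam=spline_lam)
              if len(ux) >= 4 else None)
    return AlignedPopulation(table, spline, n_excluded,
                             0.5 * (program.g1s_start + program.s_start))


def phase_from_relative_time(rel_time_h: float, program: cc.CycleProgram,
                             peak_phase_frac: float | None = None
                             ) -> cc.Phase:
    """Phase band for a treatment time relative to the E2F-1 peak."""
    peak = peak_phase_frac if peak_phase_frac is not None else \
        0.5 * (program.g1s_start + program.s_start)
    frac = (peak + rel_time_h / program.t_mean_h) % 1.0
    return cc.phase_label(frac * program.t_mean_h, program)


def assign_phase_from_e2f1(traces, program: cc.CycleProgram | None = None,
                           **kwargs) -> list[PhaseAssignment]:
    """Per-cell assignments via E2F-1 peak alignment."""
    program = program or cc.CycleProgram()
    aligned = align_to_e2f1_peak(traces, program, **kwargs)
    by_id = {r.cell_id: r for r in aligned.table.itertuples()}
    out = []
    for tr in traces:
        row = by_id.get(tr.cell_id)
        if row is None:
            out.append(PhaseAssignment(tr.cell_id, "e2f1_peak", None, np.nan,
                                       assignable=False,
                                       reason="no interior E2F-1 maximum"))
            continue
        frac = (aligned.peak_phase_frac
                + row.rel_time_h / program.t_mean_h) % 1.0
        phase = cc.phase_label(frac * program.t_mean_h, program)
        bounds = (program.g1s_start, program.s_start, program.g2_start)
        flag = any(abs(frac - b) < 0.02 for b in bounds)
        out.append(PhaseAssignment(tr.cell_id, "e2f1_peak", phase,
                                   row.rel_time_h, flag))
    return out


def group_by_phase(features: pd.DataFrame, assignments,
                   value: str = "norm_first_peak_amplitude",
                   include_boundary: bool = False) -> dict:
    """Partition per-cell feature values by assigned phase.

    Returns ``{"groups": {phase: np.ndarray}, "ns": {...},
    "excluded": {...}}``.  Unassignable and (by default)
    boundary-adjacent cells are excluded with counts; censored feature
    values are dropped per group with counts.  Cell ids present in only
    one input are reported as mismatched.
    """
    feat_ids = set(features["cell_id"])
    assign_ids = {a.cell_id for a in assignments}
    excluded = {
        "unassignable": 0, "boundary": 0, "censored": 0,
        "id_mismatch": sorted((feat_ids ^ assign_ids)),
    }
    by_id = features.set_index("cell_id")
    groups: dict = {}
    for a in assignments:
        if a.cell_id not in by_id.index:
            continue
        if not a.assignable:
            excluded["unassignable"] += 1
            continue
        if a.boundary_flag and not include_boundary:
            excluded["boundary"] += 1
            continue
        v = by_id.loc[a.cell_id, value]
        if not np.isfinite(v):
            excluded["censored"] += 1
            continue
        groups.setdefault(a.phase.value, []).append(float(v))
    groups = {k: np.asarray(v) for k, v in groups.items()}
    return {"groups": groups, "ns": {k: len(v) for k, v in groups.items()},
            "excluded": excluded}
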