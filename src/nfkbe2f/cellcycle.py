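"""Cell-cycle programs: phase boundaries, E2F drive profiles, FUCCI crossing.

A :class:`CycleProgram` describes a population's cycle timing: a mean
mitosis-to-mitosis duration T (~20 h in HeLa) with log-normal dispersion,
phase-boundary fractions partitioning [0, T) into G1 / G1-S / S / G2, and
smooth unimodal synthesis-drive profiles for E2F-1 (peaking at the G1/S
transition) and E2F-4 (delayed into S-phase).  The G1/S transition of a
FUCCI-labelled cell is detected as the crossing point of the red (APC
substrate) and green (SCF substrate) reporter channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = ["Phase", "CycleProgram", "phase_label", "e2f_drive", "fucci_crossing"]


class Phase(str, Enum):
    G1 = "G1"
    G1S = "G1/S"
    S = "S"
    G2 = "G2"


PHASE_ORDER = (Phase.G1, Phase.G1S, Phase.S, Phase.G2)


@dataclass(frozen=True)
class CycleProgram:
    """Population cell-cycle timing and E2F drive profiles.

    Boundary fractions partition the realized duration: G1 on
    [0, g1s_start), G1/S on [g1s_start, s_start), S on [s_start, g2_start),
    G2 on [g2_start, 1).  Defaults give G1 ~8 h, a ~2 h G1/S window, S ~7 h
    and G2 ~3 h for T = 20 h, consistent with a double-thymidine release
    landing at the G1/S transition and mid-S four hours later.
    """

    t_mean_h: float = 20.0
    t_sd_h: float = 1.9
    g1s_start: float = 0.40
    s_start: float = 0.50
    g2_start: float = 0.85
    # E2F-1 drive: log-normal-shaped bump in time, peak within the G1/S band
    e2f1_peak_frac: float = 0.45
    e2f1_width: float = 0.30       # log-time SD of the bump
    e2f1_amplitude: float = 1.0    # synthesis-rate multiplier at the peak
    e2f4_lag_frac: float = 0.22    # E2F-4 peak delay, fraction of T
    e2f4_width: float = 0.16       # narrower so the profile clears by t = T

    def __post_init__(self):
        if not (0.0 < self.g1s_start < self.s_start < self.g2_start < 1.0):
            raise ValueError("phase boundaries must satisfy 0 < g1s < s < g2 < 1")
        if not (self.g1s_start <= self.e2f1_peak_frac <= self.s_start):
            raise ValueError("E2F-1 peak must lie within the G1/S band")
        if self.e2f4_lag_frac <= 0:
            raise ValueError("E2F-4 profile must peak strictly after E2F-1")
        if self.t_mean_h <= 0 or self.t_sd_h < 0:
            raise ValueError("invalid duration parameters")


def phase_label(t_since_mitosis_h: float, program: CycleProgram,
                duration_h: float | None = None) -> Phase:
    """Deterministic piecewise-constant phase at a time since mitosis.

    ``duration_h`` is the cell's realized cycle duration (defaults to the
    program mean).  Raises ``ValueError`` outside [0, duration).
    """
    T = program.t_mean_h if duration_h is None else duration_h
    if not 0.0 <= t_since_mitosis_h < T:
        raise ValueError(
            f"time since mitosis {t_since_mitosis_h} h outside [0, {T} h)")
    f = t_since_mitosis_h / T
    if f < program.g1s_start:
        return Phase.G1
    if f < program.s_start:
        return Phase.G1S
    if f < program.g2_start:
        return Phase.S
    return Phase.G2


def _bump(f: float | np.ndarray, peak_frac: float, width: float,
          amplitude: float) -> float | np.ndarray:
    """Log-normal-shaped unimodal profile of cycle fraction, max = amplitude."""
    f = np.asarray(f, float)
    out = np.zeros_like(f)
    pos = f > 0
    out[pos] = amplitude * np.exp(-np.log(f[pos] / peak_frac) ** 2
                                  / (2.0 * width ** 2))
    return out if out.ndim else float(out)


def e2f_drive(t_since_mitosis_h: float | np.ndarray, program: CycleProgram,
              duration_h: float | None = None) -> tuple:
    """(E2F-1, E2F-4) synthesis-rate multipliers at a time since mitosis.

    E2F-1 peaks in late G1 at the configured amplitude; the E2F-4 drive is
    the same shape shifted into S-phase by the configured lag.  Both vanish
    at mitosis (t = 0) and have decayed to < 5 % of peak by t = T.
    """
    T = program.t_mean_h if duration_h is None else duration_h
    f = np.asarray(t_since_mitosis_h, float) / T
    if np.any(f < 0) or np.any(f >= 1.0 + 1e-9):
        raise ValueError("time since mitosis outside [0, duration)")
    e2f1 = _bump(f, program.e2f1_peak_frac, program.e2f1_width,
                 program.e2f1_amplitude)
    e2f4 = _bump(f, program.e2f1_peak_frac + program.e2f4_lag_frac,
                 program.e2f4_width, program.e2f1_amplitude)
    return e2f1, e2f4


def fucci_crossing(t: np.ndarray, red: np.ndarray, green: np.ndarray,
                   smooth_window: int = 1) -> float | None:
    """G1/S transition time from FUCCI channels.

    Returns the earliest time at which (red − green) changes sign from
    positive to negative, located by linear interpolation between the
    bracketing samples (a tie exactly at a sample resolves to that sample's
    time); ``None`` when no such crossing exists.  An optional centred
    moving-average window smooths both channels first.  The result is
    invariant under common positive rescaling of the two channels.
    """
    t = np.asarray(t, float)
    red = np.asarray(red, float)
    green = np.asarray(green, float)
    if not (len(t) == len(red) == len(green)):
        raise ValueError("time, red and green series must share a grid")
    if np.allclose(red, green):
        raise ValueError("degenerate input: red and green channels coincide")
    if smooth_window > 1:
        k = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        red = np.convolve(np.pad(red, pad, mode="edge"), k, mode="valid")[:len(t)]
        green = np.convolve(np.pad(green, pad, mode="edge"), k, mode="valid")[:len(t)]
    d = red - green
    for i in range(1, len(d)):
        if d[i - 1] > 0 and d[i] <= 0:
            if d[i] == 0:
                return float(t[i])
            return float(t[i - 1] + d[i - 1] * (t[i] - t[i - 1])
                         / (d[i - 1] - d[i]))
    return None
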