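"""Per-cell response descriptors extracted from N:C ratio and E2F channels.

The quantities mirror what is reported for single-cell NF-κB imaging:
the first nuclear-translocation amplitude normalized to the N:C ratio at
the moment of treatment, peak times, the peak1:peak2 interval, the
refractory delay (treatment to second peak), and half-times of nuclear
occupancy decline and E2F reporter decay.  All censoring is explicit —
a quantity that cannot be measured is NaN with its flag set, never
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "TraceFeatures",
    "detect_peaks",
    "first_response",
    "refractory_delay",
    "half_times",
    "cycle_durations",
    "extract_features",
    "features_table",
]

#: default peak prominence in normalized N:C units and minimum separation
DEFAULT_PROMINENCE = 0.2
DEFAULT_SEPARATION_MIN = 40.0


@dataclass
class TraceFeatures:
    cell_id: str
    baseline_nc: float = np.nan
    norm_first_peak_amplitude: float = np.nan
    time_to_first_peak_min: float = np.nan
    peak_times_min: list = field(default_factory=list)
    peak_amplitudes: list = field(default_factory=list)
    peak1_peak2_interval_min: float = np.nan
    refractory_delay_min: float = np.nan
    t_half_occupancy_min: float = np.nan
    t_half_e2f_min: float = np.nan
    censored_first_peak: bool = False
    censored_refractory: bool = False
    censored_occupancy: bool = False
    censored_e2f: bool = False


def detect_peaks(t: np.ndarray, series: np.ndarray,
                 min_prominence: float = DEFAULT_PROMINENCE,
                 min_separation: float = DEFAULT_SEPARATION_MIN
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima with the given prominence and pairwise time separation.

    Returns (peak times, peak values), time-ordered; empty arrays when the
    series has no qualifying peak.
    """
    t = np.asarray(t, float)
    series = np.asarray(series, float)
    if len(series) < 3:
        raise ValueError("series must have at least 3 samples")
    dt = np.median(np.diff(t))
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = find_peaks(series, prominence=min_prominence, distance=distance)
    return t[idx], series[idx]


def first_response(t: np.ndarray, nc: np.ndarray, t_treat: float,
                   window_min: float = 120.0) -> tuple[float, float]:
    """Normalized first-peak amplitude and time-to-peak after treatment.

    Amplitude = max N:C within (t_treat, t_treat + window] divided by the
    N:C value at treatment; a flat or falling response gives amplitude 1.0
    with the time-to-peak censored (NaN).  Raises on a zero N:C baseline.
    """
    if window_min <= 0:
        raise ValueError("window must be positive")
    t = np.asarray(t, float)
    nc = np.asarray(nc, float)
    if not (t[0] <= t_treat <= t[-1]):
        raise ValueError("treatment time outside the trace grid")
    base = float(np.interp(t_treat, t, nc))
    if base == 0:
        raise ValueError("degenerate trace: N:C at treatment is zero")
    mask = (t > t_treat) & (t <= t_treat + window_min)
    if not mask.any():
        return 1.0, np.nan
    seg = nc[mask] / base
    amp = float(seg.max())
    if amp <= 1.0:
        return 1.0, np.nan
    return amp, float(t[mask][int(np.argmax(seg))] - t_treat)


def refractory_delay(t: np.ndarray, nc: np.ndarray, t_treat: float,
                     min_prominence: float = DEFAULT_PROMINENCE,
                     min_separation: float = DEFAULT_SEPARATION_MIN) -> float:
    """Time from treatment to the second detected post-treatment peak.

    NaN (censored) when fewer than two peaks are detected after treatment.
    """
    t = np.asarray(t, float)
    nc = np.asarray(nc, float)
    mask = t >= t_treat
    pt, _ = detect_peaks(t[mask], nc[mask], min_prominence, min_separation)
    if len(pt) < 2:
        return np.nan
    return float(pt[1] - t_treat)


def half_times(t: np.ndarray, nc: np.ndarray,
               e2f: np.ndarray | None = None,
               plateau_fraction: float = 0.1) -> tuple[float, float]:
    """(T½ nuclear occupancy, T½ E2F decay), NaN where censored.

    Occupancy T½: time for N:C to fall halfway from its initial value to
    its plateau (median of the last ``plateau_fraction`` of samples),
    located by linear interpolation.  E2F T½: time for the channel to fall
    to half its initial value.
    """
    t = np.asarray(t, float)
    nc = np.asarray(nc, float)
    n_tail = max(1, int(plateau_fraction * len(nc)))
    plateau = float(np.median(nc[-n_tail:]))
    t_occ = np.nan
    if nc[0] > plateau:
        half = plateau + 0.5 * (nc[0] - plateau)
        t_occ = _first_downcross(t, nc, half)
    t_e2f = np.nan
    if e2f is not None:
        e2f = np.asarray(e2f, float)
        if e2f[0] > 0:
            t_e2f = _first_downcross(t, e2f, 0.5 * e2f[0])
    return t_occ, t_e2f


def _first_downcross(t: np.ndarray, y: np.ndarray, level: float) -> float:
    below = np.nonzero(y <= level)[0]
    if len(below) == 0:
        return np.nan
    j = int(below[0])
    if j == 0 or y[j - 1] == y[j]:
        return float(t[j])
    return float(t[j - 1] + (y[j - 1] - level) * (t[j] - t[j - 1])
                 / (y[j - 1] - y[j]))


def cycle_durations(traces) -> tuple[pd.DataFrame, int]:
    """Mitosis-to-mitosis durations (h) per cell.

    Accepts any iterable of objects with ``cell_id`` and ``mitosis_times_h``
    attributes.  Cells with fewer than two recorded mitoses are excluded;
    the exclusion count is returned alongside the table.
    """
    rows, excluded = [], 0
    for tr in traces:
        m = np.asarray(tr.mitosis_times_h, float)
        if len(m) < 2:
            excluded += 1
            continue
        for a, b in zip(m[:-1], m[1:]):
            rows.append({"cell_id": tr.cell_id, "duration_h": float(b - a)})
    return pd.DataFrame(rows, columns=["cell_id", "duration_h"]), excluded


def extract_features(trace, window_min: float = 120.0,
                     min_prominence: float = DEFAULT_PROMINENCE,
                     min_separation: float = DEFAULT_SEPARATION_MIN
                     ) -> TraceFeatures:
    """Full descriptor set for one cell trace.

    ``trace`` needs ``cell_id``, ``time_min``, ``nc`` (ratio series),
    ``treatment_time_min`` and optionally ``e2f1`` attributes.
    """
    t = np.asarray(trace.time_min, float)
    nc = np.asarray(trace.nc, float)
    t_treat = float(trace.treatment_time_min)
    f = TraceFeatures(cell_id=trace.cell_id)
    f.baseline_nc = float(np.interp(t_treat, t, nc))

    amp, ttp = first_response(t, nc, t_treat, window_min)
    f.norm_first_peak_amplitude = amp
    f.time_to_first_peak_min = ttp
    f.censored_first_peak = not np.isfinite(ttp)

    mask = t >= t_treat
    norm = nc[mask] / f.baseline_nc if f.baseline_nc > 0 else nc[mask]
    pt, pv = detect_peaks(t[mask], norm, min_prominence, min_separation)
    f.peak_times_min = [float(x - t_treat) for x in pt]
    f.peak_amplitudes = [float(v) for v in pv]
    if len(pt) >= 2:
        f.peak1_peak2_interval_min = float(pt[1] - pt[0])
        f.refractory_delay_min = float(pt[1] - t_treat)
    else:
        f.censored_refractory = True

    e2f = getattr(trace, "e2f1", None)
    t_occ, t_e2f = half_times(t[mask] - t_treat, nc[mask],
                              None if e2f is None else np.asarray(e2f)[mask])
    f.t_half_occupancy_min = t_occ
    f.t_half_e2f_min = t_e2f
    f.censored_occupancy = not np.isfinite(t_occ)
    f.censored_e2f = not np.isfinite(t_e2f)
    return f


def features_table(traces, **kwargs) -> pd.DataFrame:
    """One row of descriptors per cell (list fields serialized as counts)."""
    rows = []
    for tr in traces:
        f = extract_features(tr, **kwargs)
        rows.append({
            "cell_id": f.cell_id,
            "baseline_nc": f.baseline_nc,
            "norm_first_peak_amplitude": f.norm_first_peak_amplitude,
            "time_to_first_peak_min": f.time_to_first_peak_min,
            "n_peaks": len(f.peak_times_min),
            "peak1_peak2_interval_min": f.peak1_peak2_interval_min,
            "refractory_delay_min": f.refractory_delay_min,
            "t_half_occupancy_min": f.t_half_occupancy_min,
            "t_half_e2f_min": f.t_half_e2f_min,
            "censored_first_peak": f.censored_first_peak,
            "censored_refractory": f.censored_refractory,
            "censored_occupancy": f.censored_occupancy,
            "censored_e2f": f.censored_e2f,
        })
    return pd.DataFrame(rows)
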