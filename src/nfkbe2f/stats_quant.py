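"""Group statistics and spectroscopy quantification.

Implements the statistical toolkit used on the single-cell feature tables
(Kruskal–Wallis with Dunn's pairwise post-hoc z tests, Levene's test,
bootstrap effect summaries of cycle durations) and the FCS/FCCS
quantifications: whole-cell molecule counts from confocal particle
numbers, and the dissociation constant as the Theil–Sen slope of
free-A·free-B against complex concentration.

The Theil–Sen estimator (median of all pairwise slopes, confidence
interval from the order statistics of those slopes) and Dunn's test are
implemented here directly; both are cross-checked against independent
oracles in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "KdEstimate",
    "kruskal_dunn",
    "levene_test",
    "cycle_effect_summary",
    "theil_sen_slope",
    "estimate_kd",
    "molecules_per_cell",
]


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    group_ns: list
    alpha: float = 0.05
    pairwise: pd.DataFrame | None = None   # per-pair z and adjusted p

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class KdEstimate:
    kd_nM: float
    ci_low_nM: float
    ci_high_nM: float
    n: int


def _check_groups(groups):
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ValueError(f"group {i} has n={len(g)} < 2")
    return groups


def kruskal_dunn(groups, alpha: float = 0.05, labels=None,
                 adjust: str = "bonferroni") -> StatResult:
    """Kruskal–Wallis H (tie-corrected) with Dunn's pairwise post-hoc tests.

    Dunn's test compares mean ranks of each pair on the pooled ranking,

        z_ij = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − T) (1/n_i + 1/n_j) ),

    with tie correction T = Σ(t³−t)/(12(N−1)), two-sided p-values adjusted
    across the tested pairs (Bonferroni by default, ``adjust='holm'``
    optional).  Identical groups give H = 0 and no significant pair.
    """
    groups = _check_groups(groups)
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h_stat, p = 0.0, 1.0
    else:
        h_stat, p = sps.kruskal(*groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term

    rows = []
    pairs = list(combinations(range(len(groups)), 2))
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "z": z, "p_raw": p_raw})
    table = pd.DataFrame(rows)
    if adjust == "bonferroni":
        table["p_adj"] = np.minimum(table["p_raw"] * len(pairs), 1.0)
    elif adjust == "holm":
        order = np.argsort(table["p_raw"].to_numpy())
        m = len(pairs)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p_raw"].iloc[idx])
            adj[idx] = min(running, 1.0)
        table["p_adj"] = adj
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    table["significant"] = table["p_adj"] < alpha
    return StatResult("Kruskal-Wallis + Dunn", float(h_stat), float(p),
                      sizes, alpha, table)


def levene_test(groups, alpha: float = 0.05, center: str = "mean") -> StatResult:
    """Levene's W for equality of variances (mean-centred by default;
    ``center='median'`` gives the Brown–Forsythe variant)."""
    groups = _check_groups(groups)
    w, p = sps.levene(*groups, center=center)
    return StatResult(f"Levene ({center})", float(w), float(p),
                      [len(g) for g in groups], alpha)


def theil_sen_slope(x, y, alpha: float = 0.05) -> tuple[float, float, float]:
    """Theil–Sen slope: median of all pairwise slopes, with a rank-based
    confidence interval from the order statistics of those slopes.

    Pairs with equal x are skipped.  Returns (slope, ci_low, ci_high).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 (x, y) pairs")
    slopes = []
    for i, j in combinations(range(len(x)), 2):
        dx = x[j] - x[i]
        if dx != 0:
            slopes.append((y[j] - y[i]) / dx)
    if not slopes:
        raise ValueError("all x values are equal; slope undefined")
    slopes = np.sort(slopes)
    slope = float(np.median(slopes))
    # normal-approximation rank CI on the pairwise-slope order statistics
    n = len(x)
    n_s = len(slopes)
    var = n * (n - 1) * (2 * n + 5) / 18.0
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    m = z * np.sqrt(var)
    lo = int(np.floor((n_s - m) / 2.0))
    hi = int(np.ceil((n_s + m) / 2.0))
    lo = max(lo, 0)
    hi = min(hi, n_s - 1)
    return slope, float(slopes[lo]), float(slopes[hi])


def estimate_kd(triplets) -> KdEstimate:
    """Dissociation constant from free/complex concentration triplets.

    At equilibrium [A][B] = Kd·[AB], so regressing y = freeA·freeB on
    x = complex concentration gives Kd as the slope; the robust Theil–Sen
    estimator makes the fit insensitive to outlying measurements.
    """
    free_ab = np.array([t.free_a_nM * t.free_b_nM for t in triplets])
    cplx = np.array([t.complex_nM for t in triplets])
    if len(cplx) < 2:
        raise ValueError("need at least two triplets")
    slope, lo, hi = theil_sen_slope(cplx, free_ab)
    return KdEstimate(kd_nM=slope, ci_low_nM=lo, ci_high_nM=hi, n=len(cplx))


def molecules_per_cell(fcs) -> float:
    """Whole-cell molecule count from confocal particle numbers.

    count = n_nuc·(V_nuc/V_conf) + n_cyt·(V_cyt/V_conf): the mean particle
    number in the confocal volume scaled to each compartment's volume.
    """
    if fcs.v_conf_fL <= 0 or fcs.v_nuc_fL <= 0 or fcs.v_cyt_fL <= 0:
        raise ValueError("volumes must be positive")
    if fcs.n_nuc < 0 or fcs.n_cyt < 0:
        raise ValueError("particle numbers must be non-negative")
    return (fcs.n_nuc * fcs.v_nuc_fL / fcs.v_conf_fL
            + fcs.n_cyt * fcs.v_cyt_fL / fcs.v_conf_fL)


def _boot_ci(rng, stat, *samples, n_boot=2000, alpha=0.05):
    vals = np.empty(n_boot)
    for b in range(n_boot):
        res = [s[rng.integers(0, len(s), len(s))] for s in samples]
        vals[b] = stat(*res)
    return (float(np.quantile(vals, alpha / 2)),
            float(np.quantile(vals, 1 - alpha / 2)))


def cycle_effect_summary(untreated_h, treated_h, treated_phases=None,
                         n_boot: int = 2000, seed: int = 0,
                         alpha: float = 0.05) -> dict:
    """TNFα effect on cycle duration: mean shift, SD inflation, phase subsets.

    Returns a dict with the treated−untreated difference of mean durations
    (h) and its bootstrap CI, the fractional difference, the SD ratio
    (treated/untreated) with CI and a Levene test, and — when per-cell
    phase labels accompany the treated durations — the same summaries for
    the G1/S- and S-treated subsets.  Bootstrap is seeded and uses
    ``n_boot`` resamples.
    """
    u = np.asarray(untreated_h, float)
    tr = np.asarray(treated_h, float)
    if len(u) < 2 or len(tr) < 2:
        raise ValueError("need >= 2 cells per compared group")
    rng = np.random.default_rng(seed)
    out = {
        "n_untreated": len(u), "n_treated": len(tr),
        "mean_untreated_h": float(u.mean()), "mean_treated_h": float(tr.mean()),
        "mean_difference_h": float(tr.mean() - u.mean()),
        "fractional_difference": float((tr.mean() - u.mean()) / u.mean()),
        "sd_untreated_h": float(u.std(ddof=1)), "sd_treated_h": float(tr.std(ddof=1)),
        "sd_ratio": float(tr.std(ddof=1) / u.std(ddof=1)),
    }
    out["mean_difference_ci_h"] = _boot_ci(
        rng, lambda a, b: b.mean() - a.mean(), u, tr, n_boot=n_boot, alpha=alpha)
    out["sd_ratio_ci"] = _boot_ci(
        rng, lambda a, b: b.std(ddof=1) / a.std(ddof=1), u, tr,
        n_boot=n_boot, alpha=alpha)
    lev = levene_test([u, tr], alpha=alpha)
    out["levene_w"] = lev.statistic
    out["levene_p"] = lev.p_value
    if treated_phases is not None:
        phases = np.asarray([str(p) for p in treated_phases])
        if len(phases) != len(tr):
            raise ValueError("phase labels must match treated durations")
        for name, key in (("G1/S", "g1s"), ("S", "s")):
            sub = tr[phases == name]
            if len(sub) < 2:
                out[f"{key}_n"] = len(sub)
                continue
            out[f"{key}_n"] = len(sub)
            out[f"{key}_mean_h"] = float(sub.mean())
            out[f"{key}_mean_difference_h"] = float(sub.mean() - u.mean())
            out[f"{key}_fractional_lengthening"] = float(
                (sub.mean() - u.mean()) / u.mean())
            out[f"{key}_fractional_ci"] = _boot_ci(
                rng, lambda a, b: (b.mean() - a.mean()) / a.mean(), u, sub,
                n_boot=n_boot, alpha=alpha)
    return out
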