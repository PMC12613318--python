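"""Observables and comparison statistics.

Yield (%SA) is the percentage of realizations assembling within the
horizon.  First-assembly-time distributions are summarized by Scott-rule
histograms and Gaussian KDE curves; agreement between a model and the
ground truth is quantified by the Pearson correlation of the KDE curves and
by the similarity

    S_EMD = 1 - (1/L) * integral_0^L |F_a(t) - F_b(t)| dt,

the interval-normalized 1-Wasserstein (earth mover's) distance between the
empirical CDFs, integrated up to L = the larger 99th percentile of either
sample.  Protocol sweeps are scored by the cost C = S~A - w * T~Drive with
normalized yield and drive time (w = 0.5 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "DistributionSummary",
    "yield_pct",
    "kde_curve",
    "pearson_r_curves",
    "s_emd",
    "cost",
    "protocol_report",
    "summarize_distribution",
    "shared_grid",
]


def yield_pct(flags) -> float:
    """Percentage of realizations with assembly flag 1."""
    flags = np.asarray(flags)
    if flags.size == 0:
        raise ValueError("need at least one flag")
    return 100.0 * float(np.mean(flags != 0))


def shared_grid(
    samples_a: np.ndarray, samples_b: np.ndarray, n: int = 512
) -> np.ndarray:
    """Evaluation grid spanning both sample ranges, padded by three Scott
    bandwidths of the wider sample."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    bw = max(_scott_bw(a), _scott_bw(b))
    lo = min(a.min(), b.min()) - 3 * bw
    hi = max(a.max(), b.max()) + 3 * bw
    return np.linspace(lo, hi, n)


def _scott_bw(x: np.ndarray) -> float:
    s = x.std(ddof=1) if len(x) > 1 else 0.0
    return s * len(x) ** (-1 / 5) if s > 0 else 0.0


def kde_curve(samples, grid) -> np.ndarray:
    """Gaussian KDE (Scott bandwidth) evaluated on the grid; a small
    bandwidth floor is applied (with a warning) when the samples are
    degenerate."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if x.std(ddof=1) == 0:
        warnings.warn("degenerate samples; bandwidth floor applied",
                      stacklevel=2)
        span = np.ptp(np.asarray(grid, dtype=float))
        bw = max(span * 1e-3, 1e-12)
        g = np.asarray(grid, dtype=float)
        return np.exp(-0.5 * ((g - x[0]) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
    return gaussian_kde(x, bw_method="scott")(np.asarray(grid, dtype=float))


def pearson_r_curves(curve_a, curve_b) -> float:
    """Pearson correlation between two curves sampled on a shared grid."""
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("curves must share a grid of length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance curve: Pearson R undefined")
    return float(np.corrcoef(a, b)[0, 1])


def s_emd(samples_a, samples_b) -> float:
    """Similarity in [0, 1]: one minus the area between the two empirical
    CDFs over [0, max(p99_a, p99_b)], normalized by the interval length.
    The area is computed exactly from the piecewise-constant CDFs."""
    a = np.sort(np.asarray(samples_a, dtype=float))
    b = np.sort(np.asarray(samples_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    upper = max(np.quantile(a, 0.99), np.quantile(b, 0.99))
    if upper <= 0:
        warnings.warn("degenerate integration interval; S_EMD = 1 by "
                      "convention", stacklevel=2)
        return 1.0
    # breakpoints of |F_a - F_b| within [0, upper]
    pts = np.unique(np.concatenate(([0.0], a, b, [upper])))
    pts = pts[(pts >= 0.0) & (pts <= upper)]
    Fa = np.searchsorted(a, pts, side="right") / len(a)
    Fb = np.searchsorted(b, pts, side="right") / len(b)
    widths = np.diff(pts)
    area = float(np.sum(np.abs(Fa[:-1] - Fb[:-1]) * widths))
    return 1.0 - area / float(upper)


def cost(yield_norm: float, drive_norm: float, weight: float = 0.5) -> float:
    """Protocol cost C = S~A - weight * T~Drive; both inputs normalized to
    [0, 1].  The weight (default 0.5) encodes how much drive expenditure
    detracts from yield."""
    if not (0 <= yield_norm <= 1 and 0 <= drive_norm <= 1):
        raise ValueError("normalized inputs must lie in [0, 1]")
    return float(yield_norm - weight * drive_norm)


@dataclass
class DistributionSummary:
    """First-assembly-time distribution summary: Scott-rule density
    histogram, Gaussian KDE curve, and quartile/tail percentiles."""

    samples: np.ndarray
    hist_edges: np.ndarray
    hist_density: np.ndarray
    grid: np.ndarray
    kde: np.ndarray
    percentiles: dict = field(default_factory=dict)


def summarize_distribution(
    samples, grid: np.ndarray | None = None
) -> DistributionSummary:
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    width = 3.49 * x.std(ddof=1) / len(x) ** (1 / 3)
    if width > 0:
        edges = np.arange(x.min(), x.max() + width, width)
        if len(edges) < 2:
            edges = np.array([x.min(), x.max() + width])
    else:
        edges = np.array([x.min() - 0.5, x.max() + 0.5])
    dens, edges = np.histogram(x, bins=edges, density=True)
    if grid is None:
        grid = shared_grid(x, x)
    return DistributionSummary(
        samples=x,
        hist_edges=edges,
        hist_density=dens,
        grid=np.asarray(grid, dtype=float),
        kde=kde_curve(x, grid),
        percentiles={
            p: float(np.percentile(x, p)) for p in (25, 50, 75, 99)
        },
    )


def protocol_report(
    tau_grid,
    msm_results: dict,
    kmc_results: dict,
    weight: float = 0.5,
    maximize: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Score a shock-duration sweep for both sources.

    ``msm_results`` / ``kmc_results`` map tau -> (flags, T_FAS samples,
    T_Drive seconds).  Yields and drive times are normalized by the maximum
    observed across both sources; per tau the report carries yield, drive
    time, Pearson R and S_EMD between the sources' T_FAS distributions, and
    the cost C.  Returns (table, {source: optimal tau}) with the optimum
    taken at maximal C by default (set ``maximize=False`` for cost
    curves plotted with the opposite orientation)."""
    tau_grid = list(tau_grid)
    if len(tau_grid) < 2:
        raise ValueError("need at least two tau values")
    sources = {"msm": msm_results, "kmc": kmc_results}
    present = {k: v for k, v in sources.items() if v}
    if not present:
        raise ValueError("no results given")
    if len(present) < len(sources):
        warnings.warn("missing source; partial report", stacklevel=2)
    y_max = max(
        yield_pct(res[t][0]) for res in present.values() for t in tau_grid
    )
    d_max = max(res[t][2] for res in present.values() for t in tau_grid)
    rows = []
    for t in tau_grid:
        both = all(t in res for res in present.values())
        r_val = np.nan
        semd_val = np.nan
        if both and len(present) == 2:
            fa = np.asarray(msm_results[t][1], dtype=float)
            fb = np.asarray(kmc_results[t][1], dtype=float)
            if len(fa) >= 2 and len(fb) >= 2:
                grid = shared_grid(fa, fb)
                r_val = pearson_r_curves(
                    kde_curve(fa, grid), kde_curve(fb, grid)
                )
                semd_val = s_emd(fa, fb)
        for name, res in present.items():
            flags, t_fas, t_drive = res[t]
            y = yield_pct(flags)
            c = cost(
                y / y_max if y_max > 0 else 0.0,
                t_drive / d_max if d_max > 0 else 0.0,
                weight,
            )
            rows.append(
                {
                    "tau_neq": t,
                    "source": name,
                    "yield_pct": y,
                    "t_drive_s": t_drive,
                    "R": r_val,
                    "S_EMD": semd_val,
                    "cost": c,
                }
            )
    table = pd.DataFrame(rows)
    optima = {}
    for name in present:
        sub = table[table["source"] == name].set_index("tau_neq")["cost"]
        optima[name] = float(sub.idxmax() if maximize else sub.idxmin())
    return table, optima
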