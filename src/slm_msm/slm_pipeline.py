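"""Stochastic landscape method (SLM): turn energy trajectories into segment
datasets.

A trajectory is processed window by window (window duration ``tau_beast``):
each window is interpolated onto a uniform time grid, downsampled by ``d_s``,
and segmented at trend change-points.  Each segment is summarized by its
stochastic coordinates — the mean energy <E*> (k_B T) and the mean trend
<t*> (k_B T / s, the fitted linear-trend slope) — plus its dwell time and
KMC step count.  Segments collected up to the first assembly event form the
dataset Omega used for Markov-state-model construction.

The change-point backend is pluggable (``register_detector``); the default
is an exact penalized piecewise-linear least-squares dynamic program.  The
module also defines the near-zero-trend trap region T* and the closed-loop
drive controller that conditionally weakens the bonds for ``tau_neq``
seconds when the latest segment trend falls inside T*.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .lattice_kmc import (
    EnergyTrajectory,
    KMCSimulation,
    ModelParams,
    TargetStructure,
    build_pair_table,
    scale_energies,
)

__all__ = [
    "SLMConfig",
    "Segment",
    "SLMDataset",
    "TrapRegion",
    "DriveProtocol",
    "DegenerateWindowError",
    "window_and_resample",
    "detect_changepoints",
    "register_detector",
    "summarize_segment",
    "segment_window",
    "identify_trap_region",
    "build_equilibrium_dataset",
    "run_driven",
    "build_driven_dataset",
    "build_dataset",
]


class DegenerateWindowError(ValueError):
    """Raised when a window slice has fewer than two samples."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SLMConfig:
    """Windowing and segmentation settings for one configuration.

    ``tau_beast``: window duration in seconds; ``d_s``: integer downsampling
    factor applied to the uniform grid; ``n_bins``: trap-region
    discretization parameter; ``detector``: change-point backend id;
    ``penalty_scale``: dimensionless penalty multiplier of the default
    detector; ``min_segment``: minimum segment length in grid points.
    """

    tau_beast: float
    d_s: int = 100
    n_bins: int = 10
    detector: str = "pwlinear"
    penalty_scale: float = 10.0
    min_segment: int = 3

    def __post_init__(self) -> None:
        if self.tau_beast <= 0:
            raise ValueError("tau_beast must be positive")
        if int(self.d_s) != self.d_s or self.d_s < 1:
            raise ValueError("d_s must be an integer >= 1")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.min_segment < 2:
            raise ValueError("min_segment must be >= 2")


@dataclass(frozen=True)
class Segment:
    """One SLM segment: stochastic coordinates plus bookkeeping."""

    mean_energy: float
    mean_trend: float
    onset: float
    end: float
    n_kmc_steps: int
    drive_on: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.onset:
            raise ValueError("segment end must exceed onset")

    @property
    def T_dwell(self) -> float:
        return self.end - self.onset


@dataclass(frozen=True)
class TrapRegion:
    """Symmetric mean-trend interval [lower, upper] = [-m*j, +m*j] around
    zero; trends inside (closed interval) flag a kinetic trap."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not math.isclose(self.lower, -self.upper, rel_tol=1e-12, abs_tol=1e-15):
            raise ValueError("trap region must be symmetric about zero")
        if self.upper < 0:
            raise ValueError("upper bound must be non-negative")

    def contains(self, trend: float | np.ndarray):
        return (trend >= self.lower) & (trend <= self.upper)


@dataclass(frozen=True)
class DriveProtocol:
    """Closed-loop shock protocol: scale bond energies by ``rho`` for
    ``tau_neq`` seconds at the start of the window following a trapped
    decision (evaluated every ``tau_beast_1`` seconds)."""

    rho: float
    tau_neq: float
    tau_beast_1: float
    trap: TrapRegion

    def __post_init__(self) -> None:
        if self.tau_neq < 0:
            raise ValueError("tau_neq must be non-negative")
        if self.tau_neq >= self.tau_beast_1:
            raise ValueError(
                "tau_neq must be shorter than tau_beast_1 so the system "
                "returns to baseline energies before the next evaluation"
            )


COLUMNS = [
    "traj_id",
    "onset_s",
    "end_s",
    "mean_energy",
    "mean_trend",
    "dwell_s",
    "n_kmc_steps",
    "drive_on",
]


@dataclass
class SLMDataset:
    """Segment dataset Omega: one row per segment (time-ordered within each
    trajectory, truncated at first assembly), plus per-trajectory
    first-assembly times and flags."""

    segments: pd.DataFrame
    T_FAS: np.ndarray
    assembled: np.ndarray
    config_id: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.segments.columns]
        if missing:
            raise ValueError(f"segment table missing columns {missing}")
        for _, grp in self.segments.groupby("traj_id"):
            on = grp["onset_s"].to_numpy()
            en = grp["end_s"].to_numpy()
            if np.any(np.diff(on) < 0) or np.any(en[:-1] - 1e-9 > on[1:]):
                raise ValueError("segments must be ordered and non-overlapping")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_trajectories(self) -> int:
        return len(self.T_FAS)

    def yield_pct(self) -> float:
        return 100.0 * float(np.mean(self.assembled))

    def trends(self) -> np.ndarray:
        return self.segments["mean_trend"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        """Write the segment table as CSV and a JSON manifest alongside."""
        path = Path(path)
        self.segments.to_csv(path, index=False)
        manifest = {
            "config_id": self.config_id,
            "n_trajectories": int(self.n_trajectories),
            "n_segments": int(self.n_segments),
            "T_FAS": [float(x) for x in self.T_FAS],
            "assembled": [int(x) for x in self.assembled],
            "extra": self.extra,
        }
        path.with_suffix(".manifest.json").write_text(
            json.dumps(manifest, indent=1)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SLMDataset":
        path = Path(path)
        seg = pd.read_csv(path)
        seg["drive_on"] = seg["drive_on"].astype(bool)
        man = json.loads(path.with_suffix(".manifest.json").read_text())
        return cls(
            segments=seg,
            T_FAS=np.asarray(man["T_FAS"], dtype=float),
            assembled=np.asarray(man["assembled"], dtype=int),
            config_id=man.get("config_id", ""),
            extra=man.get("extra", {}),
        )


# ---------------------------------------------------------------------------
# windowing and resampling
# ---------------------------------------------------------------------------

def window_and_resample(
    times: np.ndarray,
    energies: np.ndarray,
    d_s: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate a window slice onto a uniform time grid (grid length =
    raw sample count) and downsample by ``d_s``, preserving both endpoints.

    The retained grid has ``ceil(n / d_s)`` points (at least 2), linearly
    spaced over the slice span, with energies linearly interpolated."""
    times = np.asarray(times, dtype=float)
    energies = np.asarray(energies, dtype=float)
    n = len(times)
    if n < 2:
        raise DegenerateWindowError("window slice needs at least 2 samples")
    m = max(2, int(math.ceil(n / d_s)))
    grid = np.linspace(times[0], times[-1], m)
    return grid, np.interp(grid, times, energies)


# ---------------------------------------------------------------------------
# change-point detection (pluggable backend)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _pwlinear_dp(y, min_seg, penalty):
    """Exact dynamic program: minimize sum of per-segment linear-fit SSE
    plus ``penalty`` per segment.  Returns change-point index array
    (interior split positions, strictly increasing)."""
    n = y.shape[0]
    # prefix sums over index coordinate x = 0..n-1
    sx = np.zeros(n + 1)
    sxx = np.zeros(n + 1)
    sy = np.zeros(n + 1)
    syy = np.zeros(n + 1)
    sxy = np.zeros(n + 1)
    for i in range(n):
        x = float(i)
        sx[i + 1] = sx[i] + x
        sxx[i + 1] = sxx[i] + x * x
        sy[i + 1] = sy[i] + y[i]
        syy[i + 1] = syy[i] + y[i] * y[i]
        sxy[i + 1] = sxy[i] + x * y[i]

    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=np.int64)
    best[0] = -penalty  # first segment pays no extra split
    for j in range(min_seg, n + 1):
        for i in range(0, j - min_seg + 1):
            if not np.isfinite(best[i]):
                continue
            m = j - i
            mx = (sx[j] - sx[i]) / m
            my = (sy[j] - sy[i]) / m
            cxx = (sxx[j] - sxx[i]) - m * mx * mx
            cxy = (sxy[j] - sxy[i]) - m * mx * my
            cyy = (syy[j] - syy[i]) - m * my * my
            if cxx > 0.0:
                sse = cyy - cxy * cxy / cxx
            else:
                sse = cyy
            if sse < 0.0:
                sse = 0.0
            val = best[i] + sse + penalty
            if val < best[j]:
                best[j] = val
                prev[j] = i
    # backtrack
    cps = np.empty(n, dtype=np.int64)
    k = 0
    j = n
    while j > 0:
        i = prev[j]
        if i > 0:
            cps[k] = i
            k += 1
        j = i
    return cps[:k][::-1].copy()


def _pwlinear_detector(
    series: np.ndarray, penalty_scale: float, min_segment: int
) -> np.ndarray:
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 2 * min_segment:
        return np.empty(0, dtype=int)
    # robust noise scale from second differences (Var = 6 sigma^2 for iid
    # Gaussian noise on top of a piecewise-linear signal)
    d2 = np.diff(y, 2)
    mad = np.median(np.abs(d2 - np.median(d2))) if len(d2) else 0.0
    sigma2 = (mad / 0.6745) ** 2 / 6.0
    floor = 1e-12 * (1.0 + float(np.var(y)))
    penalty = penalty_scale * max(sigma2, floor) * math.log(n)
    return _pwlinear_dp(y, min_segment, penalty)


_DETECTORS: dict[str, Callable[[np.ndarray, SLMConfig], np.ndarray]] = {}


def register_detector(
    name: str, fn: Callable[[np.ndarray, SLMConfig], np.ndarray]
) -> None:
    """Register a change-point backend: ``fn(series, config)`` must return
    strictly increasing interior split indices."""
    _DETECTORS[name] = fn


register_detector(
    "pwlinear",
    lambda series, cfg: _pwlinear_detector(
        series, cfg.penalty_scale, cfg.min_segment
    ),
)


def detect_changepoints(
    series: np.ndarray, config: SLMConfig | None = None
) -> np.ndarray:
    """Interior trend change-point indices of a uniform series (no seasonal
    component; linear trends per segment).  Series shorter than the backend
    minimum yield an empty list."""
    if config is None:
        config = SLMConfig(tau_beast=1.0, d_s=1)
    try:
        backend = _DETECTORS[config.detector]
    except KeyError:
        raise ValueError(f"unknown change-point detector {config.detector!r}")
    cps = np.asarray(backend(np.asarray(series, dtype=float), config), dtype=int)
    n = len(series)
    if np.any(cps <= 0) or np.any(cps >= n) or np.any(np.diff(cps) <= 0):
        raise RuntimeError("detector returned invalid change-points")
    return cps


# ---------------------------------------------------------------------------
# segment summaries
# ---------------------------------------------------------------------------

def summarize_segment(
    times: np.ndarray,
    energies: np.ndarray,
    drive_on: bool = False,
    n_kmc_steps: int = 0,
) -> Segment:
    """Stochastic coordinates of one segment slice: <E*> is the arithmetic
    mean energy and <t*> the ordinary-least-squares slope of energy against
    time; dwell and timestamps come from the slice bounds."""
    times = np.asarray(times, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if len(times) < 2:
        raise ValueError("segment slice needs at least 2 samples")
    t0 = times - times.mean()
    denom = float(t0 @ t0)
    slope = float(t0 @ (energies - energies.mean()) / denom) if denom > 0 else 0.0
    return Segment(
        mean_energy=float(energies.mean()),
        mean_trend=slope,
        onset=float(times[0]),
        end=float(times[-1]),
        n_kmc_steps=int(n_kmc_steps),
        drive_on=bool(drive_on),
    )


def segment_window(
    raw_times: np.ndarray,
    raw_energies: np.ndarray,
    config: SLMConfig,
    forced_boundaries: Sequence[float] = (),
    drive_off_time: float | None = None,
) -> list[Segment]:
    """Full SLM treatment of one window slice: resample, detect trend
    change-points, split (additionally at any forced boundary time, e.g. the
    shock-off instant) and summarize every segment.

    ``drive_off_time``: segments ending at or before it are flagged
    drive-on.  Returns [] for degenerate (sub-minimal) slices."""
    if len(raw_times) < 2:
        return []
    grid, vals = window_and_resample(raw_times, raw_energies, config.d_s)
    cps = detect_changepoints(vals, config)
    bounds = [0, *cps.tolist(), len(grid)]
    # inject forced boundaries at the nearest grid index
    for tb in forced_boundaries:
        if grid[0] < tb < grid[-1]:
            k = int(np.argmin(np.abs(grid - tb)))
            if 0 < k < len(grid) and k not in bounds:
                bounds.append(k)
    bounds = sorted(set(bounds))
    segments: list[Segment] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 2:
            continue
        sl_t = grid[a:b]
        sl_e = vals[a:b]
        n_steps = int(
            np.searchsorted(raw_times, sl_t[-1], side="right")
            - np.searchsorted(raw_times, sl_t[0], side="left")
        )
        on = (
            drive_off_time is not None
            and sl_t[-1] <= drive_off_time + 1e-9
        )
        segments.append(summarize_segment(sl_t, sl_e, on, n_steps))
    return segments


# ---------------------------------------------------------------------------
# trap region
# ---------------------------------------------------------------------------

def identify_trap_region(
    dataset: "SLMDataset | np.ndarray", n_bins: int
) -> TrapRegion:
    """Expand symmetric boundaries [-m*j, +m*j] outward from zero trend in
    increments of the jump size j (smallest strictly positive difference
    between consecutive sorted trends) until the inclusive point count
    exceeds |Omega| / n_bins; falls back to the full trend range when the
    expansion exhausts the data."""
    trends = dataset.trends() if isinstance(dataset, SLMDataset) else np.asarray(
        dataset, dtype=float
    )
    if len(trends) == 0:
        raise ValueError("empty trend set")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    threshold = len(trends) / n_bins
    s = np.sort(trends)
    diffs = np.diff(s)
    pos = diffs[diffs > 0]
    full = float(max(abs(s[0]), abs(s[-1])))
    if len(pos) == 0:  # all trends identical
        return TrapRegion(-full, full)
    jump = float(pos.min())
    # The expansion over m = 1, 2, ... stops at the smallest multiple of the
    # jump whose inclusive count exceeds the threshold.  The jump can be as
    # small as one float ulp of the trend scale, so literal iteration is
    # unbounded; solve for the stopping multiple directly (equivalent to the
    # stepwise rule) and nudge against floating-point rounding.
    k = int(math.floor(threshold)) + 1  # smallest integer count > threshold
    if k > len(trends):
        # the count can never exceed the threshold: the expansion runs off
        # the end of the data and falls back to the full trend range
        return TrapRegion(-full, full)
    a = float(np.sort(np.abs(trends))[k - 1])  # k-th smallest |trend|
    m = max(1, int(math.ceil(a / jump)))
    if m * jump < a:  # ceil rounded down by one ulp
        m += 1
    bound = m * jump
    # walk down to the minimal multiple (protects against overshoot); each
    # step must shrink the bound representably or we stop
    while m > 1:
        b2 = (m - 1) * jump
        if b2 >= bound:
            break
        if int(np.sum((trends >= -b2) & (trends <= b2))) > threshold:
            m -= 1
            bound = b2
        else:
            break
    return TrapRegion(-bound, bound)


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------

def build_dataset(
    per_traj_segments: Sequence[Sequence[Segment]],
    T_FAS: Sequence[float],
    assembled: Sequence[int],
    config_id: str = "",
    extra: dict | None = None,
) -> SLMDataset:
    """Assemble an Omega dataset from per-trajectory segment streams
    (already truncated at first assembly)."""
    if len(per_traj_segments) == 0:
        raise ValueError("need at least one trajectory")
    rows = []
    for tid, segs in enumerate(per_traj_segments):
        for s in segs:
            rows.append(
                (tid, s.onset, s.end, s.mean_energy, s.mean_trend,
                 s.T_dwell, s.n_kmc_steps, s.drive_on)
            )
    df = pd.DataFrame(rows, columns=COLUMNS)
    return SLMDataset(
        segments=df,
        T_FAS=np.asarray(T_FAS, dtype=float),
        assembled=np.asarray(assembled, dtype=int),
        config_id=config_id,
        extra=extra or {},
    )


def _new_window_slice(
    sim: KMCSimulation, k0: int, carry_t: float, carry_e: float
) -> tuple[np.ndarray, np.ndarray]:
    """Samples recorded since chunk index ``k0``, prepended with the last
    sample of the previous window so the slice starts populated."""
    chunks_t = sim.times[k0:]
    chunks_e = sim.energies[k0:]
    ts = np.concatenate([np.array([carry_t]), *chunks_t])
    es = np.concatenate([np.array([carry_e]), *chunks_e])
    return ts, es


def build_equilibrium_dataset(
    params: ModelParams,
    targets: Sequence[TargetStructure],
    config: SLMConfig,
    n_realizations: int,
    n_windows: int,
    seed: int,
    config_id: str = "",
) -> SLMDataset:
    """Run an equilibrium KMC ensemble through the SLM, window by window,
    collecting segments up to the first assembly event of each realization.

    The horizon is ``n_windows`` windows of ``config.tau_beast`` seconds
    (subject to ``params.N_steps``); unassembled trajectories record
    T_FAS equal to the final simulation time with flag 0."""
    all_segments: list[list[Segment]] = []
    t_fas: list[float] = []
    flags: list[int] = []
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(n_realizations) % (2**31 - 1)]
    for r in range(n_realizations):
        sim = KMCSimulation(params, targets, seeds[r])
        segs: list[Segment] = []
        carry_t, carry_e = sim.times[-1][-1], sim.energies[-1][-1]
        for w in range(n_windows):
            k0 = len(sim.times)
            status = sim.advance((w + 1) * config.tau_beast)
            raw_t, raw_e = _new_window_slice(sim, k0, carry_t, carry_e)
            carry_t, carry_e = raw_t[-1], raw_e[-1]
            segs.extend(segment_window(raw_t, raw_e, config))
            if status in ("assembled", "steps"):
                break
        all_segments.append(segs)
        flags.append(1 if sim.assembled else 0)
        t_fas.append(sim.T_FAS if sim.assembled else sim.t)
    return build_dataset(all_segments, t_fas, flags, config_id=config_id)


def run_driven(
    params: ModelParams,
    targets: Sequence[TargetStructure],
    protocol: DriveProtocol,
    config: SLMConfig,
    n_windows: int,
    seed: int,
) -> tuple[EnergyTrajectory, list[Segment]]:
    """One closed-loop driven realization.

    Each window of ``protocol.tau_beast_1`` seconds is simulated and
    segmented in real time.  If the trajectory assembled, it stops.
    Otherwise, when the final segment's mean trend lies inside the trap
    region, a shock (bond energies scaled by ``rho``) is scheduled for the
    first ``tau_neq`` seconds of the next window.  Windows during a shock
    are split at the shock-off instant and the covered segments flagged
    drive-on."""
    tau = protocol.tau_beast_1
    if config.tau_beast != tau:
        config = replace(config, tau_beast=tau)
    sim = KMCSimulation(params, targets, seed)
    scaled_table = build_pair_table(scale_energies(params, protocol.rho), targets)
    segs: list[Segment] = []
    drive_intervals: list[tuple[float, float]] = []
    shock_next = False
    carry_t, carry_e = sim.times[-1][-1], sim.energies[-1][-1]
    for w in range(n_windows):
        t_lo = w * tau
        t_hi = (w + 1) * tau
        drive_off: float | None = None
        k0 = len(sim.times)
        if shock_next and protocol.tau_neq > 0:
            drive_off = t_lo + protocol.tau_neq
            status = sim.advance(drive_off, pair_table=scaled_table)
            drive_intervals.append((t_lo, min(drive_off, sim.t)))
            if status == "time":
                status = sim.advance(t_hi)
        else:
            status = sim.advance(t_hi)
        shock_next = False
        raw_t, raw_e = _new_window_slice(sim, k0, carry_t, carry_e)
        carry_t, carry_e = raw_t[-1], raw_e[-1]
        forced = (drive_off,) if drive_off is not None else ()
        w_segs = segment_window(
            raw_t, raw_e, config,
            forced_boundaries=forced, drive_off_time=drive_off,
        )
        segs.extend(w_segs)
        if status in ("assembled", "steps"):
            break
        # decision at window end: trapped iff the latest trend is in T*
        if w_segs and bool(protocol.trap.contains(w_segs[-1].mean_trend)):
            shock_next = True
    traj = sim.trajectory(drive_intervals)
    return traj, segs


def build_driven_dataset(
    params: ModelParams,
    targets: Sequence[TargetStructure],
    protocol: DriveProtocol,
    config: SLMConfig,
    n_realizations: int,
    n_windows: int,
    seed: int,
    config_id: str = "neq",
) -> SLMDataset:
    """Driven (closed-loop) KMC ensemble -> Omega^neq, plus per-trajectory
    drive bookkeeping (total drive-on seconds in ``extra['t_drive_s']``)."""
    all_segments: list[list[Segment]] = []
    t_fas: list[float] = []
    flags: list[int] = []
    t_drive: list[float] = []
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(n_realizations) % (2**31 - 1)]
    for r in range(n_realizations):
        traj, segs = run_driven(
            params, targets, protocol, config, n_windows, seeds[r]
        )
        all_segments.append(segs)
        flags.append(traj.assembled_flag)
        t_fas.append(traj.T_FAS)
        t_drive.append(sum(b - a for a, b in traj.drive_intervals))
    return build_dataset(
        all_segments, t_fas, flags, config_id=config_id,
        extra={"t_drive_s": t_drive},
    )
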