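"""Coarse-grain an SLM segment dataset into a continuous-time Markov state
model (MSM) with an absorbing first-assembly (FA) state.

States are nested quantile cells of the stochastic coordinates: the trend
axis is split at empirical quantiles first (trapped vs mobile segments live
at very different trend magnitudes), then each trend bin is split at the
conditional energy quantiles.  Occupied cells become numbered states with
representative (mean energy, mean trend) coordinates; the binning vector is
reusable on new data (out-of-range coordinates clamp to the edge bins, as
the driven construction requires).

Per trajectory, segments map to a state sequence; consecutive repeats merge
into dwell periods; the sequence is sampled on a uniform grid (step = 50x
the smallest onset gap), downsampled at a lag chosen so the shortest
trajectory still contains at least five transitions, and transition counts
between distinct consecutive states give the row-stochastic matrix P.  Each
state carries an exponential dwell time whose mean matches its empirical
dwell; the resulting continuous-time chain over the state graph is the MSM.
The model is deliberately a results-oriented surrogate: Markovianity is
diagnosed (implied timescales, Chapman-Kolmogorov) rather than enforced.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .slm_pipeline import SLMDataset

__all__ = [
    "BinningVector",
    "StateSequence",
    "MSM",
    "quantile_bins",
    "assign_states",
    "merge_repeats",
    "to_uniform_grid",
    "initial_distribution",
    "select_lag",
    "estimate_msm",
    "build_msm",
    "simulate_msm",
    "implied_timescales",
    "ck_test",
    "dwell_exponential_fit_quality",
]


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinningVector:
    """Nested quantile binning: interior trend edges, per-trend-bin interior
    energy edges, and the occupied-cell -> state renumbering.

    ``state_of_cell`` maps (trend_bin, energy_bin) to a state id in
    0..N_s-1 (-1 for cells unoccupied in the training data; lookups clamp
    to the nearest occupied cell within the trend bin).  ``FA`` is the
    absorbing first-assembly state id, always N_s."""

    trend_edges: np.ndarray
    energy_edges: np.ndarray  # (n_trend_bins, n_energy_bins - 1)
    state_of_cell: np.ndarray  # (n_trend_bins, n_energy_bins) int
    state_coords: np.ndarray  # (N_s, 2): mean (energy, trend) per state

    @property
    def N_s(self) -> int:
        return self.state_coords.shape[0]

    @property
    def FA(self) -> int:
        return self.N_s

    def cell_of(self, energy: np.ndarray, trend: np.ndarray) -> np.ndarray:
        """Vectorized (energy, trend) -> state id; out-of-range coordinates
        clamp into the edge bins."""
        energy = np.atleast_1d(np.asarray(energy, dtype=float))
        trend = np.atleast_1d(np.asarray(trend, dtype=float))
        tb = np.searchsorted(self.trend_edges, trend, side="right")
        out = np.empty(len(trend), dtype=int)
        for i, (t, e) in enumerate(zip(tb, energy)):
            eb = int(np.searchsorted(self.energy_edges[t], e, side="right"))
            s = self.state_of_cell[t, eb]
            if s < 0:
                # empty training cell: nearest occupied energy bin in this
                # trend bin (ties toward lower energy bin)
                row = self.state_of_cell[t]
                occ = np.nonzero(row >= 0)[0]
                eb = occ[np.argmin(np.abs(occ - eb))]
                s = row[eb]
            out[i] = s
        return out

    def to_dict(self) -> dict:
        return {
            "trend_edges": self.trend_edges.tolist(),
            "energy_edges": self.energy_edges.tolist(),
            "state_of_cell": self.state_of_cell.tolist(),
            "state_coords": self.state_coords.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinningVector":
        return cls(
            trend_edges=np.asarray(d["trend_edges"], dtype=float),
            energy_edges=np.asarray(d["energy_edges"], dtype=float),
            state_of_cell=np.asarray(d["state_of_cell"], dtype=int),
            state_coords=np.asarray(d["state_coords"], dtype=float),
        )


def quantile_bins(
    dataset: SLMDataset, n_trend_bins: int, n_energy_bins: int
) -> BinningVector:
    """Build the adaptive binning vector from a segment dataset.

    Trend edges sit at the empirical quantiles k/n_trend_bins; inside each
    trend bin, energy edges sit at the conditional quantiles.  Occupied
    cells are numbered in (trend bin, energy bin) lexicographic order and
    labeled by their within-cell mean coordinates.  Requesting more bins
    than distinct values collapses duplicate edges (with a warning)."""
    if dataset.n_segments == 0:
        raise ValueError("empty dataset")
    if n_trend_bins < 1 or n_energy_bins < 1:
        raise ValueError("bin counts must be >= 1")
    trends = dataset.segments["mean_trend"].to_numpy()
    energies = dataset.segments["mean_energy"].to_numpy()
    qs = np.arange(1, n_trend_bins) / n_trend_bins
    t_edges = np.unique(np.quantile(trends, qs)) if n_trend_bins > 1 else np.empty(0)
    if n_trend_bins > 1 and len(t_edges) < n_trend_bins - 1:
        warnings.warn("duplicate trend quantiles collapsed", stacklevel=2)
    nt = len(t_edges) + 1
    tb = np.searchsorted(t_edges, trends, side="right")
    e_edges = np.full((nt, n_energy_bins - 1), np.nan)
    cell_state = np.full((nt, n_energy_bins), -1, dtype=int)
    coords: list[tuple[float, float]] = []
    sid = 0
    qe = np.arange(1, n_energy_bins) / n_energy_bins
    for t in range(nt):
        sel = tb == t
        if not np.any(sel):
            e_edges[t] = np.inf  # degenerate, never matched
            continue
        ee = (
            np.quantile(energies[sel], qe)
            if n_energy_bins > 1
            else np.empty(0)
        )
        if n_energy_bins > 1 and len(np.unique(ee)) < len(ee):
            warnings.warn("duplicate energy quantiles collapsed", stacklevel=2)
        e_edges[t, : len(ee)] = ee
        e_edges[t, len(ee):] = np.inf
        eb = np.searchsorted(ee, energies[sel], side="right")
        for b in range(n_energy_bins):
            inb = eb == b
            if not np.any(inb):
                continue
            cell_state[t, b] = sid
            coords.append(
                (
                    float(energies[sel][inb].mean()),
                    float(trends[sel][inb].mean()),
                )
            )
            sid += 1
    return BinningVector(
        trend_edges=np.asarray(t_edges, dtype=float),
        energy_edges=e_edges,
        state_of_cell=cell_state,
        state_coords=np.asarray(coords, dtype=float),
    )


# ---------------------------------------------------------------------------
# state sequences
# ---------------------------------------------------------------------------

@dataclass
class StateSequence:
    """Ordered (state, onset, dwell) triples of one trajectory, ending in
    the absorbing FA state (``terminal_fa``) or censored at the horizon."""

    states: np.ndarray  # int
    onsets: np.ndarray  # s
    dwells: np.ndarray  # s
    terminal_fa: bool
    T_FAS: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.onsets) < 0):
            raise ValueError("onsets must be non-decreasing")

    def __len__(self) -> int:
        return len(self.states)


def assign_states(
    dataset: SLMDataset, binning: BinningVector
) -> list[StateSequence]:
    """Map every trajectory's segments to coarse-grained state sequences;
    assembled trajectories are terminated by the FA state at T_FAS."""
    sequences: list[StateSequence] = []
    seg = dataset.segments
    groups = dict(tuple(seg.groupby("traj_id")))
    for tid in range(dataset.n_trajectories):
        grp = groups.get(tid)
        fa = bool(dataset.assembled[tid])
        if grp is None or len(grp) == 0:
            # no segments (e.g. assembly before the first full window)
            sequences.append(
                StateSequence(
                    states=np.empty(0, dtype=int),
                    onsets=np.empty(0),
                    dwells=np.empty(0),
                    terminal_fa=fa,
                    T_FAS=float(dataset.T_FAS[tid]),
                )
            )
            continue
        sts = binning.cell_of(
            grp["mean_energy"].to_numpy(), grp["mean_trend"].to_numpy()
        )
        sequences.append(
            StateSequence(
                states=sts,
                onsets=grp["onset_s"].to_numpy(),
                dwells=grp["dwell_s"].to_numpy(),
                terminal_fa=fa,
                T_FAS=float(dataset.T_FAS[tid]),
            )
        )
    return sequences


def merge_repeats(sequence: StateSequence) -> StateSequence:
    """Fuse consecutive identical states into single dwell periods (onset of
    the first occurrence, dwell summed); idempotent."""
    if len(sequence) == 0:
        return sequence
    keep = np.concatenate(([True], np.diff(sequence.states) != 0))
    idx = np.nonzero(keep)[0]
    dwells = np.add.reduceat(sequence.dwells, idx)
    return StateSequence(
        states=sequence.states[idx],
        onsets=sequence.onsets[idx],
        dwells=dwells,
        terminal_fa=sequence.terminal_fa,
        T_FAS=sequence.T_FAS,
    )


def grid_step(sequences: Sequence[StateSequence]) -> float:
    """Uniform grid step: 50x the smallest positive gap between consecutive
    segment onset times across the ensemble."""
    gaps = []
    for s in sequences:
        if len(s) >= 2:
            d = np.diff(s.onsets)
            d = d[d > 0]
            if len(d):
                gaps.append(d.min())
    if not gaps:
        raise ValueError("no trajectory with two distinct onsets")
    return 50.0 * float(min(gaps))


def to_uniform_grid(
    sequence: StateSequence, dt: float, fa_state: int
) -> np.ndarray:
    """Sample the (merged) sequence on ticks k*dt from its onset: each tick
    is labeled by the state occupying that time; assembled trajectories end
    with a single FA tick at the first tick >= T_FAS."""
    if len(sequence) == 0:
        return (
            np.array([fa_state], dtype=int)
            if sequence.terminal_fa
            else np.empty(0, dtype=int)
        )
    t0 = sequence.onsets[0]
    t_end = sequence.T_FAS if sequence.terminal_fa else (
        sequence.onsets[-1] + sequence.dwells[-1]
    )
    n_ticks = max(1, int(np.floor((t_end - t0) / dt)) + 1)
    ticks = t0 + dt * np.arange(n_ticks)
    # state occupying each tick: last segment with onset <= tick
    idx = np.searchsorted(sequence.onsets, ticks + 1e-12, side="right") - 1
    idx = np.clip(idx, 0, len(sequence) - 1)
    labels = sequence.states[idx]
    if sequence.terminal_fa:
        labels = np.append(labels[ticks < sequence.T_FAS], fa_state)
    return labels.astype(int)


def initial_distribution(
    sequences: Sequence[StateSequence], n_states: int
) -> np.ndarray:
    """pi0 over the N_s + 1 states (FA last): the fraction of trajectories
    whose first segment occupies each state."""
    if len(sequences) == 0:
        raise ValueError("need at least one trajectory")
    pi0 = np.zeros(n_states + 1)
    for s in sequences:
        first = s.states[0] if len(s) else n_states
        pi0[first] += 1.0
    return pi0 / pi0.sum()


def select_lag(
    sequences: Sequence[StateSequence], dt: float, n_transitions: int = 5
) -> float:
    """Largest grid-multiple lag L such that the shortest trajectory still
    holds at least ``n_transitions`` transitions: min(T_FAS)/L >= 5; clamps
    to dt (with a warning) when even that is too coarse."""
    t_min = min(s.T_FAS for s in sequences)
    k = int(np.floor(t_min / (n_transitions * dt)))
    if k < 1:
        warnings.warn(
            "shortest trajectory holds fewer than the requested transitions "
            "at the grid step; lag clamped to dt",
            stacklevel=2,
        )
        return dt
    return k * dt


# ---------------------------------------------------------------------------
# the MSM
# ---------------------------------------------------------------------------

@dataclass
class MSM:
    """Continuous-time Markov state model over N_s + 1 states (absorbing FA
    last): row-stochastic jump matrix P, mean dwell vector T_bar (s),
    initial distribution pi0, representative state coordinates and the lag
    used for estimation."""

    P: np.ndarray
    T_bar: np.ndarray
    pi0: np.ndarray
    state_coords: np.ndarray
    lag: float
    FA: int
    flags: dict = field(default_factory=dict)
    binning: BinningVector | None = None

    def __post_init__(self) -> None:
        n = self.P.shape[0]
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("P rows must sum to 1")
        if not np.allclose(self.P[self.FA], np.eye(n)[self.FA], atol=1e-12):
            raise ValueError("FA row must be absorbing")
        if np.any(self.T_bar[: self.FA] <= 0):
            raise ValueError("mean dwells must be positive")
        if not np.isclose(self.pi0.sum(), 1.0, atol=1e-9):
            raise ValueError("pi0 must sum to 1")

    @property
    def N_s(self) -> int:
        return self.P.shape[0] - 1

    def to_dict(self) -> dict:
        return {
            "P": self.P.tolist(),
            "T_bar": self.T_bar.tolist(),
            "pi0": self.pi0.tolist(),
            "state_coords": self.state_coords.tolist(),
            "lag": self.lag,
            "FA": self.FA,
            "flags": self.flags,
            "binning": None if self.binning is None else self.binning.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MSM":
        return cls(
            P=np.asarray(d["P"], dtype=float),
            T_bar=np.asarray(d["T_bar"], dtype=float),
            pi0=np.asarray(d["pi0"], dtype=float),
            state_coords=np.asarray(d["state_coords"], dtype=float),
            lag=float(d["lag"]),
            FA=int(d["FA"]),
            flags=d.get("flags", {}),
            binning=None
            if d.get("binning") is None
            else BinningVector.from_dict(d["binning"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "MSM":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_graph(self) -> nx.DiGraph:
        """Weighted directed graph of the model (FA included)."""
        g = nx.DiGraph()
        for s in range(self.N_s):
            g.add_node(
                s,
                mean_energy=float(self.state_coords[s, 0]),
                mean_trend=float(self.state_coords[s, 1]),
                mean_dwell=float(self.T_bar[s]),
            )
        g.add_node(self.FA, label="FA")
        for i in range(self.N_s + 1):
            for j in range(self.N_s + 1):
                if self.P[i, j] > 0 and i != j:
                    g.add_edge(i, j, probability=float(self.P[i, j]))
        return g


def _downsample_labels(labels: np.ndarray, k: int) -> np.ndarray:
    """Every k-th tick, trimming the beginning so the final tick is kept
    (aligning the series end with the lag intervals)."""
    if len(labels) == 0 or k <= 1:
        return labels
    offset = (len(labels) - 1) % k
    return labels[offset::k]


def estimate_msm(
    sequences: Sequence[StateSequence],
    lag: float,
    binning: BinningVector,
    dt: float | None = None,
) -> MSM:
    """Estimate the continuous-time MSM at the given lag.

    Gridded label sequences are downsampled at the lag, adjacent repeats
    re-merged; P counts transitions between distinct consecutive states
    (censored endings contribute dwell but no exit) and T_bar is the
    empirical mean dwell (in seconds) per state.  States never visited are
    dropped with a warning; visited states without exits (other than FA)
    become flagged self-loop sinks."""
    if dt is None:
        dt = grid_step(sequences)
    k = max(1, int(round(lag / dt)))
    n = binning.N_s
    fa = binning.FA
    counts = np.zeros((n + 1, n + 1))
    dwell_sum = np.zeros(n + 1)
    dwell_n = np.zeros(n + 1)
    dwell_samples: dict[int, list[float]] = {s: [] for s in range(n)}
    for seq in sequences:
        labels = _downsample_labels(to_uniform_grid(seq, dt, fa), k)
        if len(labels) == 0:
            continue
        # re-merge: run lengths of identical labels
        change = np.nonzero(np.diff(labels) != 0)[0]
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [len(labels)]))
        run_states = labels[starts]
        run_len = ends - starts
        for i, (s, L) in enumerate(zip(run_states, run_len)):
            if s == fa:
                continue
            dwell_sum[s] += L * lag
            dwell_n[s] += 1
            dwell_samples[s].append(L * lag)
            if i + 1 < len(run_states):
                counts[s, run_states[i + 1]] += 1
    visited = np.nonzero((dwell_n[:n] > 0) | (counts[:n].sum(axis=1) > 0))[0]
    if len(visited) < n:
        warnings.warn(
            f"{n - len(visited)} states never visited; removed from model",
            stacklevel=2,
        )
    keep = np.concatenate((visited, [fa]))
    remap = {int(s): i for i, s in enumerate(keep)}
    m = len(visited)
    P = np.zeros((m + 1, m + 1))
    flags: dict = {"censored_sinks": [], "dwell_samples": {}}
    for i, s in enumerate(visited):
        row = counts[s][keep]
        tot = row.sum()
        if tot > 0:
            P[i] = row / tot
        else:
            P[i, i] = 1.0  # censored sink: no observed exit
            flags["censored_sinks"].append(int(i))
    P[m, m] = 1.0
    T_bar = np.empty(m + 1)
    for i, s in enumerate(visited):
        T_bar[i] = dwell_sum[s] / max(dwell_n[s], 1)
        flags["dwell_samples"][int(i)] = dwell_samples[int(s)]
    T_bar[m] = np.inf
    pi0_full = initial_distribution(sequences, n)
    pi0 = np.zeros(m + 1)
    for s_old, i in remap.items():
        pi0[i] = pi0_full[s_old]
    pi0 /= pi0.sum()
    coords = binning.state_coords[visited] if m else np.empty((0, 2))
    return MSM(
        P=P,
        T_bar=T_bar,
        pi0=pi0,
        state_coords=coords,
        lag=lag,
        FA=m,
        flags=flags,
        binning=binning,
    )


def build_msm(
    dataset: SLMDataset,
    n_trend_bins: int,
    n_energy_bins: int,
    lag: float | None = None,
) -> MSM:
    """Full equilibrium construction: quantile binning, state assignment,
    repeat merging, gridding, lag selection, estimation."""
    binning = quantile_bins(dataset, n_trend_bins, n_energy_bins)
    seqs = [merge_repeats(s) for s in assign_states(dataset, binning)]
    dt = grid_step(seqs)
    if lag is None:
        lag = select_lag(seqs, dt)
    return estimate_msm(seqs, lag, binning, dt=dt)


# ---------------------------------------------------------------------------
# simulation & diagnostics
# ---------------------------------------------------------------------------

def simulate_msm(
    msm: MSM,
    n_realizations: int,
    horizon: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gillespie simulation of the MSM: start ~ pi0, exponential dwells with
    the state's mean, jumps by the rows of P; stop at FA (flag 1, T_FAS =
    elapsed) or at the horizon (flag 0, T_FAS = horizon).

    Returns (flags, T_FAS samples)."""
    rng = np.random.default_rng(seed)
    flags = np.zeros(n_realizations, dtype=int)
    t_fas = np.full(n_realizations, float(horizon))
    n = msm.N_s
    cum = np.cumsum(msm.P, axis=1)
    for r in range(n_realizations):
        s = int(np.searchsorted(np.cumsum(msm.pi0), rng.random(), side="right"))
        t = 0.0
        while t < horizon:
            if s == msm.FA:
                flags[r] = 1
                t_fas[r] = t
                break
            t += rng.exponential(msm.T_bar[s])
            if t >= horizon:
                break
            nxt = int(np.searchsorted(cum[s], rng.random(), side="right"))
            if nxt == s:  # censored sink: no exit observed
                t = horizon
                break
            s = nxt
    return flags, t_fas


def _count_matrix(label_seqs: Sequence[np.ndarray], k: int, n_states: int):
    c = np.zeros((n_states, n_states))
    for lab in label_seqs:
        if len(lab) > k:
            np.add.at(c, (lab[:-k], lab[k:]), 1.0)
    return c


def _transition_matrix(c: np.ndarray) -> np.ndarray:
    p = c.copy()
    rs = p.sum(axis=1)
    for i in range(len(p)):
        if rs[i] > 0:
            p[i] /= rs[i]
        else:
            p[i, i] = 1.0
    return p


def implied_timescales(
    label_seqs: Sequence[np.ndarray],
    lags: Sequence[int],
    n_states: int,
    dt: float = 1.0,
) -> np.ndarray:
    """Implied timescales t_k(tau) = -tau / ln |lambda_k(tau)| for the
    non-unit eigenvalues of the transition matrix estimated at each integer
    lag (in grid steps); rows ordered by descending modulus.  Flat curves
    across lags indicate Markovian dynamics at the grid resolution.

    Returns an array of shape (len(lags), n_states - 1); infinite where
    |lambda| is numerically 1, NaN where undersampled."""
    if len(lags) < 2:
        raise ValueError("need at least two lags")
    out = np.full((len(lags), n_states - 1), np.nan)
    for i, k in enumerate(lags):
        c = _count_matrix(label_seqs, int(k), n_states)
        if c.sum() == 0:
            continue
        p = _transition_matrix(c)
        ev = np.linalg.eigvals(p)
        mod = np.abs(ev)  # complex pairs enter via their modulus
        mod = np.sort(mod)[::-1]
        mod = mod[1:]  # discard the unit (stationary/absorbing) eigenvalue
        with np.errstate(divide="ignore"):
            ts = np.where(
                mod >= 1.0 - 1e-12,
                np.inf,
                -k * dt / np.log(np.maximum(mod, 1e-300)),
            )
        out[i, : len(ts)] = ts
    return out


def ck_test(
    label_seqs: Sequence[np.ndarray],
    lag: int,
    k_steps: Sequence[int],
    probe_states: Sequence[int],
    n_states: int,
    n_boot: int = 100,
    seed: int = 0,
) -> dict:
    """Chapman-Kolmogorov test: compare [P(tau)]^k diagonal entries against
    the directly estimated P(k*tau) diagonals, with bootstrap (over
    trajectories) uncertainty bands on the empirical side.

    Returns {state: (k_steps, predicted, empirical, lo, hi)}."""
    rng = np.random.default_rng(seed)
    p1 = _transition_matrix(_count_matrix(label_seqs, lag, n_states))
    results: dict[int, dict] = {}
    boot_emp = {s: np.zeros((n_boot, len(k_steps))) for s in probe_states}
    for b in range(n_boot):
        idx = rng.integers(0, len(label_seqs), len(label_seqs))
        sample = [label_seqs[i] for i in idx]
        for j, k in enumerate(k_steps):
            pk = _transition_matrix(_count_matrix(sample, lag * int(k), n_states))
            for s in probe_states:
                boot_emp[s][b, j] = pk[s, s]
    for s in probe_states:
        pred = np.empty(len(k_steps))
        emp = np.empty(len(k_steps))
        for j, k in enumerate(k_steps):
            pred[j] = np.linalg.matrix_power(p1, int(k))[s, s]
            emp[j] = _transition_matrix(
                _count_matrix(label_seqs, lag * int(k), n_states)
            )[s, s]
        lo = np.percentile(boot_emp[s], 2.5, axis=0)
        hi = np.percentile(boot_emp[s], 97.5, axis=0)
        results[s] = {
            "k_steps": np.asarray(k_steps),
            "predicted": pred,
            "empirical": emp,
            "lo": lo,
            "hi": hi,
        }
    return results


def dwell_exponential_fit_quality(
    dwell_samples: dict[int, Sequence[float]], min_samples: int = 10
) -> dict[int, float]:
    """Per-state Pearson R between the histogram of empirical dwell times
    and an exponential distribution matched to the empirical mean, binned on
    identical (Scott-rule) edges.  States with fewer than ``min_samples``
    dwells (or degenerate single-valued dwells) are skipped."""
    out: dict[int, float] = {}
    for s, samples in dwell_samples.items():
        x = np.asarray(list(samples), dtype=float)
        if len(x) < min_samples or np.ptp(x) == 0:
            continue
        width = 3.49 * x.std(ddof=1) / len(x) ** (1 / 3)
        if width <= 0:
            continue
        edges = np.arange(x.min(), x.max() + width, width)
        if len(edges) < 3:
            edges = np.linspace(x.min(), x.max(), 3)
        emp, _ = np.histogram(x, bins=edges, density=True)
        mean = x.mean()
        cdf = 1.0 - np.exp(-edges / mean)
        model = np.diff(cdf) / np.diff(edges)
        if emp.std() == 0 or model.std() == 0:
            continue
        out[s] = float(np.corrcoef(emp, model)[0, 1])
    return out
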