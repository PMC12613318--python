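"""Two-layer driven Markov state model.

The trend-triggered shock protocol alternates the physical system between
two equilibrium landscapes: configuration 1 (baseline bonds) and
configuration 2 (bonds weakened by rho).  The driven MSM joins the two
equilibrium MSMs as distinct layers: every ``tau_beast_1`` seconds the
layer-1 chain is inspected, and if it occupies a trap state (representative
trend inside T*), it jumps to layer 2 through the forward level-jumping
matrix T_F, evolves there for ``tau_neq`` seconds, and returns through the
backward matrix T_B.  T_F and T_B are estimated from the driven dataset
Omega^neq by counting the coarse states just before/after each drive
activation and deactivation.  First assembly (FA) in either layer ends a
realization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .msm_equilibrium import MSM, BinningVector
from .slm_pipeline import SLMDataset, TrapRegion

__all__ = [
    "DualStateSequence",
    "LevelJumpMatrices",
    "DrivenMSM",
    "map_segments_dual",
    "build_jump_matrices",
    "trap_states",
    "build_driven_msm",
    "simulate_driven",
]


@dataclass
class DualStateSequence:
    """One driven trajectory labeled in both layers: per segment the layer
    (0 = drive off -> configuration-1 states, 1 = drive on ->
    configuration-2 states) and the state id within that layer."""

    layers: np.ndarray  # 0/1 per segment
    states: np.ndarray  # state id in the segment's layer
    onsets: np.ndarray
    terminal_fa: bool
    T_FAS: float


@dataclass
class LevelJumpMatrices:
    """Forward (T_F: layer-1 x layer-2) and backward (T_B: layer-2 x
    layer-1) level-jumping matrices with per-row observation counts.
    Unobserved rows are flagged; sampling from them falls back to the
    nearest-mean-energy state of the destination layer."""

    T_F: np.ndarray
    T_B: np.ndarray
    counts_F: np.ndarray
    counts_B: np.ndarray

    def __post_init__(self) -> None:
        for M, c in ((self.T_F, self.counts_F), (self.T_B, self.counts_B)):
            rs = M.sum(axis=1)
            obs = c > 0
            if not np.allclose(rs[obs], 1.0, atol=1e-9):
                raise ValueError("observed rows must sum to 1")

    @property
    def unobserved_F(self) -> np.ndarray:
        return np.nonzero(self.counts_F == 0)[0]

    @property
    def unobserved_B(self) -> np.ndarray:
        return np.nonzero(self.counts_B == 0)[0]


def map_segments_dual(
    dataset: SLMDataset,
    binning1: BinningVector,
    binning2: BinningVector,
) -> list[DualStateSequence]:
    """Label every Omega^neq segment in the appropriate layer's state space:
    drive-on segments through the configuration-2 binning, drive-off
    segments through configuration 1.  (Segments produced by the driven
    controller are already split at drive on/off switch times.)"""
    out: list[DualStateSequence] = []
    groups = dict(tuple(dataset.segments.groupby("traj_id")))
    for tid in range(dataset.n_trajectories):
        grp = groups.get(tid)
        if grp is None or len(grp) == 0:
            out.append(
                DualStateSequence(
                    layers=np.empty(0, dtype=int),
                    states=np.empty(0, dtype=int),
                    onsets=np.empty(0),
                    terminal_fa=bool(dataset.assembled[tid]),
                    T_FAS=float(dataset.T_FAS[tid]),
                )
            )
            continue
        on = grp["drive_on"].to_numpy().astype(bool)
        e = grp["mean_energy"].to_numpy()
        t = grp["mean_trend"].to_numpy()
        states = np.empty(len(grp), dtype=int)
        if np.any(~on):
            states[~on] = binning1.cell_of(e[~on], t[~on])
        if np.any(on):
            states[on] = binning2.cell_of(e[on], t[on])
        out.append(
            DualStateSequence(
                layers=on.astype(int),
                states=states,
                onsets=grp["onset_s"].to_numpy(),
                terminal_fa=bool(dataset.assembled[tid]),
                T_FAS=float(dataset.T_FAS[tid]),
            )
        )
    return out


def build_jump_matrices(
    dual_sequences: Sequence[DualStateSequence],
    n_states_1: int,
    n_states_2: int,
) -> LevelJumpMatrices:
    """Count level-switch events: at each drive activation the pair (layer-1
    state just before, layer-2 state just after) increments T_F; each
    deactivation increments T_B symmetrically.  Rows are normalized where
    observed."""
    cF = np.zeros((n_states_1, n_states_2))
    cB = np.zeros((n_states_2, n_states_1))
    n_events = 0
    for seq in dual_sequences:
        for i in range(len(seq.layers) - 1):
            a, b = seq.layers[i], seq.layers[i + 1]
            if a == 0 and b == 1:
                cF[seq.states[i], seq.states[i + 1]] += 1
                n_events += 1
            elif a == 1 and b == 0:
                cB[seq.states[i], seq.states[i + 1]] += 1
                n_events += 1
    if cF.sum() == 0 or cB.sum() == 0:
        raise ValueError(
            "need at least one activation and one deactivation event"
        )
    def _norm(c):
        m = np.zeros_like(c)
        rs = c.sum(axis=1)
        nz = rs > 0
        m[nz] = c[nz] / rs[nz, None]
        return m

    lj = LevelJumpMatrices(
        T_F=_norm(cF),
        T_B=_norm(cB),
        counts_F=cF.sum(axis=1),
        counts_B=cB.sum(axis=1),
    )
    if len(lj.unobserved_F) or len(lj.unobserved_B):
        warnings.warn(
            f"{len(lj.unobserved_F)} forward / {len(lj.unobserved_B)} "
            "backward jump rows unobserved; nearest-energy fallback applies",
            stacklevel=2,
        )
    return lj


def trap_states(msm1: MSM, trap: TrapRegion) -> set[int]:
    """Layer-1 states whose representative mean trend lies inside the
    closed trap interval: the states from which drive activation occurs."""
    return {
        s
        for s in range(msm1.N_s)
        if bool(trap.contains(float(msm1.state_coords[s, 1])))
    }


@dataclass
class DrivenMSM:
    """The two equilibrium MSMs joined by level-jumping matrices plus the
    activation rule (trap state set, decision interval, shock duration)."""

    layer1: MSM
    layer2: MSM
    jumps: LevelJumpMatrices
    trap_state_ids: set[int]
    tau_beast_1: float
    tau_neq: float
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.trap_state_ids) <= set(range(self.layer1.N_s)):
            raise ValueError("trap states must be layer-1 states")
        if self.tau_neq >= self.tau_beast_1:
            raise ValueError("tau_neq must be shorter than tau_beast_1")

    def to_dict(self) -> dict:
        return {
            "layer1": self.layer1.to_dict(),
            "layer2": self.layer2.to_dict(),
            "T_F": self.jumps.T_F.tolist(),
            "T_B": self.jumps.T_B.tolist(),
            "counts_F": self.jumps.counts_F.tolist(),
            "counts_B": self.jumps.counts_B.tolist(),
            "trap_state_ids": sorted(self.trap_state_ids),
            "tau_beast_1": self.tau_beast_1,
            "tau_neq": self.tau_neq,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DrivenMSM":
        jumps = LevelJumpMatrices(
            T_F=np.asarray(d["T_F"], dtype=float),
            T_B=np.asarray(d["T_B"], dtype=float),
            counts_F=np.asarray(d["counts_F"], dtype=float),
            counts_B=np.asarray(d["counts_B"], dtype=float),
        )
        return cls(
            layer1=MSM.from_dict(d["layer1"]),
            layer2=MSM.from_dict(d["layer2"]),
            jumps=jumps,
            trap_state_ids=set(d["trap_state_ids"]),
            tau_beast_1=float(d["tau_beast_1"]),
            tau_neq=float(d["tau_neq"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "DrivenMSM":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_driven_msm(
    msm1: MSM,
    msm2: MSM,
    omega_neq: SLMDataset,
    trap: TrapRegion,
    tau_beast_1: float,
    tau_neq: float,
) -> DrivenMSM:
    """Assemble the driven MSM from the two equilibrium models, the driven
    dataset (for the level-jumping matrices) and the activation rule."""
    if msm1.binning is None or msm2.binning is None:
        raise ValueError("equilibrium MSMs must carry their binning vectors")
    if msm1.N_s != msm1.binning.N_s or msm2.N_s != msm2.binning.N_s:
        raise ValueError(
            "equilibrium MSM dropped unvisited binning states; jump-matrix "
            "indexing requires the full binning state space"
        )
    dual = map_segments_dual(omega_neq, msm1.binning, msm2.binning)
    # map binning-space states down to the MSMs' retained state spaces via
    # clamped coordinates: the binning vectors here are the full training
    # binnings, so ids coincide unless states were dropped at estimation
    jumps_full = build_jump_matrices(
        dual, msm1.binning.N_s, msm2.binning.N_s
    )
    return DrivenMSM(
        layer1=msm1,
        layer2=msm2,
        jumps=jumps_full,
        trap_state_ids=trap_states(msm1, trap),
        tau_beast_1=tau_beast_1,
        tau_neq=tau_neq,
    )


def _nearest_energy_state(energy: float, coords: np.ndarray) -> int:
    return int(np.argmin(np.abs(coords[:, 0] - energy)))


def _draw_row(
    row: np.ndarray, count: float, from_energy: float,
    dest_coords: np.ndarray, rng: np.random.Generator,
) -> int:
    if count > 0:
        return int(np.searchsorted(np.cumsum(row), rng.random(), side="right"))
    # unobserved row: deterministic nearest-mean-energy fallback
    return _nearest_energy_state(from_energy, dest_coords)


def simulate_driven(
    driven: DrivenMSM,
    n_realizations: int,
    horizon: float,
    seed: int = 0,
    tau_neq: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Simulate the two-layer chain.

    Layer 1 evolves from the configuration-1 initial distribution.  At each
    ``tau_beast_1`` boundary, a realization occupying a trap state jumps to
    layer 2 via T_F, dwells there for ``tau_neq`` seconds (the stored
    learning value unless overridden — the override is the generalization
    mode), and returns via T_B.  FA in either layer terminates.  Returns
    (flags, T_FAS samples, T_Drive) where T_Drive is the ensemble-mean
    total drive-on duration in seconds.
    """
    if tau_neq is None:
        tau_neq = driven.tau_neq
    if tau_neq >= driven.tau_beast_1:
        warnings.warn("tau_neq >= tau_beast_1: shocks overlap decisions",
                      stacklevel=2)
    if not driven.trap_state_ids or tau_neq == 0:
        # null control: the drive never engages, so the chain is exactly the
        # layer-1 equilibrium MSM (shared seed gives identical statistics)
        from .msm_equilibrium import simulate_msm

        flags, t_fas = simulate_msm(
            driven.layer1, n_realizations, horizon, seed
        )
        return flags, t_fas, 0.0
    m1, m2, lj = driven.layer1, driven.layer2, driven.jumps
    rng = np.random.default_rng(seed)
    tau = driven.tau_beast_1
    cum1 = np.cumsum(m1.P, axis=1)
    cum2 = np.cumsum(m2.P, axis=1)
    pi0c = np.cumsum(m1.pi0)
    flags = np.zeros(n_realizations, dtype=int)
    t_fas = np.full(n_realizations, float(horizon))
    t_drive = np.zeros(n_realizations)

    for r in range(n_realizations):
        s = int(np.searchsorted(pi0c, rng.random(), side="right"))
        t = 0.0
        boundary = tau
        while t < horizon:
            if s == m1.FA:
                flags[r] = 1
                t_fas[r] = t
                break
            # evolve layer 1 until the next decision boundary
            dwell = rng.exponential(m1.T_bar[s])
            if t + dwell < boundary:
                t += dwell
                nxt = int(np.searchsorted(cum1[s], rng.random(), side="right"))
                if nxt == s:  # censored sink: stays put until a boundary
                    t = boundary
                else:
                    s = nxt
                    continue
            else:
                t = boundary
            if t >= horizon:
                break
            boundary += tau
            if s != m1.FA and s in driven.trap_state_ids and tau_neq > 0:
                # activation: jump up, evolve in layer 2 for tau_neq
                e1 = float(m1.state_coords[s, 0]) if s < m1.N_s else 0.0
                s2 = _draw_row(
                    lj.T_F[s], lj.counts_F[s], e1, m2.state_coords, rng
                )
                t_act = t
                t_end = min(t_act + tau_neq, horizon)
                while t < t_end and s2 != m2.FA:
                    d2 = rng.exponential(m2.T_bar[s2])
                    if t + d2 >= t_end:
                        t = t_end
                        break
                    t += d2
                    nxt = int(
                        np.searchsorted(cum2[s2], rng.random(), side="right")
                    )
                    if nxt == s2:
                        t = t_end
                        break
                    s2 = nxt
                t_drive[r] += t - t_act
                if s2 == m2.FA:
                    flags[r] = 1
                    t_fas[r] = t
                    break
                # deactivation: jump back down
                e2 = float(m2.state_coords[s2, 0]) if s2 < m2.N_s else 0.0
                s = _draw_row(
                    lj.T_B[s2], lj.counts_B[s2], e2, m1.state_coords, rng
                )
    return flags, t_fas, float(t_drive.mean())
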