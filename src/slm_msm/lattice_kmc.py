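"""Kinetic Monte Carlo simulator of lattice self-assembly.

Distinguishable particles live on a 2D lattice and carry a discrete internal
state.  Nearest-neighbour pair energies are dictated by the designed target
structure(s): a designed partner pair in its required internal states binds
strongly (``J_s``), a designed weak contact binds with ``J_w``, and every
other contact is non-interacting.  Dynamics are rejection-free (Gillespie)
kinetic Monte Carlo over single-site hops and internal-state flips with the
symmetric detailed-balance rate form ``nu * exp(-dE/2)`` (energies in units
of k_B T).

The event loop is compiled with numba; the module-level operations
(`pair_energy`, `enumerate_moves`, `move_rate`, `kmc_step`, ...) are thin
wrappers over the same compiled kernels, so the single-step API and the
ensemble runner share one implementation of the physics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from numba import njit

__all__ = [
    "ModelParams",
    "TargetStructure",
    "LatticeState",
    "EnergyTrajectory",
    "Move",
    "pair_energy",
    "total_energy",
    "build_pair_table",
    "enumerate_moves",
    "move_rate",
    "kmc_step",
    "detect_assembly",
    "scale_energies",
    "random_initial_state",
    "KMCSimulation",
    "run_equilibrium",
]

# 4-neighbourhood, fixed order: up, down, left, right
_DR = np.array([-1, 1, 0, 0], dtype=np.int64)
_DC = np.array([0, 0, -1, 1], dtype=np.int64)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Physical and numerical parameters of the lattice KMC model.

    Energies are in units of k_B T (attractive bonds are negative), rate
    prefactors in 1/s.  ``|J_s| > |J_w|`` and both must be attractive.
    """

    lattice_width: int
    lattice_height: int
    n_particles: int
    J_s: float = -3.6
    J_w: float = -1.0
    n_internal_states: int = 2
    nu_trans: float = 1.0
    nu_state: float = 1.0
    N_steps: int = 100_000
    boundary: str = "closed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J_s >= 0 or self.J_w >= 0:
            raise ValueError("bond energies must be attractive (negative)")
        if abs(self.J_s) <= abs(self.J_w):
            raise ValueError("|J_s| must exceed |J_w|")
        if self.nu_trans <= 0 or self.nu_state <= 0:
            raise ValueError("rate prefactors must be positive")
        if self.n_particles > self.lattice_width * self.lattice_height:
            raise ValueError("more particles than lattice sites")
        if self.n_internal_states < 1:
            raise ValueError("need at least one internal state")
        if self.boundary not in ("closed", "periodic"):
            raise ValueError("boundary must be 'closed' or 'periodic'")
        if self.boundary == "periodic" and (
            self.lattice_width < 3 or self.lattice_height < 3
        ):
            raise ValueError("periodic boundary requires lattice >= 3x3")

    @property
    def periodic(self) -> bool:
        return self.boundary == "periodic"

    def to_dict(self) -> dict:
        return {
            "lattice_width": self.lattice_width,
            "lattice_height": self.lattice_height,
            "n_particles": self.n_particles,
            "J_s": self.J_s,
            "J_w": self.J_w,
            "n_internal_states": self.n_internal_states,
            "nu_trans": self.nu_trans,
            "nu_state": self.nu_state,
            "N_steps": self.N_steps,
            "boundary": self.boundary,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


def _normalize_pair(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class TargetStructure:
    """A designed target: particle ``particle_ids[k]`` belongs at
    ``offsets[k]`` (relative lattice coordinates, row-major) in internal
    state ``required_states[k]``.

    ``strong_bond_pairs`` are pairs of *offset indices* that are designed to
    bind with ``J_s``; every other adjacent offset pair in the design is a
    weak contact (``J_w``).  Offsets must form a connected cluster under the
    4-neighbourhood and strong pairs must be adjacent in the design.
    """

    offsets: tuple[tuple[int, int], ...]
    required_states: tuple[int, ...]
    strong_bond_pairs: frozenset[tuple[int, int]]
    particle_ids: tuple[int, ...] | None = None
    allow_rotations: bool = False

    def __post_init__(self) -> None:
        n = len(self.offsets)
        if n == 0:
            raise ValueError("target must contain at least one site")
        if len(self.required_states) != n:
            raise ValueError("required_states length mismatch")
        if self.particle_ids is not None and len(self.particle_ids) != n:
            raise ValueError("particle_ids length mismatch")
        if len(set(self.offsets)) != n:
            raise ValueError("duplicate offsets in target")
        adj = self._adjacent_index_pairs()
        for pair in self.strong_bond_pairs:
            if _normalize_pair(*pair) not in adj:
                raise ValueError(f"strong bond pair {pair} is not adjacent")
        # connectivity under 4-neighbourhood
        if n > 1:
            seen = {0}
            frontier = [0]
            offs = {o: k for k, o in enumerate(self.offsets)}
            while frontier:
                k = frontier.pop()
                r, c = self.offsets[k]
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    j = offs.get((r + dr, c + dc))
                    if j is not None and j not in seen:
                        seen.add(j)
                        frontier.append(j)
            if len(seen) != n:
                raise ValueError("target offsets are not connected")

    def _adjacent_index_pairs(self) -> set[tuple[int, int]]:
        offs = {o: k for k, o in enumerate(self.offsets)}
        pairs = set()
        for k, (r, c) in enumerate(self.offsets):
            for dr, dc in ((0, 1), (1, 0)):
                j = offs.get((r + dr, c + dc))
                if j is not None:
                    pairs.add(_normalize_pair(k, j))
        return pairs

    @property
    def ids(self) -> tuple[int, ...]:
        if self.particle_ids is not None:
            return self.particle_ids
        return tuple(range(len(self.offsets)))

    @property
    def weak_contact_pairs(self) -> frozenset[tuple[int, int]]:
        strong = {_normalize_pair(*p) for p in self.strong_bond_pairs}
        return frozenset(self._adjacent_index_pairs() - strong)

    def offset_variants(self) -> np.ndarray:
        """All placements to test: (n_variants, n, 2) int64, each variant
        normalized so min row/col is 0.  Translations always; the 8
        rotations/reflections when ``allow_rotations``."""
        base = np.asarray(self.offsets, dtype=np.int64)
        mats = [np.array([[1, 0], [0, 1]])]
        if self.allow_rotations:
            rot = np.array([[0, -1], [1, 0]])
            refl = np.array([[1, 0], [0, -1]])
            ms = []
            m = np.eye(2, dtype=np.int64)
            for _ in range(4):
                ms.append(m.copy())
                ms.append(m @ refl)
                m = m @ rot
            mats = ms
        variants = []
        seen = set()
        for m in mats:
            v = base @ np.asarray(m, dtype=np.int64).T
            v = v - v.min(axis=0)
            key = tuple(map(tuple, v))
            if key not in seen:
                seen.add(key)
                variants.append(v)
        return np.stack(variants)

    def to_dict(self) -> dict:
        return {
            "offsets": [list(o) for o in self.offsets],
            "required_states": list(self.required_states),
            "strong_bond_pairs": sorted(
                [list(_normalize_pair(*p)) for p in self.strong_bond_pairs]
            ),
            "particle_ids": None
            if self.particle_ids is None
            else list(self.particle_ids),
            "allow_rotations": self.allow_rotations,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TargetStructure":
        return cls(
            offsets=tuple(tuple(o) for o in d["offsets"]),
            required_states=tuple(d["required_states"]),
            strong_bond_pairs=frozenset(
                tuple(p) for p in d["strong_bond_pairs"]
            ),
            particle_ids=None
            if d.get("particle_ids") is None
            else tuple(d["particle_ids"]),
            allow_rotations=bool(d.get("allow_rotations", False)),
        )


@dataclass
class LatticeState:
    """Occupancy grid (-1 = empty, else particle id), per-particle internal
    states, and the incrementally tracked total energy in k_B T."""

    occupancy: np.ndarray
    internal_state: np.ndarray
    energy: float = 0.0

    def positions(self) -> np.ndarray:
        """(n_particles, 2) row/col of each particle."""
        n = self.internal_state.shape[0]
        pos = np.empty((n, 2), dtype=np.int64)
        rows, cols = np.nonzero(self.occupancy >= 0)
        for r, c in zip(rows, cols):
            pos[self.occupancy[r, c]] = (r, c)
        return pos

    def copy(self) -> "LatticeState":
        return LatticeState(
            self.occupancy.copy(), self.internal_state.copy(), self.energy
        )


@dataclass
class EnergyTrajectory:
    """Energy time series of one realization plus assembly metadata.

    ``times`` are event times in seconds (strictly increasing, starting at
    0), ``energies`` the total energy after each event, ``drive_intervals``
    the scheduled shock (on, off) times, ``T_FAS`` the first-assembly time
    (equal to the final time when unassembled, with ``assembled_flag`` 0).
    """

    times: np.ndarray
    energies: np.ndarray
    kmc_step_index: np.ndarray
    assembled_flag: int
    T_FAS: float
    drive_intervals: list[tuple[float, float]] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        ivs = self.drive_intervals
        for k in range(1, len(ivs)):
            if ivs[k][0] < ivs[k - 1][1]:
                raise ValueError("drive intervals must be ordered, disjoint")
        if self.assembled_flag and len(self.times) and self.T_FAS > self.times[-1]:
            raise ValueError("T_FAS beyond trajectory end")

    @property
    def n_events(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Move:
    """An elementary KMC move: a hop of ``particle`` to ``(row, col)`` or a
    flip of its internal state to ``new_state``."""

    kind: str  # "hop" | "flip"
    particle: int
    row: int = -1
    col: int = -1
    new_state: int = -1


# ---------------------------------------------------------------------------
# pair energies
# ---------------------------------------------------------------------------

def build_pair_table(
    params: ModelParams, targets: Sequence[TargetStructure]
) -> np.ndarray:
    """Dense pair-energy lookup ``E[i, j, s_i, s_j]`` over particle ids and
    internal states.  Designed strong pairs in their required states get
    ``J_s``, designed weak contacts in required states ``J_w``, everything
    else 0.  Symmetric in (i, s_i) <-> (j, s_j)."""
    n, q = params.n_particles, params.n_internal_states
    table = np.zeros((n, n, q, q), dtype=np.float64)
    for tgt in targets:
        if max(tgt.required_states, default=0) >= q:
            raise ValueError("target required state outside state space")
        if max(tgt.ids, default=0) >= n:
            raise ValueError("target particle id outside particle set")
    # weak contacts first so that a strong designation from any stored
    # target takes precedence on conflicting cells
    for strong_pass in (False, True):
        for tgt in targets:
            ids, req = tgt.ids, tgt.required_states
            pairs = tgt.strong_bond_pairs if strong_pass else tgt.weak_contact_pairs
            J = params.J_s if strong_pass else params.J_w
            for a, b in pairs:
                i, j = ids[a], ids[b]
                si, sj = req[a], req[b]
                table[i, j, si, sj] = J
                table[j, i, sj, si] = J
    return table


def pair_energy(
    state_a: int,
    state_b: int,
    pair: tuple[int, int],
    params: ModelParams,
    targets: Sequence[TargetStructure],
) -> float:
    """Interaction energy (k_B T) of adjacent particles ``pair = (i, j)``
    with internal states ``state_a``/``state_b``."""
    q = params.n_internal_states
    if not (0 <= state_a < q and 0 <= state_b < q):
        raise ValueError("invalid internal state index")
    table = build_pair_table(params, targets)
    return float(table[pair[0], pair[1], state_a, state_b])


def total_energy(
    state: LatticeState,
    params: ModelParams,
    targets: Sequence[TargetStructure],
) -> float:
    """Full recomputation of the total energy: sum of pair energies over all
    occupied nearest-neighbour pairs (each counted once)."""
    table = build_pair_table(params, targets)
    return _total_energy_core(
        state.occupancy, state.internal_state, table, params.periodic
    )


@njit(cache=True)
def _total_energy_core(occ, states, table, periodic):
    H, W = occ.shape
    e = 0.0
    for r in range(H):
        for c in range(W):
            i = occ[r, c]
            if i < 0:
                continue
            # right and down neighbours only -> each pair once
            for d in range(2):
                rr = r + (1 if d == 0 else 0)
                cc = c + (0 if d == 0 else 1)
                if periodic:
                    rr %= H
                    cc %= W
                elif rr >= H or cc >= W:
                    continue
                j = occ[rr, cc]
                if j >= 0:
                    e += table[i, j, states[i], states[j]]
    return e


# ---------------------------------------------------------------------------
# compiled kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _local_energy(occ, states, table, i, si, r, c, periodic):
    """Interaction energy of particle i (in state si) sitting at (r, c)
    with its current neighbours (excluding itself)."""
    H, W = occ.shape
    e = 0.0
    for d in range(4):
        rr = r + _DR[d]
        cc = c + _DC[d]
        if periodic:
            rr %= H
            cc %= W
        elif rr < 0 or rr >= H or cc < 0 or cc >= W:
            continue
        j = occ[rr, cc]
        if j >= 0 and j != i:
            e += table[i, j, si, states[j]]
    return e


@njit(cache=True)
def _move_delta_e(occ, pos, states, table, periodic, m, q):
    """Energy change of move index m (hops first, then flips)."""
    n = pos.shape[0]
    H, W = occ.shape
    if m < 4 * n:
        i = m // 4
        d = m % 4
        r, c = pos[i, 0], pos[i, 1]
        rr = r + _DR[d]
        cc = c + _DC[d]
        if periodic:
            rr %= H
            cc %= W
        occ[r, c] = -1  # vacate, compute both local energies, restore
        e_old = _local_energy(occ, states, table, i, states[i], r, c, periodic)
        e_new = _local_energy(occ, states, table, i, states[i], rr, cc, periodic)
        occ[r, c] = i
        return e_new - e_old
    m -= 4 * n
    i = m // (q - 1)
    k = m % (q - 1)
    s_old = states[i]
    s_new = k if k < s_old else k + 1
    r, c = pos[i, 0], pos[i, 1]
    e_old = _local_energy(occ, states, table, i, s_old, r, c, periodic)
    e_new = _local_energy(occ, states, table, i, s_new, r, c, periodic)
    return e_new - e_old


@njit(cache=True)
def _compute_rates(occ, pos, states, table, nu_trans, nu_state, periodic, rates):
    """Fill per-move rates (0 for blocked hops); returns total rate.

    Move ordering: for particle i, hops in direction order (up, down, left,
    right) occupy indices 4*i..4*i+3; flips follow, (q-1) per particle in
    ascending new-state order."""
    n = pos.shape[0]
    H, W = occ.shape
    nq = (rates.shape[0] - 4 * n) // n + 1  # q recovered from the layout
    total = 0.0
    for i in range(n):
        r, c = pos[i, 0], pos[i, 1]
        for d in range(4):
            m = 4 * i + d
            rr = r + _DR[d]
            cc = c + _DC[d]
            if periodic:
                rr %= H
                cc %= W
            elif rr < 0 or rr >= H or cc < 0 or cc >= W:
                rates[m] = 0.0
                continue
            if occ[rr, cc] >= 0:
                rates[m] = 0.0
                continue
            de = _move_delta_e(occ, pos, states, table, periodic, m, nq)
            rates[m] = nu_trans * math.exp(-0.5 * de)
            total += rates[m]
    for i in range(n):
        for k in range(nq - 1):
            m = 4 * n + i * (nq - 1) + k
            de = _move_delta_e(occ, pos, states, table, periodic, m, nq)
            rates[m] = nu_state * math.exp(-0.5 * de)
            total += rates[m]
    return total


@njit(cache=True)
def _apply_move(occ, pos, states, m, q):
    n = pos.shape[0]
    if m < 4 * n:
        i = m // 4
        d = m % 4
        H, W = occ.shape
        r, c = pos[i, 0], pos[i, 1]
        rr = (r + _DR[d]) % H
        cc = (c + _DC[d]) % W
        occ[r, c] = -1
        occ[rr, cc] = i
        pos[i, 0] = rr
        pos[i, 1] = cc
    else:
        m -= 4 * n
        i = m // (q - 1)
        k = m % (q - 1)
        s_old = states[i]
        states[i] = k if k < s_old else k + 1


@njit(cache=True)
def _check_assembly(occ, pos, states, variants, pids, req, periodic):
    """variants: (n_var, n, 2); pids/req: (n_var, n).  Each row is one
    placement variant of one stored target (its particle ids and required
    states); true iff any variant is realized somewhere on the lattice."""
    H, W = occ.shape
    n_var = variants.shape[0]
    nk = variants.shape[1]
    for v in range(n_var):
        ar = pos[pids[v, 0], 0] - variants[v, 0, 0]
        ac = pos[pids[v, 0], 1] - variants[v, 0, 1]
        ok = True
        for k in range(nk):
            r = ar + variants[v, k, 0]
            c = ac + variants[v, k, 1]
            if periodic:
                r %= H
                c %= W
            elif r < 0 or r >= H or c < 0 or c >= W:
                ok = False
                break
            pid = pids[v, k]
            if occ[r, c] != pid or states[pid] != req[v, k]:
                ok = False
                break
        if ok:
            return True
    return False


def _stack_target_variants(
    targets: Sequence["TargetStructure"],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack placement variants of all stored targets into the flat arrays
    the compiled check consumes.  All targets must have the same number of
    sites (true of the packaged designs; a general mix would need ragged
    support)."""
    sizes = {len(t.offsets) for t in targets}
    if len(sizes) != 1:
        raise NotImplementedError("stored targets must be of equal size")
    var_list, pid_list, req_list = [], [], []
    for tgt in targets:
        v = tgt.offset_variants()
        var_list.append(v)
        pid_list.append(
            np.broadcast_to(
                np.asarray(tgt.ids, dtype=np.int64), (v.shape[0], v.shape[1])
            )
        )
        req_list.append(
            np.broadcast_to(
                np.asarray(tgt.required_states, dtype=np.int64),
                (v.shape[0], v.shape[1]),
            )
        )
    return (
        np.ascontiguousarray(np.concatenate(var_list)),
        np.ascontiguousarray(np.concatenate(pid_list)),
        np.ascontiguousarray(np.concatenate(req_list)),
    )


@njit(cache=True)
def _seed_rng(seed):
    np.random.seed(seed)


# status codes returned by _run
_STATUS_TIME = 0
_STATUS_ASSEMBLED = 1
_STATUS_STEPS = 2
_STATUS_ZERO_RATE = 3


@njit(cache=True)
def _run(
    occ,
    pos,
    states,
    table,
    variants,
    pids,
    req,
    nu_trans,
    nu_state,
    periodic,
    q,
    t_start,
    t_end,
    max_steps,
    energy0,
    times,
    energies,
):
    """Advance until t_end, assembly, or max_steps applied events.

    Returns (t, energy, n_steps_done, status, n_recorded).  Events are
    recorded into times/energies from index 0.  The waiting time drawn when
    crossing t_end is discarded (exact by memorylessness)."""
    n = pos.shape[0]
    rates = np.empty(4 * n + n * (q - 1), dtype=np.float64)
    t = t_start
    e = energy0
    n_rec = 0
    steps = 0
    if _check_assembly(occ, pos, states, variants, pids, req, periodic):
        return t, e, steps, _STATUS_ASSEMBLED, n_rec
    while steps < max_steps:
        total = _compute_rates(
            occ, pos, states, table, nu_trans, nu_state, periodic, rates
        )
        if total <= 0.0:
            return t, e, steps, _STATUS_ZERO_RATE, n_rec
        u1 = np.random.random()
        dt = -math.log(1.0 - u1) / total
        if t + dt > t_end:
            t = t_end
            return t, e, steps, _STATUS_TIME, n_rec
        t += dt
        u2 = np.random.random() * total
        acc = 0.0
        chosen = rates.shape[0] - 1
        for m in range(rates.shape[0]):
            acc += rates[m]
            if u2 < acc:
                chosen = m
                break
        de = _move_delta_e(occ, pos, states, table, periodic, chosen, q)
        _apply_move(occ, pos, states, chosen, q)
        e += de
        steps += 1
        times[n_rec] = t
        energies[n_rec] = e
        n_rec += 1
        if _check_assembly(occ, pos, states, variants, pids, req, periodic):
            return t, e, steps, _STATUS_ASSEMBLED, n_rec
    return t, e, steps, _STATUS_STEPS, n_rec


# ---------------------------------------------------------------------------
# python-level operations
# ---------------------------------------------------------------------------

def enumerate_moves(
    state: LatticeState, params: ModelParams
) -> list[Move]:
    """All candidate moves from ``state``: hops to vacant in-lattice
    neighbour sites and single internal-state flips, in the fixed kernel
    ordering (deterministic given the state)."""
    occ = state.occupancy
    H, W = occ.shape
    pos = state.positions()
    q = params.n_internal_states
    moves: list[Move] = []
    for i in range(params.n_particles):
        r, c = int(pos[i, 0]), int(pos[i, 1])
        for d in range(4):
            rr, cc = r + int(_DR[d]), c + int(_DC[d])
            if params.periodic:
                rr, cc = rr % H, cc % W
            elif not (0 <= rr < H and 0 <= cc < W):
                continue
            if occ[rr, cc] < 0:
                moves.append(Move("hop", i, row=rr, col=cc))
    for i in range(params.n_particles):
        s = int(state.internal_state[i])
        for s_new in range(q):
            if s_new != s:
                moves.append(Move("flip", i, new_state=s_new))
    return moves


def move_rate(delta_E: float, kind: str, params: ModelParams) -> float:
    """Symmetric detailed-balance rate ``nu_kind * exp(-delta_E / 2)``
    (k_B T = 1)."""
    if not math.isfinite(delta_E):
        raise ValueError("delta_E must be finite")
    nu = params.nu_trans if kind == "hop" else params.nu_state
    return nu * math.exp(-0.5 * delta_E)


def _move_index(move: Move, state: LatticeState, params: ModelParams) -> int:
    n, q = params.n_particles, params.n_internal_states
    if move.kind == "hop":
        pos = state.positions()
        r, c = int(pos[move.particle, 0]), int(pos[move.particle, 1])
        H, W = state.occupancy.shape
        for d in range(4):
            rr, cc = r + int(_DR[d]), c + int(_DC[d])
            if params.periodic:
                rr, cc = rr % H, cc % W
            if (rr, cc) == (move.row, move.col):
                return 4 * move.particle + d
        raise ValueError("hop target is not a neighbour site")
    s_old = int(state.internal_state[move.particle])
    k = move.new_state if move.new_state < s_old else move.new_state - 1
    return 4 * n + move.particle * (q - 1) + k


def kmc_step(
    state: LatticeState,
    params: ModelParams,
    targets: Sequence[TargetStructure],
    rng: np.random.Generator,
) -> tuple[LatticeState, float]:
    """One rejection-free KMC step: pick a move with probability proportional
    to its rate, draw an exponential waiting time with mean 1/(total rate),
    apply the move and update the energy incrementally.

    Returns the new state and the waiting time.  Mutates a copy; the input
    state is left untouched."""
    table = build_pair_table(params, targets)
    new = state.copy()
    occ, st = new.occupancy, new.internal_state
    pos = new.positions()
    n, q = params.n_particles, params.n_internal_states
    rates = np.empty(4 * n + n * (q - 1), dtype=np.float64)
    total = _compute_rates(
        occ, pos, st, table, params.nu_trans, params.nu_state,
        params.periodic, rates,
    )
    if total <= 0.0:
        raise RuntimeError("zero total rate: no move available")
    dt = rng.exponential(1.0 / total)
    chosen = int(rng.choice(rates.shape[0], p=rates / total))
    de = _move_delta_e(occ, pos, st, table, params.periodic, chosen, q)
    _apply_move(occ, pos, st, chosen, q)
    new.energy = state.energy + float(de)
    return new, float(dt)


def detect_assembly(
    state: LatticeState,
    targets: Sequence[TargetStructure],
) -> bool:
    """True iff some placement (translations; rotations/reflections when the
    target allows them) of any stored target is realized: the designed
    particles occupy the designed footprint in their required internal
    states.  Extra particles elsewhere do not matter."""
    if not targets:
        raise ValueError("empty target list")
    variants, pids, req = _stack_target_variants(targets)
    return bool(
        _check_assembly(
            state.occupancy, state.positions(), state.internal_state,
            variants, pids, req, False,
        )
    )


def scale_energies(params: ModelParams, rho: float) -> ModelParams:
    """Divide both bond energies by ``rho`` (drive shock weakening); all
    other fields unchanged.  ``rho <= 1`` is allowed but warned against for
    drive use (it would strengthen, not weaken, the bonds)."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    if rho <= 1:
        warnings.warn(
            "rho <= 1 does not weaken the bonds; drive semantics violated",
            stacklevel=2,
        )
    return replace(params, J_s=params.J_s / rho, J_w=params.J_w / rho)


def random_initial_state(
    params: ModelParams,
    targets: Sequence[TargetStructure],
    rng: np.random.Generator,
) -> LatticeState:
    """Particles placed uniformly over vacant sites with uniform internal
    states; energy initialized by full recomputation."""
    H, W = params.lattice_height, params.lattice_width
    occ = np.full((H, W), -1, dtype=np.int64)
    sites = rng.choice(H * W, size=params.n_particles, replace=False)
    for i, s in enumerate(sites):
        occ[s // W, s % W] = i
    states = rng.integers(
        0, params.n_internal_states, size=params.n_particles
    ).astype(np.int64)
    st = LatticeState(occ, states, 0.0)
    st.energy = total_energy(st, params, targets)
    return st


class KMCSimulation:
    """A single KMC realization advanced window by window.

    The driven-control loop needs to interleave simulation with segmentation
    and swap the interaction table during shocks, so the realization is
    exposed as a session: ``advance(t_end, pair_table=...)`` runs the
    compiled event loop up to a wall-clock boundary, first assembly, or the
    global step budget, appending events to the stored trajectory.

    All randomness derives from ``seed``: initial placement uses one child
    stream, the event loop another (the kernel RNG is seeded once at
    construction, so sessions must be advanced sequentially, not
    interleaved).
    """

    def __init__(
        self,
        params: ModelParams,
        targets: Sequence[TargetStructure],
        seed: int,
    ):
        if not targets:
            raise ValueError("empty target list")
        self.params = params
        self.targets = list(targets)
        self.seed = int(seed)
        ss = np.random.SeedSequence(seed)
        s_place, s_core = ss.generate_state(2)
        rng = np.random.default_rng(int(s_place))
        self.state = random_initial_state(params, targets, rng)
        _seed_rng(int(s_core % (2**31 - 1)))
        self._pos = self.state.positions()
        self.base_table = build_pair_table(params, targets)
        self._variants, self._pids, self._req = _stack_target_variants(targets)
        self.t = 0.0
        self.steps = 0
        self.times: list[np.ndarray] = [np.zeros(1)]
        self.energies: list[np.ndarray] = [np.array([self.state.energy])]
        self.assembled = _check_assembly(
            self.state.occupancy, self._pos, self.state.internal_state,
            self._variants, self._pids, self._req, params.periodic,
        )
        self.T_FAS: float | None = 0.0 if self.assembled else None

    @property
    def steps_remaining(self) -> int:
        return self.params.N_steps - self.steps

    def advance(
        self,
        t_end: float,
        pair_table: np.ndarray | None = None,
    ) -> str:
        """Run until ``t_end`` (or assembly / step budget) under the given
        interaction table (defaults to the base table).  Returns one of
        "time", "assembled", "steps"."""
        if self.assembled:
            return "assembled"
        if self.steps_remaining <= 0:
            return "steps"
        table = self.base_table if pair_table is None else pair_table
        cap = self.steps_remaining
        times = np.empty(cap, dtype=np.float64)
        energies = np.empty(cap, dtype=np.float64)
        p = self.params
        t, e, steps, status, n_rec = _run(
            self.state.occupancy,
            self._pos,
            self.state.internal_state,
            table,
            self._variants,
            self._pids,
            self._req,
            p.nu_trans,
            p.nu_state,
            p.periodic,
            p.n_internal_states,
            self.t,
            float(t_end),
            cap,
            self.state.energy,
            times,
            energies,
        )
        self.t = float(t)
        self.state.energy = float(e)
        self.steps += int(steps)
        if n_rec:
            self.times.append(times[:n_rec].copy())
            self.energies.append(energies[:n_rec].copy())
        if status == _STATUS_ASSEMBLED:
            self.assembled = True
            self.T_FAS = self.t
            return "assembled"
        if status == _STATUS_ZERO_RATE:
            raise RuntimeError("zero total rate during KMC run")
        if status == _STATUS_STEPS:
            return "steps"
        return "time"

    def trajectory(
        self, drive_intervals: Iterable[tuple[float, float]] = ()
    ) -> EnergyTrajectory:
        times = np.concatenate(self.times)
        energies = np.concatenate(self.energies)
        flag = 1 if self.assembled else 0
        t_fas = self.T_FAS if self.assembled else float(times[-1])
        return EnergyTrajectory(
            times=times,
            energies=energies,
            kmc_step_index=np.arange(len(times)),
            assembled_flag=flag,
            T_FAS=float(t_fas),
            drive_intervals=[tuple(iv) for iv in drive_intervals],
            seed=self.seed,
        )


def run_equilibrium(
    params: ModelParams,
    targets: Sequence[TargetStructure],
    horizon: int | None = None,
    seed: int = 0,
    tau_window: float | None = None,
) -> EnergyTrajectory:
    """One equilibrium realization from a random initial condition.

    Terminates at first assembly or after ``horizon`` KMC steps (defaults to
    ``params.N_steps``).  When ``tau_window`` is given the event loop is
    advanced in wall-clock windows of that duration (the pattern the driven
    controller uses), which leaves the law of the process unchanged but
    makes shared-seed comparisons with driven runs exact.
    """
    if horizon is None:
        horizon = params.N_steps
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    params = replace(params, N_steps=int(horizon))
    if horizon == 0:
        return EnergyTrajectory(
            times=np.zeros(0),
            energies=np.zeros(0),
            kmc_step_index=np.zeros(0, dtype=np.int64),
            assembled_flag=0,
            T_FAS=0.0,
            seed=seed,
        )
    sim = KMCSimulation(params, targets, seed)
    if tau_window is None or tau_window <= 0:
        while not sim.assembled and sim.steps_remaining > 0:
            sim.advance(np.inf)
    else:
        k = 1
        while not sim.assembled and sim.steps_remaining > 0:
            sim.advance(k * tau_window)
            k += 1
    return sim.trajectory()
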