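"""Tests for quantile binning, state sequences, CTMC estimation,
simulation, and the Markovianity diagnostics."""

import numpy as np
import pytest

from slm_msm.msm_equilibrium import (
    MSM,
    BinningVector,
    StateSequence,
    assign_states,
    build_msm,
    ck_test,
    dwell_exponential_fit_quality,
    estimate_msm,
    grid_step,
    implied_timescales,
    initial_distribution,
    merge_repeats,
    quantile_bins,
    select_lag,
    simulate_msm,
    to_uniform_grid,
)

from conftest import make_dataset


def simple_binning(n_states: int, coords=None) -> BinningVector:
    """One trend bin split into n_states energy cells at integer edges:
    state k covers energies in [k, k+1)."""
    if coords is None:
        coords = [(k + 0.5, 0.0) for k in range(n_states)]
    return BinningVector(
        trend_edges=np.empty(0),
        energy_edges=np.arange(1.0, n_states)[None, :],
        state_of_cell=np.arange(n_states)[None, :],
        state_coords=np.asarray(coords, dtype=float),
    )


class TestQuantileBins:
    def test_uniform_2x2_equal_occupancy(self):
        rng = np.random.default_rng(0)
        n = 400
        ds = make_dataset(rng.uniform(-1, 1, n), rng.uniform(-5, 0, n))
        b = quantile_bins(ds, 2, 2)
        assert b.N_s == 4
        states = b.cell_of(
            ds.segments["mean_energy"].to_numpy(),
            ds.segments["mean_trend"].to_numpy(),
        )
        occ = np.bincount(states, minlength=4)
        assert np.all(np.abs(occ - n / 4) <= n * 0.05)

    def test_single_segment(self):
        ds = make_dataset([0.3], [-2.0])
        b = quantile_bins(ds, 3, 3)
        assert b.N_s == 1

    def test_matches_sort_and_split_oracle(self):
        rng = np.random.default_rng(5)
        n = 200
        trends = rng.normal(0, 1, n)
        energies = rng.normal(-5, 2, n)
        ds = make_dataset(trends, energies)
        b = quantile_bins(ds, 2, 3)
        got = b.cell_of(energies, trends)
        # oracle: split sorted trends at the median, then each half into
        # energy terciles; label cells in (trend, energy) lexicographic order
        t_med = np.quantile(trends, 0.5)
        oracle = np.empty(n, dtype=int)
        label = 0
        labels = {}
        for tb in range(2):
            sel = trends > t_med if tb else trends <= t_med
            e_sel = energies[sel]
            edges = np.quantile(e_sel, [1 / 3, 2 / 3])
            for eb in range(3):
                labels[(tb, eb)] = label
                label += 1
            eb_idx = np.searchsorted(edges, e_sel, side="right")
            oracle[np.nonzero(sel)[0]] = [
                labels[(tb, int(e))] for e in eb_idx
            ]
        np.testing.assert_array_equal(got, oracle)

    def test_invalid_inputs(self):
        ds = make_dataset([0.1, 0.2])
        with pytest.raises(ValueError):
            quantile_bins(ds, 0, 2)


class TestAssignStates:
    def test_representative_coordinates_map_home(self, dataset_factory):
        rng = np.random.default_rng(1)
        ds = dataset_factory(rng.normal(0, 1, 120), rng.normal(-4, 2, 120))
        b = quantile_bins(ds, 2, 2)
        for s in range(b.N_s):
            e, t = b.state_coords[s]
            assert b.cell_of(e, t)[0] == s

    def test_out_of_range_clamps(self):
        ds = make_dataset([-0.5, 0.5], [0.0, 1.0])
        b = quantile_bins(ds, 1, 2)
        assert b.cell_of(999.0, 0.0)[0] == b.N_s - 1
        assert b.cell_of(-999.0, 0.0)[0] == 0

    def test_terminal_fa(self):
        ds = make_dataset([0.1, 0.2], traj_id=[0, 0], assembled=[1],
                          t_fas=[2.0])
        b = quantile_bins(ds, 1, 1)
        seqs = assign_states(ds, b)
        assert seqs[0].terminal_fa and seqs[0].T_FAS == 2.0


class TestMergeRepeats:
    def _seq(self, states, dwells):
        onsets = np.concatenate(([0.0], np.cumsum(dwells)[:-1]))
        return StateSequence(
            states=np.asarray(states), onsets=onsets,
            dwells=np.asarray(dwells, dtype=float),
            terminal_fa=False, T_FAS=float(sum(dwells)),
        )

    def test_adjacent_fused(self):
        m = merge_repeats(self._seq([0, 0, 1], [1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(m.states, [0, 1])
        np.testing.assert_allclose(m.dwells, [3.0, 3.0])
        assert m.onsets[0] == 0.0

    def test_no_repeats_unchanged(self):
        s = self._seq([0, 1, 2], [1.0, 1.0, 1.0])
        m = merge_repeats(s)
        np.testing.assert_array_equal(m.states, s.states)

    def test_all_same_state(self):
        m = merge_repeats(self._seq([3, 3, 3, 3], [1.0, 0.5, 0.5, 1.0]))
        assert len(m) == 1 and m.dwells[0] == pytest.approx(3.0)

    def test_idempotent(self):
        s = self._seq([0, 0, 1, 1, 0], [1, 2, 1, 1, 4])
        once = merge_repeats(s)
        twice = merge_repeats(once)
        np.testing.assert_array_equal(once.states, twice.states)
        np.testing.assert_allclose(once.dwells, twice.dwells)


class TestUniformGrid:
    def test_grid_step_rule(self):
        s = StateSequence(
            states=np.array([0, 1, 0]),
            onsets=np.array([0.0, 0.1, 0.25]),
            dwells=np.array([0.1, 0.15, 0.2]),
            terminal_fa=False, T_FAS=0.45,
        )
        assert grid_step([s]) == pytest.approx(5.0)

    def test_equal_gaps(self):
        s = StateSequence(
            states=np.array([0, 1]), onsets=np.array([0.0, 2.0]),
            dwells=np.array([2.0, 2.0]), terminal_fa=False, T_FAS=4.0,
        )
        assert grid_step([s]) == pytest.approx(100.0)

    def test_dwell_fractions_reconstructed(self):
        dt = 0.5
        s = StateSequence(
            states=np.array([0, 1]), onsets=np.array([0.0, 7.0]),
            dwells=np.array([7.0, 5.0]), terminal_fa=False, T_FAS=12.0,
        )
        labels = to_uniform_grid(s, dt, fa_state=2)
        for state, dwell in ((0, 7.0), (1, 5.0)):
            got = np.sum(labels == state) * dt
            assert abs(got - dwell) <= dt + 1e-9

    def test_fa_tick_appended(self):
        s = StateSequence(
            states=np.array([0]), onsets=np.array([0.0]),
            dwells=np.array([1.0]), terminal_fa=True, T_FAS=1.0,
        )
        labels = to_uniform_grid(s, 0.25, fa_state=9)
        assert labels[-1] == 9 and np.all(labels[:-1] == 0)


class TestInitialDistribution:
    def _seq(self, first):
        return StateSequence(
            states=np.array([first]), onsets=np.array([0.0]),
            dwells=np.array([1.0]), terminal_fa=False, T_FAS=1.0,
        )

    def test_point_mass(self):
        pi0 = initial_distribution([self._seq(3)] * 5, 4)
        assert pi0[3] == 1.0

    def test_half_half(self):
        seqs = [self._seq(0), self._seq(0), self._seq(1), self._seq(1)]
        pi0 = initial_distribution(seqs, 2)
        np.testing.assert_allclose(pi0, [0.5, 0.5, 0.0])

    def test_counting_oracle(self):
        rng = np.random.default_rng(2)
        firsts = rng.integers(0, 4, 300)
        pi0 = initial_distribution([self._seq(f) for f in firsts], 4)
        np.testing.assert_allclose(
            pi0[:4], np.bincount(firsts, minlength=4) / 300
        )
        assert pi0.sum() == pytest.approx(1.0)


class TestSelectLag:
    def _seqs(self, t_min):
        return [StateSequence(
            states=np.array([0]), onsets=np.array([0.0]),
            dwells=np.array([t_min]), terminal_fa=True, T_FAS=t_min,
        )]

    def test_floor_to_grid(self):
        assert select_lag(self._seqs(10.0), 0.5) == pytest.approx(2.0)

    def test_boundary(self):
        assert select_lag(self._seqs(2.5), 0.5) == pytest.approx(0.5)

    def test_clamp_warns(self):
        with pytest.warns(UserWarning):
            lag = select_lag(self._seqs(1.9), 0.5)
        assert lag == 0.5


class TestEstimateMSM:
    def test_hand_counted_toy(self):
        """Two trajectories [1,1,2,FA] and [1,2,2,FA] on lag ticks give
        P(1->2) = P(2->FA) = 1 and mean dwells of 1.5 lag each."""
        lag = 1.0
        b = simple_binning(3)
        seqs = []
        for states in ([1, 1, 2], [1, 2, 2]):
            onsets = np.arange(len(states), dtype=float)
            seqs.append(StateSequence(
                states=np.array(states), onsets=onsets,
                dwells=np.ones(len(states)), terminal_fa=True,
                T_FAS=float(len(states)),
            ))
        msm = estimate_msm(seqs, lag, b, dt=lag)
        # state 0 never visited -> dropped; retained ids: {1->0, 2->1, FA=2}
        assert msm.N_s == 2
        assert msm.P[0, 1] == 1.0
        assert msm.P[1, 2] == 1.0
        np.testing.assert_allclose(msm.T_bar[:2], [1.5, 1.5])

    def test_rows_stochastic_and_fa_absorbing(self, dataset_factory):
        rng = np.random.default_rng(4)
        n = 300
        ds = dataset_factory(
            rng.normal(0, 1, n), rng.normal(-3, 1, n),
            traj_id=np.repeat(np.arange(30), 10),
            assembled=rng.integers(0, 2, 30),
        )
        msm = build_msm(ds, 2, 2)
        np.testing.assert_allclose(msm.P.sum(axis=1), 1.0, atol=1e-9)
        assert msm.P[msm.FA, msm.FA] == 1.0

    def test_censored_sink_flagged(self):
        b = simple_binning(2)
        seqs = [StateSequence(
            states=np.array([0]), onsets=np.array([0.0]),
            dwells=np.array([5.0]), terminal_fa=False, T_FAS=5.0,
        )]
        with pytest.warns(UserWarning):
            msm = estimate_msm(seqs, 1.0, b, dt=1.0)
        assert msm.flags["censored_sinks"] == [0]
        assert msm.P[0, 0] == 1.0


class TestSimulateMSM:
    def _msm(self, P, T_bar, pi0, coords=None):
        n = len(T_bar) - 1
        return MSM(
            P=np.asarray(P, dtype=float),
            T_bar=np.asarray(T_bar, dtype=float),
            pi0=np.asarray(pi0, dtype=float),
            state_coords=np.asarray(
                coords if coords is not None
                else [(0.0, 0.0)] * n
            ),
            lag=1.0, FA=n,
        )

    def test_start_at_fa(self):
        msm = self._msm([[0, 1], [0, 1]], [1.0, np.inf], [0, 1])
        flags, t_fas = simulate_msm(msm, 200, 10.0, seed=0)
        assert flags.all() and np.all(t_fas == 0.0)

    def test_no_path_to_fa(self):
        P = [[0.5, 0.5, 0], [0.5, 0.5, 0], [0, 0, 1]]
        msm = self._msm(P, [1.0, 1.0, np.inf], [0.5, 0.5, 0.0],
                        coords=[(0, 0), (1, 0)])
        flags, _ = simulate_msm(msm, 300, 50.0, seed=1)
        assert flags.sum() == 0

    def test_exponential_mean_recovered(self):
        m = 2.0
        msm = self._msm([[0, 1], [0, 1]], [m, np.inf], [1, 0])
        flags, t_fas = simulate_msm(msm, 10_000, 1e6, seed=2)
        assert flags.all()
        se = m / np.sqrt(10_000)
        assert t_fas.mean() == pytest.approx(m, abs=3 * se)

    def test_yield_monotone_in_horizon(self):
        P = [[0.7, 0.3], [0.0, 1.0]]
        msm = self._msm(P, [1.0, np.inf], [1.0, 0.0])
        yields = [
            simulate_msm(msm, 800, h, seed=3)[0].mean()
            for h in (1.0, 5.0, 25.0)
        ]
        assert yields == sorted(yields)


class TestParameterRecovery:
    def test_small_ctmc_recovery(self):
        """Chain rebuilt from its own simulated trajectories recovers the
        jump probabilities and mean dwells (small fast version of the full
        recovery check)."""
        rng = np.random.default_rng(6)
        P_true = np.array([
            [0.0, 0.7, 0.3],
            [0.4, 0.0, 0.6],
            [0.0, 0.0, 1.0],
        ])
        T_true = np.array([8.0, 12.0])
        n_traj = 300
        seqs = []
        for _ in range(n_traj):
            s, t = 0, 0.0
            states, onsets, dwells = [], [], []
            while s != 2 and t < 600.0:
                d = rng.exponential(T_true[s])
                states.append(s)
                onsets.append(t)
                dwells.append(d)
                t += d
                s = rng.choice(3, p=P_true[s])
            seqs.append(StateSequence(
                states=np.array(states), onsets=np.array(onsets),
                dwells=np.array(dwells), terminal_fa=(s == 2), T_FAS=t,
            ))
        msm = estimate_msm(seqs, 0.2, simple_binning(2), dt=0.2)
        n01 = sum((np.array(q.states) == 0).sum() for q in seqs)
        for i in range(2):
            for j in range(3):
                if i == j:
                    continue
                se = np.sqrt(
                    P_true[i, j] * (1 - P_true[i, j]) / max(n01, 1)
                ) + 0.02
                assert msm.P[i, j] == pytest.approx(
                    P_true[i, j], abs=3 * se + 0.05
                )
            assert msm.T_bar[i] == pytest.approx(T_true[i], rel=0.15)


class TestImpliedTimescales:
    def test_markov_chain_flat(self):
        rng = np.random.default_rng(7)
        P = np.array([[0.9, 0.1], [0.2, 0.8]])
        seqs = []
        for _ in range(20):
            x = [0]
            for _ in range(3000):
                x.append(rng.choice(2, p=P[x[-1]]))
            seqs.append(np.array(x))
        its = implied_timescales(seqs, [1, 2, 4, 8], 2)
        t2 = its[:, 0]
        assert np.all(np.isfinite(t2))
        assert t2.max() / t2.min() < 1.25  # flat within sampling error

    def test_identity_matrix_infinite(self):
        seqs = [np.zeros(100, dtype=int), np.ones(100, dtype=int)]
        its = implied_timescales(seqs, [1, 2], 2)
        assert np.isinf(its[0, 0])

    def test_two_state_closed_form(self):
        P = np.array([[0.85, 0.15], [0.15, 0.85]])
        lam2 = 0.7  # second eigenvalue of the symmetric chain
        rng = np.random.default_rng(8)
        seqs = []
        for _ in range(30):
            x = [int(rng.random() < 0.5)]
            for _ in range(4000):
                x.append(rng.choice(2, p=P[x[-1]]))
            seqs.append(np.array(x))
        its = implied_timescales(seqs, [1, 2], 2)
        expected = -1.0 / np.log(lam2)
        assert its[0, 0] == pytest.approx(expected, rel=0.1)


class TestCKTest:
    @staticmethod
    def _markov_seqs(n_traj=60, length=800, seed=9):
        rng = np.random.default_rng(seed)
        P = np.array([[0.92, 0.08], [0.1, 0.9]])
        seqs = []
        for _ in range(n_traj):
            x = [int(rng.random() < 0.5)]
            for _ in range(length):
                x.append(rng.choice(2, p=P[x[-1]]))
            seqs.append(np.array(x))
        return seqs

    def test_k1_exact_identity(self):
        seqs = self._markov_seqs(20, 300)
        res = ck_test(seqs, lag=1, k_steps=[1], probe_states=[0], n_states=2,
                      n_boot=20, seed=0)
        assert res[0]["predicted"][0] == pytest.approx(
            res[0]["empirical"][0], abs=1e-12
        )

    def test_markov_within_bands(self):
        seqs = self._markov_seqs()
        res = ck_test(seqs, lag=2, k_steps=[1, 2, 4], probe_states=[0, 1],
                      n_states=2, n_boot=60, seed=1)
        for s in (0, 1):
            ok = (res[s]["predicted"] >= res[s]["lo"] - 0.02) & (
                res[s]["predicted"] <= res[s]["hi"] + 0.02
            )
            assert ok.all()

    def test_semi_markov_detected(self):
        """Heavy-tailed (Pareto) dwell times violate the semigroup property:
        the predicted return probabilities leave the empirical bands."""
        rng = np.random.default_rng(10)
        seqs = []
        for _ in range(60):
            x = []
            s = 0
            while len(x) < 900:
                dwell = int(min(rng.pareto(0.8) + 1, 300))
                x.extend([s] * dwell)
                s = 1 - s
            seqs.append(np.array(x[:900]))
        res = ck_test(seqs, lag=1, k_steps=[4, 16, 64], probe_states=[0],
                      n_states=2, n_boot=60, seed=2)
        outside = (res[0]["predicted"] < res[0]["lo"]) | (
            res[0]["predicted"] > res[0]["hi"]
        )
        assert outside.any()


class TestDwellExponentialFit:
    def test_exponential_self_consistency(self):
        rng = np.random.default_rng(11)
        r = dwell_exponential_fit_quality({0: rng.exponential(3.0, 10_000)})
        assert r[0] > 0.95

    def test_identical_histograms(self):
        # exact exponential quantile sample: near-perfect match
        q = np.linspace(0.005, 0.995, 500)
        x = -np.log(1 - q)
        r = dwell_exponential_fit_quality({0: x})
        assert r[0] > 0.99

    def test_uniform_contrast(self):
        rng = np.random.default_rng(12)
        r = dwell_exponential_fit_quality({
            0: rng.exponential(3.0, 5000),
            1: rng.uniform(3.0, 6.0, 5000),
        })
        assert r[1] < r[0] - 0.2

    def test_undersampled_skipped(self):
        r = dwell_exponential_fit_quality({0: [1.0, 2.0]})
        assert 0 not in r
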