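import cmath

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kurastab as ks
from kurastab.synchrony import (
    SynchronyError,
    _directional,
    _directional_matrix,
    pair_index,
    reference_wrap_times,
)


def brute_force_index(theta_ref, theta_other, burn_in):
    """Independent enumeration oracle: scan every sample interval for 2*pi
    crossings, interpolate both phases at the crossing, and average unit
    vectors with plain complex arithmetic (both strobe directions)."""

    def directional(ref, other):
        vectors = []
        for t0 in range(len(ref) - 1):
            lo, hi = ref[t0], ref[t0 + 1]
            m = int(np.floor(lo / (2 * np.pi))) + 1
            while m * 2 * np.pi <= hi:
                level = m * 2 * np.pi
                frac = (level - lo) / (hi - lo)
                tstar = t0 + frac
                if tstar >= burn_in:
                    o = other[t0] * (1 - frac) + other[t0 + 1] * frac
                    vectors.append(cmath.exp(1j * (o - level)))
                m += 1
        assert vectors
        return abs(sum(vectors) / len(vectors))

    return (directional(theta_ref, theta_other)
            + directional(theta_other, theta_ref)) / 2


class TestExtractPhase:
    def test_pure_sinusoid_frequency_recovery(self):
        t = np.arange(1000)
        phase = ks.extract_phase(np.cos(2 * np.pi * 0.05 * t))
        freq = np.diff(phase[100:-100]) / (2 * np.pi)
        assert np.allclose(freq, 0.05, atol=1e-3)

    def test_fixed_offset_recovered(self):
        t = np.arange(1000)
        phi = 0.8
        p1 = ks.extract_phase(np.sin(2 * np.pi * 0.04 * t))
        p2 = ks.extract_phase(np.sin(2 * np.pi * 0.04 * t + phi))
        diff = (p2 - p1)[100:-100]
        assert np.allclose(np.angle(np.exp(1j * diff)), phi, atol=0.02)

    def test_constant_signal_rejected(self):
        with pytest.raises(SynchronyError, match="constant"):
            ks.extract_phase(np.full(500, 0.3))


class TestStroboscopicIndex:
    @pytest.mark.parametrize("lag", [0.0, 0.3, np.pi, 5.1])
    def test_locked_pair_scores_one_at_any_lag(self, lag):
        theta = 2 * np.pi * 0.043 * np.arange(2000)
        assert ks.stroboscopic_index(theta, theta + lag, burn_in=100) == \
            pytest.approx(1.0, abs=1e-12)

    def test_incommensurate_free_running_scores_zero(self):
        t = np.arange(20000)
        th1 = 2 * np.pi * 0.05 * t
        th2 = 2 * np.pi * 0.05 * np.sqrt(2) * t
        m = len(reference_wrap_times(th1, 100)[0])
        assert ks.stroboscopic_index(th1, th2, burn_in=100) < 1 / np.sqrt(m)

    def test_four_symmetric_phases_cancel_exactly(self):
        # partner advancing at 5/4 the reference rate hits phases
        # {0, pi/2, pi, 3pi/2} at successive strobes; over a multiple of 4
        # events the unit vectors cancel exactly.
        w = 2 * np.pi / 20
        t = np.arange(20 * 400 + 1)  # exactly 400 wrap events
        d = _directional(w * t, 1.25 * w * t, burn_in=0, interpolate=True)
        assert d == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            # smooth random-walk instantaneous frequencies around 0.05 cyc/step
            rates = 2 * np.pi * (0.05 + 0.01 * np.cumsum(rng.normal(0, 0.02, 600)))
            th1 = np.concatenate([[0.0], np.cumsum(np.clip(rates, 0.05, 1.0))])
            th2 = th1 * rng.uniform(0.8, 1.2) + rng.uniform(0, 2 * np.pi)
            ours = ks.stroboscopic_index(th1, th2, burn_in=50)
            oracle = brute_force_index(th1, th2, burn_in=50)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_by_construction(self):
        t = np.arange(3000)
        th1 = 2 * np.pi * 0.04 * t + 0.3 * np.sin(0.01 * t)
        th2 = 2 * np.pi * 0.055 * t
        assert ks.stroboscopic_index(th1, th2) == ks.stroboscopic_index(th2, th1)

    def test_no_wrap_events_rejected(self):
        slow = np.linspace(0, 1.0, 300)  # never completes a cycle
        with pytest.raises(SynchronyError, match="wrap"):
            ks.stroboscopic_index(slow, slow + 0.1, burn_in=0)

    @given(st.floats(-np.pi, np.pi), st.floats(0.02, 0.09))
    @settings(max_examples=20, deadline=None)
    def test_bounds_and_global_shift_invariance(self, shift, rate):
        t = np.arange(2000)
        th1 = 2 * np.pi * rate * t
        th2 = 2 * np.pi * rate * 1.31 * t
        base = ks.stroboscopic_index(th1, th2, burn_in=100)
        assert 0.0 <= base <= 1.0
        # a common shift slides the strobe instants, which can only add or
        # remove an event at each window edge: the index moves by O(1/M)
        m = len(reference_wrap_times(th1, 100)[0])
        shifted = ks.stroboscopic_index(th1 + shift, th2 + shift, burn_in=100)
        assert abs(shifted - base) <= 5.0 / m
        wrapped = ks.stroboscopic_index(th1 + 4 * np.pi, th2 + 4 * np.pi,
                                        burn_in=100)
        assert abs(wrapped - base) <= 5.0 / m


class TestSyncPattern:
    def test_34_nodes_yield_561_pairs(self, net34):
        freqs = ks.sample_frequencies(34, seed=1)
        system = ks.build_system(net34, freqs, k_global=1000.0)
        traj = ks.simulate(system, 2000, init_phases=2)
        pattern = ks.sync_pattern(traj)
        assert pattern.indices.shape == (561,)
        assert np.all((pattern.indices >= 0) & (pattern.indices <= 1))

    def test_globally_locked_trajectory_all_ones(self):
        # identical frequencies, strong zero-delay coupling: full synchrony
        n = 5
        w = (np.ones((n, n)) - np.eye(n)) * 0.3
        net = ks.StructuralNetwork(w, np.where(w > 0, 10.0, 0.0))
        system = ks.build_system(net, np.full(n, 50.0), k_global=3.0)
        traj = ks.simulate(system, 2000, init_phases=1)
        pattern = ks.sync_pattern(traj)
        assert np.all(pattern.indices > 0.999)

    def test_self_index_is_one(self, traj8):
        d = _directional_matrix(traj8.phases, burn_in=100, interpolate=True)
        assert np.allclose(np.diag(d), 1.0, atol=1e-12)

    def test_signal_pathway_exact_on_locked_trajectory(self):
        # fully locked network: phase differences are constant, so strobing
        # the Hilbert-extracted phases of sin(theta) must reproduce the
        # direct-phase indices almost exactly
        n = 5
        w = (np.ones((n, n)) - np.eye(n)) * 0.3
        net = ks.StructuralNetwork(w, np.where(w > 0, 10.0, 0.0))
        system = ks.build_system(net, np.full(n, 50.0), k_global=3.0)
        traj = ks.simulate(system, 2000, init_phases=1)
        direct = ks.sync_pattern(traj, source="phase").indices
        hilbert = ks.sync_pattern(traj, source="signal").indices
        assert np.max(np.abs(direct - hilbert)) < 0.02

    def test_signal_pathway_agrees_in_locking_regime(self, net8):
        # partially locked regime (per-step increments below the pi/step
        # sampling bound): unlocked pairs carry O(1/sqrt(M)) strobe-sampling
        # scatter, so agreement is distributional rather than per-pair exact
        system = ks.build_system(net8, ks.sample_frequencies(8, seed=5),
                                 k_global=50.0)
        traj = ks.simulate(system, 2000, init_phases=3)
        assert np.abs(np.diff(traj.phases, axis=0)).max() < np.pi
        direct = ks.sync_pattern(traj, source="phase").indices
        hilbert = ks.sync_pattern(traj, source="signal").indices
        diffs = np.abs(direct - hilbert)
        assert np.median(diffs) < 0.05
        assert diffs.max() < 0.15

    def test_pair_order_is_row_major_upper_triangle(self):
        n = 5
        iu = np.triu_indices(n, k=1)
        for pos, (i, j) in enumerate(zip(*iu)):
            assert pair_index(int(i), int(j), n) == pos
            assert pair_index(int(j), int(i), n) == pos


class TestAveragePattern:
    def test_single_pattern_identity_with_zero_diagonal(self):
        p = ks.SyncPattern(np.array([0.2, 0.4, 0.6]), 3)
        m = ks.average_pattern([p])
        assert np.array_equal(np.diag(m), np.zeros(3))
        assert m[0, 1] == 0.2 and m[1, 2] == 0.6
        assert np.array_equal(m, m.T)

    def test_mean_of_extremes(self):
        zeros = ks.SyncPattern(np.zeros(3), 3)
        ones = ks.SyncPattern(np.ones(3), 3)
        m = ks.average_pattern([zeros, ones])
        iu = np.triu_indices(3, k=1)
        assert np.allclose(m[iu], 0.5)

    def test_heterogeneous_sizes_rejected(self):
        with pytest.raises(ValueError, match="heterogeneous"):
            ks.average_pattern([ks.SyncPattern(np.zeros(3), 3),
                                ks.SyncPattern(np.zeros(6), 4)])
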