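"""The 1D map: feedforward induction, environments, recurrent learning,
ordered trace statistics."""

import tracemalloc

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from btspmap import (
    MapParams,
    block_average,
    empirical_trace_stats,
    feedforward_induction,
    generate_environment_sequence,
    iterate_scalar_synapse,
    recurrent_learn,
)
from btspmap.plasticity import map_update


class TestFeedforwardInduction:
    def test_pointwise_values_at_plateau(self, cosine_params):
        w = np.zeros(64)
        w1 = feedforward_induction(w, 0.0, cosine_params)
        assert w1[0] == pytest.approx(2 * 0.3)  # f_P(0)=2, f_D(0)=0
        w = np.ones(64)
        w1 = feedforward_induction(w, np.pi, cosine_params)
        assert w1[0] == pytest.approx(1 - 2 * 0.3)  # opposite phase: pure depression

    def test_repeated_induction_fixed_point(self):
        params = MapParams.cosine(0.2, 0.25)
        theta = 2 * np.pi * np.arange(64) / 64
        w = np.full(64, 0.5)
        for _ in range(1000):  # brute-force iteration
            w = feedforward_induction(w, 0.0, params)
        fp, fd = params.f_p(theta), params.f_d(theta)
        denom = params.P * fp + params.D * fd
        expected = np.where(denom > 0, params.P * fp / np.maximum(denom, 1e-300), w)
        np.testing.assert_allclose(w, expected, atol=1e-8)

    def test_nonfinite_plateau_phase_rejected(self, cosine_params):
        with pytest.raises(ValueError):
            feedforward_induction(np.zeros(8), np.nan, cosine_params)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        P=st.floats(0.0, 0.25),
        D=st.floats(0.0, 0.25),
        w0=st.floats(0.0, 1.0),
        theta=st.floats(0.0, 2 * np.pi),
    )
    def test_cosine_update_never_clips_for_small_rates(self, P, D, w0, theta):
        # for P+D <= 1/2 the cosine update is a convex-type contraction
        params = MapParams.cosine(P, D)
        raw = w0 + P * (1 - w0) * params.f_p(theta) - D * w0 * params.f_d(theta)
        assert 0.0 <= raw <= 1.0
        assert map_update(w0, theta, params) == pytest.approx(raw)


class TestEnvironmentSequence:
    def test_dense_single_cell_case(self):
        seq = generate_environment_sequence(N=16, M=1, s=1.0, n=5, seed=0)
        for k in range(5):
            assert sorted(seq.slots[k]) == list(range(16))
            assert seq.active[k].all()

    def test_exactly_m_cells_per_slot(self):
        seq = generate_environment_sequence(N=8, M=5, s=0.3, n=4, seed=3)
        for k in range(4):
            counts = np.bincount(seq.slots[k], minlength=8)
            np.testing.assert_array_equal(counts, 5)

    def test_determinism_and_seed_sensitivity(self):
        a = generate_environment_sequence(N=16, M=2, s=0.5, n=6, seed=11)
        b = generate_environment_sequence(N=16, M=2, s=0.5, n=6, seed=11)
        c = generate_environment_sequence(N=16, M=2, s=0.5, n=6, seed=12)
        np.testing.assert_array_equal(a.slots, b.slots)
        np.testing.assert_array_equal(a.active, b.active)
        assert not np.array_equal(a.slots, c.slots)

    def test_extension_preserves_history(self):
        # sub-streamed RNG: a longer sequence reproduces the shorter prefix
        short = generate_environment_sequence(N=16, M=2, s=0.5, n=4, seed=7)
        long = generate_environment_sequence(N=16, M=2, s=0.5, n=9, seed=7)
        np.testing.assert_array_equal(long.slots[:4], short.slots)
        np.testing.assert_array_equal(long.active[:4], short.active)

    def test_activation_fraction_matches_s(self):
        s = 0.3
        seq = generate_environment_sequence(N=32, M=4, s=s, n=50, seed=21)
        frac = seq.active.mean()
        se = np.sqrt(s * (1 - s) / seq.active.size)
        assert abs(frac - s) < 3 * se

    def test_invalid_sparseness_rejected(self):
        with pytest.raises(ValueError):
            generate_environment_sequence(N=8, M=1, s=0.0, n=2, seed=0)
        with pytest.raises(ValueError):
            generate_environment_sequence(N=8, M=1, s=1.2, n=2, seed=0)


class TestRecurrentLearning:
    def test_all_silent_environments_leave_matrix_unchanged(self, cosine_params):
        seq = generate_environment_sequence(N=8, M=2, s=0.5, n=6, seed=2)
        seq.active[:] = False
        W0 = np.random.default_rng(0).random((16, 16))
        W, _ = recurrent_learn(W0, seq, cosine_params)
        np.testing.assert_array_equal(W, W0)

    def test_single_environment_closed_form(self):
        params = MapParams.cosine(0.4, 0.2)
        seq = generate_environment_sequence(N=32, M=1, s=1.0, n=1, seed=5)
        W, _ = recurrent_learn(np.zeros((32, 32)), seq, params)
        ph = seq.phase_angles(0)
        dth = ph[:, None] - ph[None, :]
        expected = np.clip(0.4 * (1 + np.cos(dth)), 0.0, 1.0)
        np.fill_diagonal(expected, 0.0)  # self-connections untouched
        np.testing.assert_allclose(W, expected, atol=1e-12)

    def test_snapshots_and_shape_check(self, cosine_params):
        seq = generate_environment_sequence(N=8, M=2, s=1.0, n=5, seed=2)
        W0 = np.full((16, 16), 0.5)
        W, snaps = recurrent_learn(W0, seq, cosine_params, snapshots=(0, 4))
        assert set(snaps) == {0, 4}
        np.testing.assert_array_equal(snaps[4], W)
        with pytest.raises(ValueError):
            recurrent_learn(np.zeros((3, 3)), seq, cosine_params)

    def test_weights_stay_in_unit_interval(self):
        params = MapParams.cosine(0.8, 0.7)  # large rates force clipping
        seq = generate_environment_sequence(N=16, M=2, s=0.8, n=20, seed=9)
        W, _ = recurrent_learn(
            np.random.default_rng(1).random((32, 32)), seq, params
        )
        assert (W >= 0).all() and (W <= 1).all()

    def test_memory_footprint_in_place(self, cosine_params):
        # learning at N=128, M=8 must not materialise large temporaries
        seq = generate_environment_sequence(N=128, M=8, s=0.5, n=3, seed=4)
        W0 = np.random.default_rng(2).random((1024, 1024))
        tracemalloc.start()
        recurrent_learn(W0, seq, cosine_params)
        _, peak = tracemalloc.get_traced_memory()
        tracemalloc.stop()
        assert peak < 500 * 1024**2


class TestOrderedStats:
    def test_constant_matrix(self):
        seq = generate_environment_sequence(N=16, M=2, s=1.0, n=3, seed=8)
        W = np.full((32, 32), 0.7)
        st_ = empirical_trace_stats(W, seq, eta=0)
        assert st_.amplitude == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(st_.mean_profile, 0.7)
        np.testing.assert_allclose(st_.var_profile, 0.0, atol=1e-15)

    def test_pure_cosine_matrix_has_unit_amplitude(self):
        seq = generate_environment_sequence(N=32, M=2, s=1.0, n=3, seed=1)
        ph = seq.phase_angles(1)
        W = np.cos(ph[:, None] - ph[None, :])
        st_ = empirical_trace_stats(W, seq, eta=seq.n - 1 - 1)
        assert st_.amplitude == pytest.approx(1.0, abs=1e-10)
        assert st_.sine_amplitude == pytest.approx(0.0, abs=1e-10)

    def test_relabelling_invariance(self, small_learned_system):
        W, seq = small_learned_system
        perm = np.random.default_rng(5).permutation(seq.n_cells)
        W2 = W[np.ix_(perm, perm)]
        seq2 = generate_environment_sequence(seq.N, seq.M, seq.s, seq.n, seq.seed)
        seq2.slots = seq.slots[:, perm]
        seq2.active = seq.active[:, perm]
        a = empirical_trace_stats(W, seq, eta=2)
        b = empirical_trace_stats(W2, seq2, eta=2)
        assert b.amplitude == pytest.approx(a.amplitude, rel=1e-12)
        np.testing.assert_allclose(b.mean_profile, a.mean_profile, atol=1e-12)

    def test_palimpsest_decay_in_expectation(self, cosine_params):
        etas = np.arange(0, 8, 2)
        amps = np.zeros(etas.size)
        for rep in range(6):
            seq = generate_environment_sequence(N=32, M=2, s=1.0, n=30, seed=600 + rep)
            W0 = np.random.default_rng(700 + rep).random((64, 64))
            W, _ = recurrent_learn(W0, seq, cosine_params)
            amps += [empirical_trace_stats(W, seq, int(e)).amplitude for e in etas]
        amps /= 6
        assert all(b < a + 0.01 for a, b in zip(amps, amps[1:]))

    def test_out_of_range_age_rejected(self, small_learned_system):
        W, seq = small_learned_system
        with pytest.raises(ValueError):
            empirical_trace_stats(W, seq, eta=seq.n)


class TestBlockAverage:
    def test_dense_single_cell_equals_reordered_matrix(self):
        seq = generate_environment_sequence(N=16, M=1, s=1.0, n=2, seed=3)
        W = np.random.default_rng(0).random((16, 16))
        block, missing = block_average(W, seq, env=1)
        assert not missing.any()
        order = np.argsort(seq.slots[1])
        reordered = W[np.ix_(order, order)].astype(float)
        np.fill_diagonal(reordered, np.nan)
        np.testing.assert_allclose(block, reordered, equal_nan=True)

    def test_constant_matrix_constant_block(self, small_learned_system):
        _, seq = small_learned_system
        W = np.full((seq.n_cells, seq.n_cells), 0.3)
        block, missing = block_average(W, seq, env=0)
        assert np.allclose(block[~np.isnan(block)], 0.3)

    def test_empty_slots_flagged_not_zero_filled(self, cosine_params):
        seq = generate_environment_sequence(N=8, M=2, s=0.4, n=4, seed=12)
        seq.active[0, seq.slots[0] == 3] = False  # force slot 3 empty
        W = np.random.default_rng(1).random((16, 16))
        block, missing = block_average(W, seq, env=0)
        assert missing[3]
        assert np.isnan(block[:, 3]).all() and np.isnan(block[3, :]).all()

    def test_presynaptic_average_variance_shrinks_with_population(self, cosine_params):
        # what each postsynaptic cell receives is the presynaptic slot
        # average over sM active cells: its quenched variance about the
        # mean profile shrinks ≈ 1/(sM); the doubly averaged N×N block is
        # smoother still
        N = 24
        out, out_block = {}, {}
        for sM, (M, s) in {2: (4, 0.5), 8: (16, 0.5)}.items():
            row_vars, block_vars = [], []
            for rep in range(4):
                seq = generate_environment_sequence(
                    N=N, M=M, s=s, n=40, seed=50 + M + rep
                )
                W0 = np.random.default_rng(60 + M + rep).random(
                    (seq.n_cells, seq.n_cells)
                )
                W, _ = recurrent_learn(W0, seq, cosine_params)
                env = seq.n - 1  # age 0
                st_ = empirical_trace_stats(W, seq, 0)
                idx = np.flatnonzero(seq.active[env])
                sl = seq.slots[env][idx]
                sub = W[np.ix_(idx, idx)].astype(float)
                np.fill_diagonal(sub, np.nan)
                resid = []
                for a in range(N):
                    cols = np.flatnonzero(sl == a)
                    if cols.size == 0:
                        continue
                    row_avg = np.nanmean(sub[:, cols], axis=1)
                    d = np.mod(a - sl, N)
                    profile = st_.mean_weight + st_.amplitude * np.cos(
                        2 * np.pi * d / N
                    )
                    resid.extend(row_avg - profile)
                row_vars.append(np.nanvar(resid))
                block, _ = block_average(W, seq, env)
                offs = np.mod(np.arange(N)[:, None] - np.arange(N)[None, :], N)
                block_vars.append(
                    np.nanvar(
                        block
                        - st_.mean_weight
                        - st_.amplitude * np.cos(2 * np.pi * offs / N)
                    )
                )
            out[sM] = np.mean(row_vars)
            out_block[sM] = np.mean(block_vars)
        assert out[2] / out[8] == pytest.approx(8 / 2, rel=0.6)
        assert out_block[2] < out[2] and out_block[8] < out[8]


class TestScalarSynapse:
    def test_trajectory_stays_bounded_and_deterministic(self, cosine_params):
        rng1 = np.random.default_rng(0)
        rng2 = np.random.default_rng(0)
        w1 = iterate_scalar_synapse(cosine_params, 0.5, 500, rng1)
        w2 = iterate_scalar_synapse(cosine_params, 0.5, 500, rng2)
        np.testing.assert_array_equal(w1, w2)
        assert (w1 >= 0).all() and (w1 <= 1).all()
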