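import itertools

import numpy as np
import pytest

from nmrdecomp import LineSpec, align_components, compute_stft, make_fid, ncpd, nmf, ntd
from nmrdecomp.factorize import core_pairing, fit_decay_constant, rank_scan


def rand_pos(shape, seed):
    return np.random.default_rng(seed).random(shape) + 0.05


class TestNMF:
    def test_rank1_exact_recovery(self):
        h = rand_pos(20, 1)
        w = rand_pos(30, 2)
        res = nmf(np.outer(h, w), 1, tol=1e-9, n_restarts=2, seed=0)
        assert res.rel_error < 1e-6
        # profiles proportional to the generators
        assert abs(np.corrcoef(res.time_profiles[0], h)[0, 1]) > 1 - 1e-6
        assert abs(np.corrcoef(res.freq_profiles[0], w)[0, 1]) > 1 - 1e-6

    def test_rigid_mobile_two_line_separation(self):
        # static polymer analogue: one broad (rigid, T2*=0.3 ms) and one
        # narrow (mobile, T2*=20 ms) line
        fid = make_fid(
            [LineSpec(-20000.0, 1.0, 3e-4), LineSpec(20000.0, 0.6, 0.02)],
            n_points=4096, dwell_time=5e-6,
        )
        sg = compute_stft(fid, 128, 32, "hann")
        res = nmf(sg, 2, tol=1e-5, n_restarts=3, seed=0)
        refs = np.array([
            compute_stft(make_fid([LineSpec(-20000.0, 1.0, 3e-4)], 4096, 5e-6), 128, 32).magnitude.sum(0),
            compute_stft(make_fid([LineSpec(20000.0, 0.6, 0.02)], 4096, 5e-6), 128, 32).magnitude.sum(0),
        ])
        perm, sims = align_components(res, refs)
        assert (sims >= 0.98).all()
        t2 = [fit_decay_constant(res.time_profiles[int(c)], sg.frame_times) for c in perm]
        assert t2[1] / t2[0] >= 10

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            nmf(np.zeros((4, 5)), 1)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            nmf(-np.ones((4, 5)), 1)

    def test_k_bounds(self):
        V = rand_pos((4, 6), 0)
        with pytest.raises(ValueError):
            nmf(V, 0)
        with pytest.raises(ValueError):
            nmf(V, 5)

    def test_objective_monotone_nonincreasing(self):
        V = rand_pos((15, 25), 7)
        res = nmf(V, 3, tol=0, max_iter=60, n_restarts=1, seed=1, track_objective=True)
        diffs = np.diff(res.objective_trace)
        assert (diffs <= 1e-12).all()

    def test_nested_init_monotone_in_rank(self):
        V = rand_pos((20, 30), 9) @ np.eye(30)
        prev = None
        prev_err = None
        for k in (1, 2, 3):
            init = None if prev is None else (prev.time_profiles.T, prev.freq_profiles)
            res = nmf(V, k, tol=1e-7, max_iter=800, init=init, seed=0)
            if prev_err is not None:
                assert res.rel_error <= prev_err + 1e-9
            prev, prev_err = res, res.rel_error

    def test_reconstruction_matches_rel_error(self):
        V = rand_pos((10, 12), 3)
        res = nmf(V, 2, tol=1e-6, n_restarts=2, seed=0)
        err = np.linalg.norm(V - res.reconstruct()) / np.linalg.norm(V)
        assert err == pytest.approx(res.rel_error, abs=1e-12)

    def test_freq_profiles_unit_max(self):
        res = nmf(rand_pos((10, 12), 4), 2, n_restarts=2, seed=0)
        assert np.allclose(res.freq_profiles.max(axis=1), 1.0)
        assert (res.freq_profiles >= 0).all() and (res.time_profiles >= 0).all()


class TestNTD:
    def test_rank_111_exact(self):
        a, b, c = rand_pos(6, 3), rand_pos(7, 4), rand_pos(8, 5)
        X = np.einsum("i,j,k->ijk", a, b, c)
        res = ntd(X, (1, 1, 1), tol=1e-9, n_restarts=2, seed=0)
        assert res.rel_error < 1e-6
        assert abs(np.corrcoef(res.sample_profiles[0], a)[0, 1]) > 1 - 1e-6
        assert abs(np.corrcoef(res.freq_profiles[0], c)[0, 1]) > 1 - 1e-6

    def test_rank_exceeds_dimension(self):
        X = rand_pos((3, 4, 5), 0)
        with pytest.raises(ValueError, match="rank"):
            ntd(X, (4, 1, 1))

    def test_objective_monotone(self):
        X = rand_pos((5, 6, 7), 8)
        res = ntd(X, (2, 2, 2), tol=0, max_iter=40, n_restarts=1, seed=2, track_objective=True)
        assert (np.diff(res.objective_trace) <= 1e-12).all()

    def test_degradation_recovery(self, degradation_tensor, degradation, reference_profiles):
        # the headline separation: 4-rank NTD on the 16-sample series recovers
        # each component's spectrum, composition time course and T2* ordering
        _, truth = degradation
        res = ntd(degradation_tensor, (4, 4, 4), tol=1e-3, n_restarts=3, seed=0)
        perm, sims = align_components(res, reference_profiles)
        assert (sims >= 0.95).all()
        M = res.spectral_sample_profiles()
        T = res.spectral_time_profiles()
        comp = truth["composition"].to_numpy().T
        t2 = {}
        for ci, name in enumerate(truth["components"]):
            fc = int(perm[ci])
            r = np.corrcoef(comp[ci], M[fc])[0, 1]
            assert r >= 0.9, f"{name}: composition r={r:.3f}"
            t2[name] = fit_decay_constant(T[fc], degradation_tensor.frame_times)
        assert t2["cellulose"] < t2["protein"] < t2["lipid"]

    def test_core_pairing_identity_on_superdiagonal(self):
        G = np.zeros((3, 3, 3))
        G[0, 0, 0], G[1, 1, 1], G[2, 2, 2] = 5, 3, 1
        from nmrdecomp.factorize import DeconvolutionResult

        res = DeconvolutionResult(
            method="ntd", n_components=(3, 3, 3),
            freq_profiles=np.ones((3, 4)), time_profiles=np.ones((3, 5)),
            sample_profiles=np.ones((3, 6)), core=G,
        )
        assert core_pairing(res) == [(0, 0, 0), (1, 1, 1), (2, 2, 2)]


class TestNCPD:
    def test_rank1_exact(self):
        a, b, c = rand_pos(5, 1), rand_pos(6, 2), rand_pos(7, 3)
        X = np.einsum("i,j,k->ijk", a, b, c)
        res = ncpd(X, 1, tol=1e-9, n_restarts=2, seed=0)
        assert res.rel_error < 1e-6

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            ncpd(rand_pos((3, 4, 5), 0), 0)

    def test_degradation_runs_and_records_error(self, degradation_tensor):
        res = ncpd(degradation_tensor, 4, tol=1e-3, max_iter=500, n_restarts=2, seed=0)
        assert 0 < res.rel_error < 1
        assert res.n_iter > 0

    def test_objective_monotone(self):
        X = rand_pos((5, 6, 7), 4)
        res = ncpd(X, 2, tol=0, max_iter=40, n_restarts=1, seed=3, track_objective=True)
        assert (np.diff(res.objective_trace) <= 1e-12).all()


class TestAlignComponents:
    def test_recovers_known_shuffle(self):
        ref = rand_pos((4, 10), 0)
        shuffled = ref[[2, 0, 3, 1]]
        perm, sims = align_components(shuffled, ref)
        assert np.allclose(sims, 1.0)
        assert list(perm) == [1, 3, 0, 2]

    def test_matches_brute_force_assignment(self):
        rng = np.random.default_rng(12)
        ref = rng.random((4, 8)) + 0.01
        prof = rng.random((4, 8)) + 0.01
        perm, sims = align_components(prof, ref)
        refn = ref / np.linalg.norm(ref, axis=1, keepdims=True)
        profn = prof / np.linalg.norm(prof, axis=1, keepdims=True)
        best = max(
            itertools.permutations(range(4)),
            key=lambda p: sum(refn[i] @ profn[p[i]] for i in range(4)),
        )
        assert list(perm) == list(best)

    def test_single_component(self):
        perm, sims = align_components(np.ones((1, 5)), np.ones((1, 5)))
        assert list(perm) == [0] and sims[0] == pytest.approx(1.0)

    def test_axis_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            align_components(np.ones((2, 5)), np.ones((2, 6)))


class TestFitDecayConstant:
    def test_exact_exponential(self):
        t = np.linspace(0, 0.05, 10)
        assert fit_decay_constant(np.exp(-t / 0.01), t) == pytest.approx(0.01, abs=1e-6)

    def test_noisy_exponential_within_ten_percent(self):
        rng = np.random.default_rng(42)
        t = np.linspace(0, 0.03, 20)
        p = np.exp(-t / 0.01)
        p = np.clip(p + 0.02 * rng.standard_normal(20), 1e-6, None)
        assert fit_decay_constant(p, t) == pytest.approx(0.01, rel=0.10)

    def test_constant_profile_reports_no_decay(self):
        t = np.linspace(0, 1, 10)
        assert fit_decay_constant(np.ones(10), t) == np.inf

    def test_too_few_points(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match=">= 3"):
            fit_decay_constant(np.array([1.0, 0.001, 0.001, 0.001]), t)


def test_rank_scan_errors_decrease():
    V = rand_pos((12, 15), 6)
    out = rank_scan(V, [1, 2, 3], tol=1e-6, n_restarts=2, seed=0)
    errs = [e for _, e in out]
    assert errs[0] >= errs[1] >= errs[2] - 1e-9
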