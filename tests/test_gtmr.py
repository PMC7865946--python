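import numpy as np
import pytest
from scipy.stats import spearmanr

from nmrdecomp import (
    compute_stft,
    fit_gtm,
    fit_gtmr,
    make_fid,
    map_coordinates,
    predict_forward,
    predict_inverse,
    r_squared,
)
from nmrdecomp.gtmr import (
    flatten_spectrograms,
    load_gtmr,
    profile_to_spectrum,
    save_gtmr,
)
from nmrdecomp.synthetic import LineSpec


@pytest.fixture(scope="module")
def linear_model():
    x = np.linspace(0, 1, 100)[:, None]
    return fit_gtmr(x, 2 * x + 1, max_iter=300), x


class TestFitGTM:
    def test_loglik_monotone_on_arc(self):
        th = np.linspace(0, np.pi, 200)
        arc = np.column_stack([np.cos(th), np.sin(th)])
        m = fit_gtm(arc, max_iter=200)
        assert (np.diff(m.loglik_trace) >= -1e-9).all()

    def test_arc_positions_ordered(self):
        # a noiseless 1-D manifold should map monotonically onto the latent
        # sheet; a 5x5 RBF basis keeps the map smooth enough not to fold
        th = np.linspace(0, np.pi, 200)
        arc = np.column_stack([np.cos(th), np.sin(th)])
        m = fit_gtm(arc, grid_size=15, n_rbf_per_side=5)
        coords = map_coordinates(m, arc)
        centred = coords - coords.mean(0)
        axis = np.linalg.svd(centred, full_matrices=False)[2][0]
        assert abs(spearmanr(th, centred @ axis).statistic) >= 0.95

    def test_degenerate_cluster_converges_to_point(self):
        rng = np.random.default_rng(0)
        point = np.array([3.0, -1.0, 5.0])
        data = point + 1e-3 * rng.standard_normal((100, 3))
        m = fit_gtm(data, grid_size=8, n_rbf_per_side=4, max_iter=100)
        R = m.responsibilities(m.scale(data))
        proj = m.unscale(R @ m.node_means())
        assert np.abs(proj - data).max() < 1e-2

    def test_responsibilities_sum_to_one(self, linear_model):
        m, x = linear_model
        R = m.gtm.responsibilities(m.gtm.scale(np.column_stack([x, 2 * x + 1])))
        assert np.allclose(R.sum(axis=1), 1.0, atol=1e-12)
        assert (R >= 0).all()

    def test_constant_column_rejected(self):
        data = np.column_stack([np.arange(10.0), np.ones(10)])
        with pytest.raises(ValueError, match="column"):
            fit_gtm(data)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            fit_gtm(np.array([[1.0, 2.0]]))


class TestGTMRPrediction:
    def test_forward_linear_r2(self, linear_model):
        m, _ = linear_model
        xq = np.linspace(0.01, 0.99, 50)[:, None]
        pred = predict_forward(m, xq)
        assert r_squared(2 * xq + 1, pred.mean) >= 0.99

    def test_inverse_linear_r2(self):
        x = np.linspace(0, 1, 100)[:, None]
        m = fit_gtmr(x, 3 * x - 2, max_iter=300)
        yq = 3 * np.linspace(0.01, 0.99, 50)[:, None] - 2
        pred = predict_inverse(m, yq)
        assert r_squared((yq + 2) / 3, pred.mean) >= 0.99

    def test_forward_inverse_roundtrip(self, linear_model):
        m, _ = linear_model
        xq = np.linspace(0.05, 0.95, 30)[:, None]
        y = predict_forward(m, xq).mean
        back = predict_inverse(m, y).mean
        assert r_squared(xq, back) >= 0.98

    def test_training_row_consistency(self, product_table):
        X = product_table.column("propionate")[:, None]
        Y = np.column_stack([product_table.column("acetate"), product_table.column("co2")])
        m = fit_gtmr(X, Y)
        pred = predict_inverse(m, Y[5:6])
        assert np.abs(pred.mean - X[5]) / np.abs(X[5]) < 0.1

    def test_product_kinetics_forward_r2(self, product_table):
        # propionate-analogue intensity predicts the acetate- and CO2-analogues
        X = product_table.column("propionate")[:, None]
        B = product_table.column("acetate")
        C = product_table.column("co2")
        m = fit_gtmr(X, np.column_stack([B, C]))
        pred = predict_forward(m, X)
        assert r_squared(B, pred.mean[:, 0]) >= 0.9
        assert r_squared(C, pred.mean[:, 1]) >= 0.9

    def test_constant_y_predicts_constant(self):
        x = np.linspace(0, 1, 50)[:, None]
        y = np.full((50, 1), 7.0) + 1e-9 * np.arange(50)[:, None]  # ~constant
        m = fit_gtmr(x, y, max_iter=50)
        pred = predict_forward(m, np.array([[0.3], [0.9]]))
        assert np.allclose(pred.mean, 7.0, atol=1e-6)

    def test_dimension_mismatch(self, linear_model):
        m, _ = linear_model
        with pytest.raises(ValueError, match="dims"):
            predict_forward(m, np.ones((3, 2)))
        with pytest.raises(ValueError, match="dims"):
            predict_inverse(m, np.ones((3, 2)))

    def test_row_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            fit_gtmr(np.ones((5, 2)) + np.arange(5)[:, None], np.ones((4, 1)))

    def test_autoscaling_invariance(self, product_table):
        X = product_table.column("propionate")[:, None]
        Y = product_table.column("acetate")[:, None]
        m1 = fit_gtmr(X, Y)
        m2 = fit_gtmr(10.0 * X, Y)
        p1 = predict_forward(m1, X)
        p2 = predict_forward(m2, 10.0 * X)
        assert np.allclose(p1.mean, p2.mean, rtol=1e-6)

    def test_responsibilities_match_bruteforce(self, product_table):
        X = product_table.column("propionate")[:, None]
        Y = product_table.column("acetate")[:, None]
        m = fit_gtmr(X, Y)
        q = (X - m.gtm.scaling[0][m.x_dims]) / m.gtm.scaling[1][m.x_dims]
        R = m.gtm.responsibilities(q, dims=m.x_dims)
        mu = m.gtm.node_means()[:, m.x_dims]
        d2 = ((q[:, None, :] - mu[None, :, :]) ** 2).sum(-1)
        dens = np.exp(-0.5 * m.gtm.beta * (d2 - d2.min(axis=1, keepdims=True)))
        assert np.allclose(R, dens / dens.sum(1, keepdims=True), rtol=1e-10, atol=1e-12)


class TestMapCoordinates:
    def test_near_duplicate_rows_map_within_one_cell(self):
        # the latent map is continuous: rows that coincide to within jitter
        # land in the same lattice cell (and exact duplicates coincide)
        th = np.linspace(0, np.pi, 200)
        arc = np.column_stack([np.cos(th), np.sin(th)])
        m = fit_gtm(arc, grid_size=15, n_rbf_per_side=5)
        spacing = 2.0 / 14
        x = arc[100:101]
        c1 = map_coordinates(m, x)
        c2 = map_coordinates(m, x + 1e-6)
        assert np.linalg.norm(c1 - c2) < spacing
        assert np.array_equal(c1, map_coordinates(m, x))

    def test_coordinates_match_responsibility_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((200, 2))
        m = fit_gtm(data, grid_size=10, n_rbf_per_side=4, max_iter=200)
        xs = m.scale(data)
        mu = m.node_means()
        d2 = ((xs[:, None, :] - mu[None, :, :]) ** 2).sum(-1)
        dens = np.exp(-0.5 * m.beta * (d2 - d2.min(axis=1, keepdims=True)))
        R = dens / dens.sum(axis=1, keepdims=True)
        assert np.allclose(map_coordinates(m, data, "mean"), R @ m.latent_grid, atol=1e-10)
        assert np.allclose(
            map_coordinates(m, data, "mode"), m.latent_grid[np.argmax(R, axis=1)]
        )
        # mean and mode stay close in the bulk of a smooth map
        d = np.linalg.norm(map_coordinates(m, data, "mean") - map_coordinates(m, data, "mode"), axis=1)
        assert np.median(d) < 2 * (2.0 / 9)

    def test_unknown_mode(self):
        m = fit_gtm(np.random.default_rng(0).random((20, 2)), grid_size=5, n_rbf_per_side=3, max_iter=20)
        with pytest.raises(ValueError):
            map_coordinates(m, np.random.default_rng(1).random((5, 2)), mode="median")


class TestRSquared:
    def test_known_values(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0
        assert r_squared([1, 2, 3], [2, 2, 2]) == 0.0
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2, 2, 2], [1, 2, 3])


class TestDescriptorHelpers:
    def test_flatten_unflatten_spectrum(self):
        fids = [
            make_fid([LineSpec(1000.0 * (i + 1), 1.0, 0.01)], n_points=512, dwell_time=1e-4)
            for i in range(3)
        ]
        sgs = [compute_stft(f, 64, 32) for f in fids]
        X, meta = flatten_spectrograms(sgs)
        assert X.shape[0] == 3
        sp = profile_to_spectrum(X[0], meta)
        assert sp.frequencies.size == 64
        # reconstructed spectrum peaks where the line was
        assert abs(sp.frequencies[np.argmax(sp.intensities)] - 1000.0) < 160

    def test_serialization_roundtrip(self, tmp_path, product_table):
        X = product_table.column("propionate")[:, None]
        Y = product_table.column("acetate")[:, None]
        m = fit_gtmr(X, Y)
        path = str(tmp_path / "model.npz")
        save_gtmr(m, path)
        back = load_gtmr(path)
        p1 = predict_forward(m, X).mean
        p2 = predict_forward(back, X).mean
        assert np.allclose(p1, p2)
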