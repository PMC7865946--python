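"""Generative topographic mapping (GTM) and GTM regression (GTMR).

GTM models data in R^D as a 2-D latent lattice of K nodes mapped through an
RBF network y(z) = W^T phi(z) into data space, with isotropic Gaussian noise
of precision beta; it is fitted by EM (MAP variant with a ridge prior on W).
GTMR fits one joint GTM on the column-concatenation of an autoscaled
descriptor block X and property block Y; conditioning the node
responsibilities on either block alone then yields forward (X -> Y) or
inverse (Y -> X) prediction as a responsibility-weighted average over node
means.  This is what lets a fitted map both predict properties from spectra
and propose a spectrum for target properties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "GTMModel",
    "GTMRModel",
    "PredictionResult",
    "fit_gtm",
    "fit_gtmr",
    "predict_forward",
    "predict_inverse",
    "map_coordinates",
    "r_squared",
    "flatten_spectrograms",
    "profile_to_spectrum",
    "save_gtmr",
    "load_gtmr",
]


def _lattice(n_per_side: int) -> np.ndarray:
    g = np.linspace(-1.0, 1.0, n_per_side)
    zz, yy = np.meshgrid(g, g, indexing="ij")
    return np.column_stack([zz.ravel(), yy.ravel()])


@dataclass
class GTMModel:
    """A fitted generative topographic map."""

    latent_grid: np.ndarray       # K x 2 nodes in [-1, 1]^2
    rbf_centers: np.ndarray       # M x 2
    rbf_width: float              # sigma, lattice units
    weights: np.ndarray           # (M+1) x D, last row = bias
    beta: float                   # noise precision
    scaling: Tuple[np.ndarray, np.ndarray]   # per-dimension (mean, std)
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    regularization: float = 1e-3
    grid_shape: Tuple[int, int] = (0, 0)

    def phi(self, latent: Optional[np.ndarray] = None) -> np.ndarray:
        """RBF design matrix with bias column, K x (M+1)."""
        z = self.latent_grid if latent is None else np.atleast_2d(latent)
        d2 = ((z[:, None, :] - self.rbf_centers[None, :, :]) ** 2).sum(-1)
        phi = np.exp(-d2 / (2.0 * self.rbf_width**2))
        return np.column_stack([phi, np.ones(len(z))])

    def node_means(self) -> np.ndarray:
        """Node images in (scaled) data space, K x D."""
        return self.phi() @ self.weights

    def scale(self, data: np.ndarray) -> np.ndarray:
        mean, std = self.scaling
        return (np.atleast_2d(np.asarray(data, float)) - mean) / std

    def unscale(self, data: np.ndarray, dims: Optional[np.ndarray] = None) -> np.ndarray:
        mean, std = self.scaling
        if dims is not None:
            mean, std = mean[dims], std[dims]
        return data * std + mean

    def log_responsibilities(
        self, data_scaled: np.ndarray, dims: Optional[np.ndarray] = None
    ) -> np.ndarray:
        """Log responsibilities (n x K), optionally conditioned on a dimension block."""
        mu = self.node_means()
        if dims is not None:
            mu = mu[:, dims]
        d2 = ((np.atleast_2d(data_scaled)[:, None, :] - mu[None, :, :]) ** 2).sum(-1)
        logp = -0.5 * self.beta * d2
        return logp - logsumexp(logp, axis=1, keepdims=True)

    def responsibilities(self, data_scaled, dims=None) -> np.ndarray:
        return np.exp(self.log_responsibilities(data_scaled, dims))


@dataclass
class GTMRModel:
    """Joint GTM over [X_scaled | Y_scaled] with recorded block indices."""

    gtm: GTMModel
    x_dims: np.ndarray
    y_dims: np.ndarray
    descriptor_meta: Optional[dict] = None   # e.g. spectrogram shape for un-flattening

    def __post_init__(self) -> None:
        x, y = set(self.x_dims.tolist()), set(self.y_dims.tolist())
        D = self.gtm.weights.shape[1]
        if x & y or (x | y) != set(range(D)):
            raise ValueError("x_dims and y_dims must partition the data dimensions")


@dataclass
class PredictionResult:
    mean: np.ndarray              # responsibility-weighted prediction, original units
    mode: np.ndarray              # argmax-responsibility node prediction
    responsibilities: np.ndarray  # n x K


def fit_gtm(
    data: np.ndarray,
    grid_size: int = 20,
    n_rbf_per_side: int = 7,
    rbf_width_factor: float = 2.0,
    regularization: float = 1e-3,
    max_iter: int = 300,
    tol: float = 1e-5,
    seed: Optional[int] = None,
    beta_max: float = 1e10,
) -> GTMModel:
    """Fit a GTM by (MAP) EM.

    Data are autoscaled internally.  Weights are initialized from the first
    two principal axes (deterministic); pass ``seed`` for random
    initialization instead.  ``loglik_trace`` records the ridge-penalized
    log-likelihood, which EM increases monotonically.
    """
    X = np.atleast_2d(np.asarray(data, dtype=float))
    n, D = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows to fit a GTM")
    if np.isnan(X).any():
        raise ValueError("data contain missing values")
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    zero = np.where(std == 0)[0]
    if len(zero):
        raise ValueError(f"constant (zero-variance) columns: {zero.tolist()}")
    Xs = (X - mean) / std

    latent = _lattice(grid_size)
    centers = _lattice(n_rbf_per_side)
    spacing = 2.0 / (n_rbf_per_side - 1)
    model = GTMModel(
        latent_grid=latent,
        rbf_centers=centers,
        rbf_width=rbf_width_factor * spacing,
        weights=np.zeros((centers.shape[0] + 1, D)),
        beta=1.0,
        scaling=(mean, std),
        regularization=regularization,
        grid_shape=(grid_size, grid_size),
    )
    Phi = model.phi()
    K = latent.shape[0]

    # initialization: PCA plane (deterministic) or seeded random weights
    if seed is None:
        # map the latent lattice onto the first two principal axes
        U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
        sv = np.sqrt((S**2) / n)
        targets = np.zeros((K, D))
        for a in range(min(2, len(S))):
            targets += np.outer(latent[:, a], sv[a] * Vt[a])
        W, *_ = np.linalg.lstsq(Phi, targets, rcond=None)
        lam3 = float(sv[2] ** 2) if len(S) > 2 else 0.0
    else:
        rng = np.random.default_rng(seed)
        W = rng.normal(scale=0.1, size=(Phi.shape[1], D))
        lam3 = 0.0
    model.weights = W
    mu = model.node_means()
    d = np.sort(((mu[:, None, :] - mu[None, :, :]) ** 2).sum(-1), axis=1)
    nn = float(np.mean(d[:, 1])) if K > 1 else 1.0
    model.beta = 1.0 / max(max(lam3, nn / 2.0), 1e-6)

    trace = []
    prev_obj = -np.inf
    for _ in range(max_iter):
        mu = model.node_means()
        d2 = ((Xs[:, None, :] - mu[None, :, :]) ** 2).sum(-1)    # n x K
        logp = 0.5 * D * (np.log(model.beta) - np.log(2 * np.pi)) - 0.5 * model.beta * d2
        lse = logsumexp(logp, axis=1)
        loglik = float(np.sum(lse - np.log(K)))
        obj = loglik - 0.5 * regularization * float((model.weights**2).sum())
        trace.append(obj)
        if np.isfinite(prev_obj) and abs(obj - prev_obj) < tol * (abs(prev_obj) + 1e-12):
            break
        prev_obj = obj

        R = np.exp(logp - lse[:, None])                          # n x K
        Gd = R.sum(axis=0)                                       # per-node mass
        lhs = (Phi.T * Gd) @ Phi + (regularization / model.beta) * np.eye(Phi.shape[1])
        rhs = Phi.T @ (R.T @ Xs)
        model.weights = np.linalg.solve(lhs, rhs)
        mu = model.node_means()
        d2 = ((Xs[:, None, :] - mu[None, :, :]) ** 2).sum(-1)
        new_beta = n * D / max(float((R * d2).sum()), 1e-300)
        if new_beta > beta_max:
            # noiseless data: nodes have collapsed onto the points and the
            # noise precision diverges; clamp and stop before numerics degrade
            model.beta = beta_max
            break
        model.beta = new_beta

    model.loglik_trace = np.array(trace)
    return model


def fit_gtmr(X: np.ndarray, Y: np.ndarray, **gtm_kwargs) -> GTMRModel:
    """Fit a joint GTM on [X | Y] for bidirectional regression."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"row mismatch: X has {X.shape[0]}, Y has {Y.shape[0]}")
    if Y.shape[1] < 1:
        raise ValueError("Y must have at least one property column")
    joint = np.column_stack([X, Y])
    gtm = fit_gtm(joint, **gtm_kwargs)
    return GTMRModel(
        gtm=gtm,
        x_dims=np.arange(X.shape[1]),
        y_dims=np.arange(X.shape[1], X.shape[1] + Y.shape[1]),
    )


def _conditional_predict(model: GTMRModel, query, cond_dims, target_dims) -> PredictionResult:
    gtm = model.gtm
    q = np.atleast_2d(np.asarray(query, dtype=float))
    if q.shape[1] != len(cond_dims):
        raise ValueError(f"query has {q.shape[1]} dims, expected {len(cond_dims)}")
    mean, std = gtm.scaling
    qs = (q - mean[cond_dims]) / std[cond_dims]
    R = gtm.responsibilities(qs, dims=cond_dims)
    mu_t = gtm.node_means()[:, target_dims]
    pred_scaled = R @ mu_t
    mode_scaled = mu_t[np.argmax(R, axis=1)]
    return PredictionResult(
        mean=gtm.unscale(pred_scaled, target_dims),
        mode=gtm.unscale(mode_scaled, target_dims),
        responsibilities=R,
    )


def predict_forward(model: GTMRModel, x_query) -> PredictionResult:
    """Predict properties from descriptors: condition node responsibilities on X."""
    return _conditional_predict(model, x_query, model.x_dims, model.y_dims)


def predict_inverse(model: GTMRModel, y_target) -> PredictionResult:
    """Predict descriptors (e.g. an STFT spectrum) from target properties."""
    return _conditional_predict(model, y_target, model.y_dims, model.x_dims)


def map_coordinates(model, data, mode: str = "mean") -> np.ndarray:
    """Latent 2-D coordinates of data rows (responsibility mean or argmax node)."""
    gtm = model.gtm if isinstance(model, GTMRModel) else model
    R = gtm.responsibilities(gtm.scale(data))
    if mode == "mean":
        return R @ gtm.latent_grid
    if mode == "mode":
        return gtm.latent_grid[np.argmax(R, axis=1)]
    raise ValueError(f"mode must be 'mean' or 'mode', got {mode!r}")


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yt.size != yp.size or yt.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    ss_tot = float(((yt - yt.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("y_true has zero variance; R^2 undefined")
    return 1.0 - float(((yt - yp) ** 2).sum()) / ss_tot


# ---------------------------------------------------------------------------
# spectrogram descriptors
# ---------------------------------------------------------------------------

def flatten_spectrograms(spectrograms, min_std: float = 0.0):
    """Row-major flatten spectrogram magnitudes into a descriptor matrix.

    Columns whose standard deviation across samples is <= ``min_std`` (e.g.
    empty baseline bins, which would break autoscaling) are dropped; the
    returned metadata records the spectrogram shape and the retained-column
    mask so inverse predictions can be un-flattened.
    """
    mats = [s.magnitude for s in spectrograms]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("all spectrograms must share one shape")
    X = np.stack([m.ravel() for m in mats])
    keep = X.std(axis=0) > min_std
    meta = {
        "shape": shape,
        "keep_mask": keep,
        "frame_times": spectrograms[0].frame_times,
        "frequencies": spectrograms[0].frequencies,
    }
    return X[:, keep], meta


def profile_to_spectrum(descriptor: np.ndarray, meta: dict):
    """Un-flatten an (inverse-predicted) descriptor and sum frames to a Spectrum1D."""
    from .io import Spectrum1D

    flat = np.zeros(int(np.prod(meta["shape"])))
    flat[meta["keep_mask"]] = np.asarray(descriptor, dtype=float).ravel()
    mag = flat.reshape(meta["shape"])
    return Spectrum1D(meta["frequencies"], mag.sum(axis=0), label="predicted spectrum")


# ---------------------------------------------------------------------------
# serialization: one .npz container with a JSON metadata entry
# ---------------------------------------------------------------------------

def save_gtmr(model: GTMRModel, path: str) -> None:
    gtm = model.gtm
    meta = {
        "rbf_width": gtm.rbf_width,
        "beta": gtm.beta,
        "regularization": gtm.regularization,
        "grid_shape": list(gtm.grid_shape),
    }
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        latent_grid=gtm.latent_grid,
        rbf_centers=gtm.rbf_centers,
        weights=gtm.weights,
        scale_mean=gtm.scaling[0],
        scale_std=gtm.scaling[1],
        loglik_trace=gtm.loglik_trace,
        x_dims=model.x_dims,
        y_dims=model.y_dims,
    )


def load_gtmr(path: str) -> GTMRModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        gtm = GTMModel(
            latent_grid=z["latent_grid"],
            rbf_centers=z["rbf_centers"],
            rbf_width=float(meta["rbf_width"]),
            weights=z["weights"],
            beta=float(meta["beta"]),
            scaling=(z["scale_mean"], z["scale_std"]),
            loglik_trace=z["loglik_trace"],
            regularization=float(meta["regularization"]),
            grid_shape=tuple(meta["grid_shape"]),
        )
        return GTMRModel(gtm=gtm, x_dims=z["x_dims"], y_dims=z["y_dims"])
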