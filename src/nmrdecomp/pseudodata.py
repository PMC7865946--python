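"""Gaussian-mixture pseudodata: fit a GMM to an existing dataset and draw
surrogate samples with the same distribution, for use as GTMR inputs when no
new experiments are available."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = ["GMMParams", "fit_gmm", "sample_pseudodata", "bic_scan", "write_pseudodata"]


@dataclass
class GMMParams:
    """Mixture weights / means / full covariances of a fitted GMM."""

    weights: np.ndarray       # simplex vector, length k
    means: np.ndarray         # k x D
    covariances: np.ndarray   # k x D x D, symmetric PSD
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")
        k, D = self.means.shape
        if self.covariances.shape != (k, D, D):
            raise ValueError("covariances must be (k, D, D)")
        for c, cov in enumerate(self.covariances):
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"covariance {c} is not symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-10:
                raise ValueError(f"covariance {c} is not positive semi-definite")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def mixture_mean(self) -> np.ndarray:
        return self.weights @ self.means

    def mixture_covariance(self) -> np.ndarray:
        m = self.mixture_mean()
        cov = np.zeros_like(self.covariances[0])
        for w, mu, S in zip(self.weights, self.means, self.covariances):
            d = mu - m
            cov += w * (S + np.outer(d, d))
        return cov


def fit_gmm(
    data: np.ndarray,
    n_components: int,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
    reg_covar: float = 1e-6,
) -> GMMParams:
    """EM-fit a full-covariance GMM (diagonal regularization ``reg_covar``)."""
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.ndim != 2 or np.isnan(X).any():
        raise ValueError("data must be a 2-D matrix without missing values")
    if n_components < 1:
        raise ValueError(f"n_components must be >= 1, got {n_components}")
    if X.shape[0] <= n_components:
        raise ValueError(f"need more rows ({X.shape[0]}) than components ({n_components})")
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        max_iter=max_iter,
        tol=tol,
        reg_covar=reg_covar,
        random_state=seed,
        n_init=3,
    ).fit(X)
    covs = 0.5 * (gm.covariances_ + np.swapaxes(gm.covariances_, 1, 2))
    return GMMParams(weights=gm.weights_, means=gm.means_, covariances=covs, seed=seed)


def sample_pseudodata(params: GMMParams, n: int, seed: Optional[int] = None) -> np.ndarray:
    """Draw n i.i.d. pseudodata rows: component by weight, then multivariate normal."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    counts = rng.multinomial(n, params.weights)
    blocks = [
        rng.multivariate_normal(mu, cov, size=c, method="svd")
        for mu, cov, c in zip(params.means, params.covariances, counts)
        if c > 0
    ]
    out = np.vstack(blocks)
    return out[rng.permutation(n)]


def bic_scan(data: np.ndarray, ks: Sequence[int], **kwargs) -> list:
    """(k, BIC) pairs over candidate component counts, to guide model choice."""
    X = np.atleast_2d(np.asarray(data, dtype=float))
    out = []
    for k in ks:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            random_state=kwargs.get("seed", 0),
            reg_covar=kwargs.get("reg_covar", 1e-6),
        ).fit(X)
        out.append((k, float(gm.bic(X))))
    return out


def write_pseudodata(
    data: np.ndarray,
    path: str,
    source: Optional[str] = None,
    seed: Optional[int] = None,
    n_components: Optional[int] = None,
) -> None:
    """Write pseudodata as CSV with a provenance header (source hash, seed, k)."""
    lines = []
    if source is not None:
        try:
            digest = hashlib.sha256(open(source, "rb").read()).hexdigest()
        except OSError:
            digest = "unavailable"
        lines.append(f"# source = {source} (sha256 {digest})")
    lines.append(f"# seed = {seed}")
    lines.append(f"# n_components = {n_components}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, np.atleast_2d(data), delimiter=",")
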