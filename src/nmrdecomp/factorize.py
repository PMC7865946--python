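"""Non-negative matrix and tensor factorization of STFT spectrograms.

A magnitude spectrogram of a multi-component FID is approximately additive
over components, each contributing (decay profile) x (line shape).  NMF
factors one spectrogram V(t, f) into k such rank-1 terms; for a series of
samples the stacked tensor X(sample, t, f) is factored either by
non-negative Tucker decomposition (NTD: small core G plus per-mode factor
matrices A, B, C) or non-negative canonical polyadic decomposition (NCPD:
a plain sum of rank-1 outer products).  All three solvers use Frobenius-loss
multiplicative updates, which keep every factor entry non-negative and never
increase the objective.

Identifiability conventions: frequency profiles are normalized to unit
maximum with the absorbed scale pushed into the time profiles (NMF) or the
core / sample factors (NTD / NCPD), and components are reported sorted by
decreasing energy.  Rank is user-specified; ``rank_scan`` helps choose it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectro import Spectrogram, SpectroTensor

__all__ = [
    "DeconvolutionResult",
    "nmf",
    "ntd",
    "ncpd",
    "align_components",
    "fit_decay_constant",
    "core_pairing",
    "rank_scan",
]

_EPS = 1e-12
# convergence is judged on the objective change across this many iterations,
# so a slow-start plateau of the multiplicative updates is not mistaken for
# convergence
_CHECK_INTERVAL = 10


@dataclass
class DeconvolutionResult:
    """Separated components from NMF/NTD/NCPD.

    freq_profiles[c] is component c's spectrum (unit maximum); time_profiles[c]
    its frame-by-frame decay pattern (carries T2* information);
    sample_profiles[c] its loading across samples (absent for NMF).  ``core``
    is the NTD core tensor.  ``rel_error`` is ||X - Xhat||_F / ||X||_F.
    """

    method: str
    n_components: Union[int, Tuple[int, int, int]]
    freq_profiles: np.ndarray
    time_profiles: np.ndarray
    sample_profiles: Optional[np.ndarray] = None
    core: Optional[np.ndarray] = None
    rel_error: float = float("nan")
    n_iter: int = 0
    seed: Optional[int] = None
    converged: bool = False
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def reconstruct(self) -> np.ndarray:
        """Reassemble the model approximation Xhat from the stored factors."""
        if self.method == "nmf":
            return self.time_profiles.T @ self.freq_profiles
        A = self.sample_profiles.T
        B = self.time_profiles.T
        C = self.freq_profiles.T
        if self.method == "ncpd":
            return np.einsum("ir,jr,kr->ijk", A, B, C)
        return np.einsum("pqr,ip,jq,kr->ijk", self.core, A, B, C)

    def spectral_sample_profiles(self) -> Optional[np.ndarray]:
        """Sample loading of each *spectral* component (component x sample).

        For NTD the spectral (frequency-mode) components need not pair
        one-to-one with sample-mode factor columns; contracting the core and
        the sample/time factors over all frames gives the total amount of
        spectral component r present in each sample, which is the
        "composition" time course the factorization implies.  For NCPD this
        is just ``sample_profiles``.
        """
        if self.sample_profiles is None:
            return None
        if self.method == "ncpd":
            return self.sample_profiles
        return np.einsum(
            "ip,jq,pqr->ri", self.sample_profiles.T, self.time_profiles.T, self.core,
            optimize=True,
        )

    def spectral_time_profiles(self) -> np.ndarray:
        """Frame-by-frame decay of each spectral component, summed over samples."""
        if self.method == "nmf" or self.method == "ncpd":
            return self.time_profiles
        return np.einsum(
            "ip,jq,pqr->rj", self.sample_profiles.T, self.time_profiles.T, self.core,
            optimize=True,
        )

    def sample_fractions(self) -> Optional[np.ndarray]:
        """Per-sample composition renormalized to fractions (columns sum to 1)."""
        if self.sample_profiles is None:
            return None
        tot = self.sample_profiles.sum(axis=0, keepdims=True)
        return self.sample_profiles / np.where(tot > 0, tot, 1.0)


def _as_matrix(spectrogram) -> np.ndarray:
    V = spectrogram.magnitude if isinstance(spectrogram, Spectrogram) else np.asarray(spectrogram, float)
    if V.ndim != 2:
        raise ValueError("NMF input must be 2-D (frames x frequencies)")
    if (V < 0).any():
        raise ValueError("NMF input must be non-negative")
    return V


def _as_tensor(tensor) -> np.ndarray:
    X = tensor.magnitude if isinstance(tensor, SpectroTensor) else np.asarray(tensor, float)
    if X.ndim != 3:
        raise ValueError("tensor input must be 3-D (samples x frames x frequencies)")
    if (X < 0).any():
        raise ValueError("tensor input must be non-negative")
    return X


def _check_scale(norm: float) -> None:
    if norm == 0:
        raise ValueError("input is identically zero; factorization has no scale")


def nmf(
    spectrogram,
    k: int,
    max_iter: int = 2000,
    tol: float = 1e-3,
    n_restarts: int = 5,
    seed: int = 0,
    init: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    track_objective: bool = False,
) -> DeconvolutionResult:
    """Non-negative matrix factorization V(t, f) ~ sum_c w_c(t) h_c(f).

    Runs ``n_restarts`` seeded random initializations (or a single run from
    ``init=(W0, H0)``; a W0 with fewer than k columns is padded with tiny
    positive entries, giving nested-rank warm starts) and keeps the best fit.
    Convergence: relative change of the Frobenius objective < ``tol``.
    """
    V = _as_matrix(spectrogram)
    n_t, n_f = V.shape
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > min(n_t, n_f):
        raise ValueError(f"k={k} exceeds min(n_frames, n_freq)={min(n_t, n_f)}")
    norm = np.linalg.norm(V)
    _check_scale(norm)

    rng = np.random.default_rng(seed)
    scale = math.sqrt(V.mean() / k)
    best = None
    restarts = 1 if init is not None else max(1, n_restarts)
    for restart in range(restarts):
        if init is not None:
            W0, H0 = init
            W = np.full((n_t, k), _EPS + scale * 1e-6)
            H = np.full((k, n_f), _EPS + scale * 1e-6)
            W[:, : W0.shape[1]] = np.maximum(W0, _EPS)
            H[: H0.shape[0], :] = np.maximum(H0, _EPS)
        elif restart == 0:
            # deterministic absolute-value SVD start (NNDSVD-like): converges
            # much faster than random and reaches better optima at the
            # default tolerance
            U, S, Vt = np.linalg.svd(V, full_matrices=False)
            W = np.abs(U[:, :k]) * np.sqrt(S[:k])[None, :] + _EPS
            H = np.sqrt(S[:k])[:, None] * np.abs(Vt[:k]) + _EPS
        else:
            W = scale * rng.random((n_t, k)) + _EPS
            H = scale * rng.random((k, n_f)) + _EPS
        trace = []
        err = np.linalg.norm(V - W @ H) / norm
        trace.append(err)
        checkpoint = err
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
            H *= (W.T @ V) / ((W.T @ W) @ H + _EPS)
            err = np.linalg.norm(V - W @ H) / norm
            if track_objective:
                trace.append(err)
            if it % _CHECK_INTERVAL == 0:
                if checkpoint - err < tol * checkpoint:
                    converged = True
                    break
                checkpoint = err
        if best is None or err < best[0]:
            best = (err, W.copy(), H.copy(), it, converged, np.array(trace))

    err, W, H, it, converged, trace = best
    W, H = _normalize_nmf(W, H)
    return DeconvolutionResult(
        method="nmf",
        n_components=k,
        freq_profiles=H,
        time_profiles=W.T,
        rel_error=float(err),
        n_iter=it,
        seed=seed,
        converged=converged,
        objective_trace=trace,
    )


def _normalize_nmf(W: np.ndarray, H: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    peaks = H.max(axis=1)
    peaks = np.where(peaks > 0, peaks, 1.0)
    H = H / peaks[:, None]
    W = W * peaks[None, :]
    energy = np.linalg.norm(W, axis=0) * np.linalg.norm(H, axis=1)
    order = np.argsort(-energy)
    return W[:, order], H[order]


# ---------------------------------------------------------------------------
# NTD
# ---------------------------------------------------------------------------

def _tucker_reconstruct(G, A, B, C) -> np.ndarray:
    return np.einsum("pqr,ip,jq,kr->ijk", G, A, B, C, optimize=True)


def _abs_svd_factor(X: np.ndarray, mode: int, rank: int) -> np.ndarray:
    unf = np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)
    U = np.linalg.svd(unf, full_matrices=False)[0]
    return np.abs(U[:, :rank]) + _EPS


def ntd(
    tensor,
    ranks: Tuple[int, int, int],
    max_iter: int = 2000,
    tol: float = 1e-3,
    n_restarts: int = 5,
    seed: int = 0,
    track_objective: bool = False,
) -> DeconvolutionResult:
    """Non-negative Tucker decomposition X ~ G x1 A x2 B x3 C.

    A (samples x r1) holds compositions, B (frames x r2) decay patterns,
    C (frequencies x r3) component spectra; G couples them.  Multiplicative
    updates on the Frobenius loss; best of ``n_restarts`` seeded runs.
    """
    X = _as_tensor(tensor)
    dims = X.shape
    ranks = tuple(int(r) for r in ranks)
    if len(ranks) != 3:
        raise ValueError("ranks must be a (sample, time, frequency) triple")
    for r, d, name in zip(ranks, dims, ("sample", "time", "frequency")):
        if not 1 <= r <= d:
            raise ValueError(f"{name} rank {r} outside [1, {d}]")
    norm = np.linalg.norm(X)
    _check_scale(norm)

    rng = np.random.default_rng(seed)
    scale = (X.mean() / np.prod(ranks)) ** (1 / 4)
    best = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            # deterministic start from the absolute values of the truncated
            # HOSVD factors; the core is the corresponding contraction
            A, B, C = (_abs_svd_factor(X, m, r) for m, r in enumerate(ranks))
            G = np.abs(np.einsum("ijk,ip,jq,kr->pqr", X, A, B, C, optimize=True)) + _EPS
        else:
            A = scale * rng.random((dims[0], ranks[0])) + _EPS
            B = scale * rng.random((dims[1], ranks[1])) + _EPS
            C = scale * rng.random((dims[2], ranks[2])) + _EPS
            G = scale * rng.random(ranks) + _EPS
        Xhat = _tucker_reconstruct(G, A, B, C)
        err = np.linalg.norm(X - Xhat) / norm
        trace = [err]
        checkpoint = err
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # factor updates: numerator/denominator share the contraction
            # X(1) (C kron B) G(1)^T computed via einsum on X and Xhat
            num = np.einsum("ijk,jq,kr,pqr->ip", X, B, C, G, optimize=True)
            den = np.einsum("ijk,jq,kr,pqr->ip", Xhat, B, C, G, optimize=True)
            A *= num / (den + _EPS)
            Xhat = _tucker_reconstruct(G, A, B, C)

            num = np.einsum("ijk,ip,kr,pqr->jq", X, A, C, G, optimize=True)
            den = np.einsum("ijk,ip,kr,pqr->jq", Xhat, A, C, G, optimize=True)
            B *= num / (den + _EPS)
            Xhat = _tucker_reconstruct(G, A, B, C)

            num = np.einsum("ijk,ip,jq,pqr->kr", X, A, B, G, optimize=True)
            den = np.einsum("ijk,ip,jq,pqr->kr", Xhat, A, B, G, optimize=True)
            C *= num / (den + _EPS)
            Xhat = _tucker_reconstruct(G, A, B, C)

            num = np.einsum("ijk,ip,jq,kr->pqr", X, A, B, C, optimize=True)
            den = np.einsum("ijk,ip,jq,kr->pqr", Xhat, A, B, C, optimize=True)
            G *= num / (den + _EPS)
            Xhat = _tucker_reconstruct(G, A, B, C)

            err = np.linalg.norm(X - Xhat) / norm
            if track_objective:
                trace.append(err)
            if it % _CHECK_INTERVAL == 0:
                if checkpoint - err < tol * checkpoint:
                    converged = True
                    break
                checkpoint = err
        if best is None or err < best[0]:
            best = (err, A.copy(), B.copy(), C.copy(), G.copy(), it, converged, np.array(trace))

    err, A, B, C, G, it, converged, trace = best
    A, B, C, G = _normalize_tucker(A, B, C, G)
    return DeconvolutionResult(
        method="ntd",
        n_components=ranks,
        freq_profiles=C.T,
        time_profiles=B.T,
        sample_profiles=A.T,
        core=G,
        rel_error=float(err),
        n_iter=it,
        seed=seed,
        converged=converged,
        objective_trace=trace,
    )


def _normalize_tucker(A, B, C, G):
    # push B and C column scales into the core; order modes by core energy
    for mode, M in ((1, B), (2, C)):
        peaks = M.max(axis=0)
        peaks = np.where(peaks > 0, peaks, 1.0)
        M /= peaks[None, :]
        shape = [1, 1, 1]
        shape[mode] = -1
        G = G * peaks.reshape(shape)
    orders = []
    for mode in range(3):
        energy = np.sqrt((np.moveaxis(G, mode, 0).reshape(G.shape[mode], -1) ** 2).sum(axis=1))
        orders.append(np.argsort(-energy))
    A = A[:, orders[0]]
    B = B[:, orders[1]]
    C = C[:, orders[2]]
    G = G[np.ix_(orders[0], orders[1], orders[2])]
    return A, B, C, G


def core_pairing(result: DeconvolutionResult) -> list:
    """Pair sample/time/frequency components across NTD modes via the core.

    Greedily selects the largest core entries with mutually unused indices;
    meaningful when the three ranks are equal.  Returns (i, j, k) triples.
    """
    if result.core is None:
        raise ValueError("core_pairing requires an NTD result")
    G = np.abs(result.core.copy())
    n = min(G.shape)
    triples = []
    for _ in range(n):
        i, j, k = np.unravel_index(np.argmax(G), G.shape)
        triples.append((int(i), int(j), int(k)))
        G[i, :, :] = -1
        G[:, j, :] = -1
        G[:, :, k] = -1
    return triples


# ---------------------------------------------------------------------------
# NCPD
# ---------------------------------------------------------------------------

def ncpd(
    tensor,
    k: int,
    max_iter: int = 2000,
    tol: float = 1e-3,
    n_restarts: int = 5,
    seed: int = 0,
    track_objective: bool = False,
) -> DeconvolutionResult:
    """Non-negative canonical polyadic decomposition X ~ sum_c a_c o b_c o c_c."""
    X = _as_tensor(tensor)
    dims = X.shape
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    norm = np.linalg.norm(X)
    _check_scale(norm)

    rng = np.random.default_rng(seed)
    scale = (X.mean() / k) ** (1 / 3)
    best = None
    for restart in range(max(1, n_restarts)):
        if restart == 0 and k <= min(dims):
            A, B, C = (_abs_svd_factor(X, m, k) for m in range(3))
            s = (np.linalg.norm(X) / max(k, 1)) ** (1 / 3)
            A, B, C = A * s, B * s, C * s
        else:
            A = scale * rng.random((dims[0], k)) + _EPS
            B = scale * rng.random((dims[1], k)) + _EPS
            C = scale * rng.random((dims[2], k)) + _EPS
        err = np.linalg.norm(X - np.einsum("ir,jr,kr->ijk", A, B, C)) / norm
        trace = [err]
        checkpoint = err
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            A *= np.einsum("ijk,jr,kr->ir", X, B, C, optimize=True) / (
                A @ ((B.T @ B) * (C.T @ C)) + _EPS
            )
            B *= np.einsum("ijk,ir,kr->jr", X, A, C, optimize=True) / (
                B @ ((A.T @ A) * (C.T @ C)) + _EPS
            )
            C *= np.einsum("ijk,ir,jr->kr", X, A, B, optimize=True) / (
                C @ ((A.T @ A) * (B.T @ B)) + _EPS
            )
            err = np.linalg.norm(X - np.einsum("ir,jr,kr->ijk", A, B, C)) / norm
            if track_objective:
                trace.append(err)
            if it % _CHECK_INTERVAL == 0:
                if checkpoint - err < tol * checkpoint:
                    converged = True
                    break
                checkpoint = err
        if best is None or err < best[0]:
            best = (err, A.copy(), B.copy(), C.copy(), it, converged, np.array(trace))

    err, A, B, C, it, converged, trace = best
    # unit-max b_c and c_c; scale absorbed into the sample loadings a_c
    for M in (B, C):
        peaks = M.max(axis=0)
        peaks = np.where(peaks > 0, peaks, 1.0)
        M /= peaks[None, :]
        A *= peaks[None, :]
    energy = np.linalg.norm(A, axis=0) * np.linalg.norm(B, axis=0) * np.linalg.norm(C, axis=0)
    order = np.argsort(-energy)
    A, B, C = A[:, order], B[:, order], C[:, order]
    return DeconvolutionResult(
        method="ncpd",
        n_components=k,
        freq_profiles=C.T,
        time_profiles=B.T,
        sample_profiles=A.T,
        rel_error=float(err),
        n_iter=it,
        seed=seed,
        converged=converged,
        objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# post-processing helpers
# ---------------------------------------------------------------------------

def align_components(
    result: Union[DeconvolutionResult, np.ndarray], reference: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Match recovered frequency profiles to reference spectra.

    Hungarian assignment maximizing total cosine similarity.  Returns
    ``(permutation, similarities)`` where ``permutation[i]`` is the component
    index assigned to reference row i.  If the counts differ, only
    ``min(n_ref, n_comp)`` pairs are assigned.
    """
    profiles = result.freq_profiles if isinstance(result, DeconvolutionResult) else np.asarray(result, float)
    reference = np.asarray(reference, dtype=float)
    if profiles.shape[1] != reference.shape[1]:
        raise ValueError(
            f"frequency axis mismatch: {profiles.shape[1]} vs {reference.shape[1]}"
        )
    ref_n = reference / (np.linalg.norm(reference, axis=1, keepdims=True) + _EPS)
    prof_n = profiles / (np.linalg.norm(profiles, axis=1, keepdims=True) + _EPS)
    sim = ref_n @ prof_n.T
    rows, cols = linear_sum_assignment(-sim)
    return cols, sim[rows, cols]


def fit_decay_constant(
    time_profile: np.ndarray, frame_times: np.ndarray, threshold: float = 0.05
) -> float:
    """Estimate T2* from a component's frame-magnitude decay.

    Least-squares line fit of log(profile) vs time over entries above
    ``threshold`` x max; returns -1/slope in seconds, or ``inf`` when the
    profile does not decay.
    """
    p = np.asarray(time_profile, dtype=float)
    t = np.asarray(frame_times, dtype=float)
    if p.shape != t.shape:
        raise ValueError("time_profile and frame_times must have equal length")
    if (p < 0).any():
        raise ValueError("time_profile must be non-negative")
    if not p.any():
        raise ValueError("time_profile is identically zero")
    mask = p > threshold * p.max()
    if mask.sum() < 3:
        raise ValueError(f"only {int(mask.sum())} points above threshold; need >= 3")
    slope = np.polyfit(t[mask], np.log(p[mask]), 1)[0]
    span = t[mask].max() - t[mask].min()
    if slope >= 0 or (span > 0 and -slope * span < 1e-6):
        return float("inf")  # no measurable decay
    return float(-1.0 / slope)


def rank_scan(data, ks: Sequence, method: str = "nmf", **kwargs) -> list:
    """Relative reconstruction error as a function of rank, to guide rank choice."""
    out = []
    for k in ks:
        if method == "nmf":
            res = nmf(data, k, **kwargs)
        elif method == "ncpd":
            res = ncpd(data, k, **kwargs)
        elif method == "ntd":
            res = ntd(data, k if isinstance(k, tuple) else (k, k, k), **kwargs)
        else:
            raise ValueError(f"unknown method {method!r}")
        out.append((k, res.rel_error))
    return out
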