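"""Affine-invariant Riemannian geometry on symmetric positive-definite matrices.

Spatial covariance matrices of band-filtered EEG epochs live on the SPD
manifold.  Every performance metric in this package is built from three
primitives on that manifold:

* the affine-invariant distance ``delta_R(A, B) = ||log(A^{-1/2} B A^{-1/2})||_F``,
* the Fréchet (geometric) mean, the minimiser of the sum of squared distances,
* the geodesic ``A #_t B`` connecting two SPD matrices, used for weighted
  mean updates.

All operations are invariant under congruence ``X -> W X W^T`` for any
invertible ``W`` — i.e. under arbitrary full-rank spatial remixing of the
EEG channels — which is what makes the derived metrics montage-agnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

logger = logging.getLogger("bcitrack")

__all__ = [
    "GeometryConfig",
    "trial_covariance",
    "riemannian_distance",
    "distances_to",
    "frechet_mean",
    "geodesic_power",
]


@dataclass
class GeometryConfig:
    """Numerical knobs for SPD computations.

    Parameters
    ----------
    mean_tolerance:
        Fréchet-mean iterations stop once the Frobenius norm of the mean
        tangent vector falls below this value.
    mean_max_iterations:
        Hard cap on fixed-point iterations; on hitting it a warning is
        logged and the best iterate returned.
    spd_jitter:
        Diagonal loading used to restore positive-definiteness of
        degenerate covariance estimates.  Applied only when the smallest
        eigenvalue is non-positive.
    """

    mean_tolerance: float = 1e-8
    mean_max_iterations: int = 50
    spd_jitter: float = 1e-10

    def __post_init__(self) -> None:
        if self.mean_tolerance <= 0:
            raise ValueError("mean_tolerance must be > 0")
        if self.mean_max_iterations < 1:
            raise ValueError("mean_max_iterations must be >= 1")
        if self.spd_jitter < 0:
            raise ValueError("spd_jitter must be >= 0")


DEFAULT_CONFIG = GeometryConfig()


def _validate_spd(mat: np.ndarray, name: str = "matrix", tol: float = 1e-8) -> None:
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square, got shape {mat.shape}")
    sym_err = np.max(np.abs(mat - mat.T))
    scale = max(np.max(np.abs(mat)), 1.0)
    if sym_err > tol * scale:
        raise ValueError(f"{name} is not symmetric (max asymmetry {sym_err:.3g})")
    w = np.linalg.eigvalsh((mat + mat.T) / 2)
    if w[0] <= 0:
        raise ValueError(f"{name} is not positive definite (min eigenvalue {w[0]:.3g})")


def trial_covariance(
    epoch: np.ndarray, config: GeometryConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Spatial sample covariance of one band-filtered epoch.

    Parameters
    ----------
    epoch:
        ``(channels, samples)`` array; requires more samples than channels.
    config:
        Supplies the diagonal jitter used if the estimate is not SPD.

    Returns
    -------
    ``(channels, channels)`` SPD matrix (divisor ``samples - 1``,
    symmetrised; jitter applied only when the smallest eigenvalue is
    non-positive).
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise ValueError("epoch must be 2-D (channels x samples)")
    n_ch, n_s = epoch.shape
    if n_s <= n_ch:
        raise ValueError(
            f"degenerate epoch: {n_s} samples for {n_ch} channels "
            "(need samples > channels)"
        )
    centered = epoch - epoch.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / (n_s - 1)
    cov = (cov + cov.T) / 2
    w = np.linalg.eigvalsh(cov)
    if w[0] <= 0:
        eps = max(config.spd_jitter, 1e-10 * np.trace(cov) / n_ch)
        cov = cov + eps * np.eye(n_ch)
        while np.linalg.eigvalsh(cov)[0] <= 0:
            eps *= 10
            cov = cov + eps * np.eye(n_ch)
    return cov


def riemannian_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Affine-invariant Riemannian distance between two SPD matrices.

    Computed as the square root of the sum of squared log generalized
    eigenvalues of the pencil ``(a, b)`` — numerically preferable to
    forming an explicit inverse.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    _validate_spd(a, "a")
    _validate_spd(b, "b")
    ev = scipy.linalg.eigh(a, b, eigvals_only=True)
    return float(np.sqrt(np.sum(np.log(ev) ** 2)))


def _inv_sqrtm(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (mat^{1/2}, mat^{-1/2}) via eigendecomposition."""
    w, v = np.linalg.eigh(mat)
    if w[0] <= 0:
        raise ValueError("matrix is not positive definite")
    sq = (v * np.sqrt(w)) @ v.T
    isq = (v / np.sqrt(w)) @ v.T
    return sq, isq


def distances_to(ref: np.ndarray, mats: np.ndarray) -> np.ndarray:
    """Riemannian distances from ``ref`` to a stack of SPD matrices.

    Vectorised over the stack: ``mats`` has shape ``(n, d, d)``.  The
    stack is whitened by ``ref^{-1/2}`` once, then a single batched
    eigendecomposition yields all distances.
    """
    mats = np.asarray(mats, dtype=float)
    _, isq = _inv_sqrtm(np.asarray(ref, dtype=float))
    whitened = isq @ mats @ isq
    w = np.linalg.eigvalsh((whitened + np.swapaxes(whitened, -1, -2)) / 2)
    if np.any(w <= 0):
        raise ValueError("non-SPD matrix in stack")
    return np.sqrt(np.sum(np.log(w) ** 2, axis=-1))


def frechet_mean(
    mats: np.ndarray,
    weights: np.ndarray | None = None,
    config: GeometryConfig = DEFAULT_CONFIG,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted Fréchet mean of SPD matrices under the affine-invariant metric.

    Fixed-point iteration in the tangent space at the current estimate,
    initialised at the (weighted) arithmetic mean unless ``init`` is
    given (engines warm-start from the previous trial's mean).  Stops
    when the tangent-space gradient norm drops below
    ``config.mean_tolerance``; non-convergence logs a warning and
    returns the best iterate.
    """
    mats = np.asarray(mats, dtype=float)
    if mats.ndim == 2:
        mats = mats[None]
    if mats.ndim != 3 or mats.shape[1] != mats.shape[2]:
        raise ValueError("mats must be a (n, d, d) stack of square matrices")
    n = mats.shape[0]
    if n == 0:
        raise ValueError("cannot average an empty set of matrices")
    if weights is None:
        w_arr = np.full(n, 1.0 / n)
    else:
        w_arr = np.asarray(weights, dtype=float)
        if w_arr.shape != (n,) or np.any(w_arr < 0):
            raise ValueError("weights must be n non-negative reals")
        if not np.isclose(w_arr.sum(), 1.0):
            raise ValueError("weights must sum to 1")
    if n == 1:
        return mats[0].copy()

    est = np.asarray(init, dtype=float) if init is not None else np.tensordot(w_arr, mats, axes=1)
    for _ in range(config.mean_max_iterations):
        sq, isq = _inv_sqrtm(est)
        whitened = isq @ mats @ isq
        whitened = (whitened + np.swapaxes(whitened, -1, -2)) / 2
        ev, vec = np.linalg.eigh(whitened)
        if np.any(ev <= 0):
            raise ValueError("non-SPD matrix encountered while averaging")
        logs = (vec * np.log(ev)[:, None, :]) @ np.swapaxes(vec, -1, -2)
        tangent = np.tensordot(w_arr, logs, axes=1)
        grad_norm = np.linalg.norm(tangent, "fro")
        if grad_norm <= config.mean_tolerance:
            return est
        tw, tv = np.linalg.eigh(tangent)
        step = (tv * np.exp(tw)) @ tv.T
        est = sq @ step @ sq
        est = (est + est.T) / 2
    logger.warning(
        "Fréchet mean did not converge in %d iterations (gradient norm %.3g)",
        config.mean_max_iterations,
        grad_norm,
    )
    warnings.warn(
        f"Fréchet mean did not converge (gradient norm {grad_norm:.3g})",
        RuntimeWarning,
        stacklevel=2,
    )
    return est


def geodesic_power(base: np.ndarray, target: np.ndarray, alpha: float) -> np.ndarray:
    """Point at parameter ``alpha`` on the geodesic from ``base`` to ``target``.

    ``base^{1/2} (base^{-1/2} target base^{-1/2})^alpha base^{1/2}``; the
    Riemannian analogue of the Euclidean convex sum
    ``(1 - alpha) * base + alpha * target``.  ``alpha = 0`` returns
    ``base``, ``alpha = 1`` returns ``target``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    base = np.asarray(base, dtype=float)
    target = np.asarray(target, dtype=float)
    if base.shape != target.shape:
        raise ValueError("dimension mismatch between base and target")
    _validate_spd(base, "base")
    _validate_spd(target, "target")
    if alpha == 0.0:
        return base.copy()
    if alpha == 1.0:
        return target.copy()
    sq, isq = _inv_sqrtm(base)
    inner = isq @ target @ isq
    inner = (inner + inner.T) / 2
    w, v = np.linalg.eigh(inner)
    powered = (v * w**alpha) @ v.T
    out = sq @ powered @ sq
    return (out + out.T) / 2
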