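"""Geometry of symmetric positive-definite (SPD) matrices.

Covariance features live on the SPD manifold; the decoder maps them to a
Euclidean tangent space at a reference point (the affine-invariant
geometric mean of the training covariances) before classification.
All routines are batched over a leading axis where useful.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

__all__ = [
    "sym_powm",
    "logm_spd",
    "expm_sym",
    "geometric_mean",
    "tangent_map",
    "tangent_unmap",
    "vec_upper",
    "unvec_upper",
]


def _eigh(mats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, u = np.linalg.eigh(mats)
    return w, u


def sym_powm(mat: np.ndarray, power: float) -> np.ndarray:
    """Matrix power of an SPD matrix (batched on leading axes)."""
    w, u = _eigh(mat)
    if np.any(w <= 0):
        raise np.linalg.LinAlgError("matrix is not positive definite")
    return (u * (w**power)[..., None, :]) @ np.swapaxes(u, -1, -2)


def logm_spd(mat: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix (batched)."""
    w, u = _eigh(mat)
    if np.any(w <= 0):
        raise np.linalg.LinAlgError("matrix is not positive definite")
    return (u * np.log(w)[..., None, :]) @ np.swapaxes(u, -1, -2)


def expm_sym(mat: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (batched)."""
    w, u = _eigh(mat)
    return (u * np.exp(w)[..., None, :]) @ np.swapaxes(u, -1, -2)


def geometric_mean(
    covs: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> np.ndarray:
    """Affine-invariant (Karcher) mean of a stack of SPD matrices.

    Fixed-point iteration initialized at the arithmetic mean:
    ``M <- M^1/2 exp(mean_i log(M^-1/2 C_i M^-1/2)) M^1/2``, stopping when
    the Frobenius norm of the mean tangent update drops below ``tol``.
    """
    covs = np.asarray(covs, float)
    if covs.ndim != 3:
        raise ValueError("covs must be a stack of matrices (n, m, m)")
    if covs.shape[0] == 1:
        return covs[0].copy()
    mean = covs.mean(axis=0)
    for _ in range(max_iter):
        rt = sym_powm(mean, 0.5)
        irt = sym_powm(mean, -0.5)
        tangents = logm_spd(irt @ covs @ irt)
        update = tangents.mean(axis=0)
        mean = rt @ expm_sym(update) @ rt
        mean = 0.5 * (mean + mean.T)
        if np.linalg.norm(update, "fro") < tol:
            return mean
    raise RuntimeError(
        "geometric mean did not converge within "
        f"{max_iter} iterations (last update norm "
        f"{np.linalg.norm(update, 'fro'):.3e})"
    )


def _upper_indices(m: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(m)


def vec_upper(sym: np.ndarray) -> np.ndarray:
    """Vectorize a symmetric matrix with sqrt(2)-weighted off-diagonals.

    The weighting makes the Euclidean norm of the vector equal the
    Frobenius norm of the matrix.  Batched on leading axes.
    """
    m = sym.shape[-1]
    iu, ju = _upper_indices(m)
    weights = np.where(iu == ju, 1.0, np.sqrt(2.0))
    return sym[..., iu, ju] * weights


def unvec_upper(v: np.ndarray, m: int) -> np.ndarray:
    """Inverse of :func:`vec_upper`."""
    iu, ju = _upper_indices(m)
    weights = np.where(iu == ju, 1.0, 1.0 / np.sqrt(2.0))
    out = np.zeros(v.shape[:-1] + (m, m))
    out[..., iu, ju] = v * weights
    out = out + np.swapaxes(out, -1, -2)
    out[..., np.arange(m), np.arange(m)] *= 0.5
    return out


def tangent_map(cov: np.ndarray, c_ref: np.ndarray) -> np.ndarray:
    """Project SPD matrices to the tangent space at ``c_ref``.

    ``v = vec_upper(log(C_ref^-1/2 C C_ref^-1/2))``; batched over a
    leading axis of ``cov``.
    """
    irt = sym_powm(c_ref, -0.5)
    return vec_upper(logm_spd(irt @ cov @ irt))


def tangent_unmap(v: np.ndarray, c_ref: np.ndarray) -> np.ndarray:
    """Map tangent vectors back to SPD matrices (inverse of tangent_map)."""
    m = c_ref.shape[-1]
    rt = sym_powm(c_ref, 0.5)
    return rt @ expm_sym(unvec_upper(v, m)) @ rt


def logm_frechet_adjoint(mat: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Adjoint of the Frechet derivative of logm at SPD ``mat``.

    Given dJ/d(log M) = ``grad`` (symmetric), returns dJ/dM.  Uses the
    Daleckii-Krein formula on the eigenbasis: divided differences of log
    on the spectrum.  Batched on leading axes.
    """
    w, u = _eigh(mat)
    if np.any(w <= 0):
        raise np.linalg.LinAlgError("matrix is not positive definite")
    lw = np.log(w)
    num = lw[..., :, None] - lw[..., None, :]
    den = w[..., :, None] - w[..., None, :]
    near = np.abs(den) < 1e-12 * np.maximum(np.abs(w[..., :, None]), 1.0)
    # divided difference -> 1/lambda on (near-)coincident eigenvalues
    loewner = np.where(near, 1.0 / w[..., :, None], num / np.where(near, 1.0, den))
    inner = np.swapaxes(u, -1, -2) @ grad @ u
    return u @ (loewner * inner) @ np.swapaxes(u, -1, -2)
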