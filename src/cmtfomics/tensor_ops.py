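"""Dense 3-way tensor algebra primitives.

These are the building blocks for coupled matrix-tensor factorization
(CMTF): mode-n matricization and its inverse, the Khatri-Rao product,
CP (CANDECOMP/PARAFAC) reconstruction and the residual error metrics
shared by both fitting frameworks.

Tensors are plain ``numpy`` arrays with the canonical axis order
``(sample, microbe, pathway)``; the shared sample mode is always first.
Matricization follows the Kolda-Bader mode-n convention: rows index the
chosen mode and columns enumerate the remaining modes with the
lower-numbered mode varying fastest.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "matricize",
    "fold",
    "khatri_rao",
    "cp_reconstruct",
    "matrix_reconstruct",
    "tensor_vector_contract",
    "residual_norms",
]


def _check_mode(mode: int) -> None:
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode!r}")


def matricize(t: np.ndarray, mode: int) -> np.ndarray:
    """Unfold a 3-way tensor along ``mode`` (1-based).

    Row ``i`` of the result is the vectorization of the slice ``t[..., i,
    ...]`` with the lower-numbered remaining axis varying fastest
    (Fortran order over the remaining axes).

    Parameters
    ----------
    t : ndarray, 3-way
    mode : int in {1, 2, 3}

    Returns
    -------
    ndarray of shape ``(t.shape[mode-1], prod(other dims))``
    """
    t = np.asarray(t)
    if t.ndim != 3:
        raise ValueError(f"expected a 3-way tensor, got ndim={t.ndim}")
    _check_mode(mode)
    return np.moveaxis(t, mode - 1, 0).reshape(t.shape[mode - 1], -1, order="F")


def fold(m: np.ndarray, mode: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`matricize` under the same column ordering."""
    m = np.asarray(m)
    _check_mode(mode)
    if len(shape) != 3:
        raise ValueError("shape must be a 3-tuple")
    moved = [shape[mode - 1]] + [s for i, s in enumerate(shape) if i != mode - 1]
    if m.ndim != 2 or m.shape[0] != moved[0] or m.size != int(np.prod(shape)):
        raise ValueError(
            f"matrix of shape {m.shape} cannot fold into {tuple(shape)} along mode {mode}"
        )
    return np.moveaxis(m.reshape(moved, order="F"), 0, mode - 1)


def khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker (Khatri-Rao) product of I x R and J x R matrices.

    Column ``r`` of the result is ``kron(a[:, r], b[:, r])``; the output
    has shape ``(I*J, R)``.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"column counts differ: {a.shape[1]} vs {b.shape[1]}"
        )
    # (I, 1, R) * (1, J, R) -> (I, J, R); a's index is the slow one, matching kron
    return (a[:, None, :] * b[None, :, :]).reshape(-1, a.shape[1])


def _check_rank(*factors: np.ndarray) -> int:
    ranks = {f.shape[1] for f in factors}
    if len(ranks) != 1:
        raise ValueError(f"factor matrices disagree on component count: {sorted(ranks)}")
    return ranks.pop()


def cp_reconstruct(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Rebuild the 3-way tensor ``sum_r w_r a_r (outer) b_r (outer) c_r``.

    ``weights`` defaults to all ones (the unweighted CP model).
    """
    a, b, c = (np.atleast_2d(np.asarray(f, dtype=float)) for f in (a, b, c))
    r = _check_rank(a, b, c)
    if weights is None:
        weights = np.ones(r)
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.size != r:
        raise ValueError(f"weights length {weights.size} != component count {r}")
    return np.einsum("r,ir,jr,kr->ijk", weights, a, b, c)


def matrix_reconstruct(
    a: np.ndarray,
    d: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Rebuild the coupled matrix ``sum_r w_r a_r (outer) d_r``."""
    a, d = (np.atleast_2d(np.asarray(f, dtype=float)) for f in (a, d))
    r = _check_rank(a, d)
    if weights is None:
        weights = np.ones(r)
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.size != r:
        raise ValueError(f"weights length {weights.size} != component count {r}")
    return (a * weights) @ d.T


def tensor_vector_contract(
    t: np.ndarray, a_r: np.ndarray, b_r: np.ndarray, c_r: np.ndarray
) -> float:
    """Contract a 3-way tensor with one vector per mode.

    Returns ``sum_{ijk} t[i,j,k] a_r[i] b_r[j] c_r[k]`` (the full
    tensor-vector product across all three modes).
    """
    t = np.asarray(t, dtype=float)
    a_r, b_r, c_r = (np.asarray(v, dtype=float).ravel() for v in (a_r, b_r, c_r))
    if t.shape != (a_r.size, b_r.size, c_r.size):
        raise ValueError(
            f"vector lengths {(a_r.size, b_r.size, c_r.size)} do not match tensor shape {t.shape}"
        )
    return float(np.einsum("ijk,i,j,k->", t, a_r, b_r, c_r))


def residual_norms(
    x: np.ndarray, xhat: np.ndarray, mask: np.ndarray | None = None
) -> dict[str, float]:
    """Residual error metrics between data ``x`` and reconstruction ``xhat``.

    Returns ``sse`` (sum of squared residuals over unmasked entries),
    ``rmse`` (root mean squared residual per unmasked entry) and
    ``rel_sq`` (sse divided by the squared norm of the unmasked data).

    ``mask`` is a binary array of the same shape; entries with mask 0 are
    excluded from every sum.
    """
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    if mask is None:
        resid = x - xhat
        data = x
        count = x.size
    else:
        mask = np.asarray(mask)
        if mask.shape != x.shape:
            raise ValueError(f"mask shape {mask.shape} != data shape {x.shape}")
        resid = (x - xhat) * mask
        data = x * mask
        count = int(np.count_nonzero(mask))
    sse = float(np.sum(resid**2))
    denom = float(np.sum(data**2))
    if count == 0:
        raise ValueError("mask excludes every entry")
    if denom == 0.0:
        raise ZeroDivisionError("relative error undefined: unmasked data is all zero")
    return {
        "sse": sse,
        "rmse": float(np.sqrt(sse / count)),
        "rel_sq": sse / denom,
    }
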