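"""Basic coupled matrix-tensor factorization fitted by alternating least squares.

The model factorizes a 3-way tensor ``T`` (sample x microbe x pathway)
and a matrix ``M`` (sample x metabolite) that share the sample mode:

    T ~ sum_r a_r o b_r o c_r        M ~ sum_r a_r o d_r

(``o`` denotes the outer product).  Every latent factor is shared by
both blocks through the sample loadings ``a``.  Fitting alternates
closed-form least-squares updates of ``a``, ``b``, ``c``, ``d`` until
the relative change of the reconstruction RMSE drops below a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import CoupledDataset
from .tensor_ops import (
    cp_reconstruct,
    khatri_rao,
    matricize,
    matrix_reconstruct,
)

__all__ = ["FactorModel", "FitConfig", "init_factors", "als_sweep", "fit_basic"]


@dataclass
class FactorModel:
    """Shared-factor CMTF model: factor matrices with ``R`` columns each.

    a : samples x R (shared mode), b : microbes x R, c : pathways x R,
    d : metabolites x R.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    R: int
    rmse_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            f = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if f.shape[1] != self.R:
                raise ValueError(f"factor {name} has {f.shape[1]} columns, expected R={self.R}")
            setattr(self, name, f)

    def reconstruct(self) -> tuple[np.ndarray, np.ndarray]:
        """Return the reconstructed (tensor, matrix) pair."""
        return cp_reconstruct(self.a, self.b, self.c), matrix_reconstruct(self.a, self.d)

    def component_sq_norms(self) -> np.ndarray:
        """Squared norm of each rank-1 component's joint reconstruction.

        For component ``r`` this is |a_r|^2 |b_r|^2 |c_r|^2 (tensor
        block) + |a_r|^2 |d_r|^2 (matrix block); used to order factors
        by contribution.
        """
        na = np.sum(self.a**2, axis=0)
        nb = np.sum(self.b**2, axis=0)
        nc = np.sum(self.c**2, axis=0)
        nd = np.sum(self.d**2, axis=0)
        return na * nb * nc + na * nd


@dataclass
class FitConfig:
    """Settings for the ALS fit.

    tol is the relative-change threshold on the reconstruction RMSE;
    rmse_on selects which block(s) the stopping RMSE is computed over.
    coupled_a_update=False reproduces a legacy normal-matrix form for
    the shared-mode update that ignores the metabolite block's Gram
    term (kept for comparison; the default is the exact coupled
    least-squares solve).
    """

    R: int = 3
    tol: float = 1e-6
    max_iter: int = 500
    seed: int | None = 0
    init: str = "random-normal"
    rmse_on: str = "both"  # both | tensor | matrix
    coupled_a_update: bool = True

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init not in ("random-normal", "random-uniform"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.rmse_on not in ("both", "tensor", "matrix"):
            raise ValueError(f"unknown rmse_on {self.rmse_on!r}")


def init_factors(
    shapes: tuple[int, int, int, int],
    R: int,
    seed: int | None = 0,
    init: str = "random-normal",
) -> FactorModel:
    """Draw random starting factors for the four modes.

    ``shapes`` is (n_samples, n_microbes, n_pathways, n_metabolites).
    Reproducible given ``seed``; entries are standard normal or
    uniform(0, 1) depending on ``init``.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if len(shapes) != 4 or any(s < 1 for s in shapes):
        raise ValueError(f"shapes must be four positive mode sizes, got {shapes!r}")
    rng = np.random.default_rng(seed)
    if init == "random-normal":
        draw = lambda n: rng.standard_normal((n, R))
    elif init == "random-uniform":
        # uniform on (0.1, 1) keeps columns away from zero
        draw = lambda n: rng.uniform(0.1, 1.0, (n, R))
    else:
        raise ValueError(f"unknown init {init!r}")
    a, b, c, d = (draw(n) for n in shapes)
    return FactorModel(a=a, b=b, c=c, d=d, R=R)


def als_sweep(
    data: CoupledDataset, model: FactorModel, coupled_a_update: bool = True
) -> FactorModel:
    """One alternating-least-squares sweep updating a, b, c, d in order.

    Each update is the exact least-squares solution of the corresponding
    linear subproblem, solved through the normal equations with a
    pseudoinverse (rank-deficient Gram matrices are therefore harmless).
    The shared-mode update solves the coupled system over both blocks:

        a = [T(1) (c kr b) + M d] (b'b * c'c + d'd)^+

    where ``kr`` is the Khatri-Rao product and ``*`` the Hadamard
    product.  With ``coupled_a_update=False`` the ``d'd`` term is
    dropped from the normal matrix.
    """
    T, M = data.tensor, data.matrix
    if not (np.all(np.isfinite(T)) and np.all(np.isfinite(M))):
        raise ValueError("non-finite entries in data")
    a, b, c, d = model.a, model.b, model.c, model.d
    t1, t2, t3 = matricize(T, 1), matricize(T, 2), matricize(T, 3)

    gram = lambda x: x.T @ x
    rhs_a = t1 @ khatri_rao(c, b) + M @ d
    normal_a = gram(b) * gram(c)
    if coupled_a_update:
        normal_a = normal_a + gram(d)
    a = rhs_a @ np.linalg.pinv(normal_a)
    b = t2 @ khatri_rao(c, a) @ np.linalg.pinv(gram(a) * gram(c))
    c = t3 @ khatri_rao(b, a) @ np.linalg.pinv(gram(a) * gram(b))
    d = M.T @ np.linalg.pinv(a).T
    return replace(model, a=a, b=b, c=c, d=d)


def _stopping_rmse(data: CoupledDataset, model: FactorModel, rmse_on: str) -> float:
    that, mhat = model.reconstruct()
    sse_t = float(np.sum((data.tensor - that) ** 2))
    sse_m = float(np.sum((data.matrix - mhat) ** 2))
    if rmse_on == "tensor":
        return float(np.sqrt(sse_t / data.tensor.size))
    if rmse_on == "matrix":
        return float(np.sqrt(sse_m / data.matrix.size))
    return float(np.sqrt((sse_t + sse_m) / (data.tensor.size + data.matrix.size)))


def _standardize(model: FactorModel) -> FactorModel:
    """Order components by joint contribution and fix signs for reporting.

    Components are sorted by descending squared reconstruction norm;
    each component's sample column is sign-flipped so its
    largest-magnitude loading is positive (compensated in b and d so the
    reconstruction is unchanged).
    """
    order = np.argsort(model.component_sq_norms())[::-1]
    a, b, c, d = (f[:, order].copy() for f in (model.a, model.b, model.c, model.d))
    for r in range(model.R):
        col = a[:, r]
        if col[np.argmax(np.abs(col))] < 0:
            a[:, r] *= -1.0
            b[:, r] *= -1.0
            d[:, r] *= -1.0
    return replace(model, a=a, b=b, c=c, d=d)


def fit_basic(data: CoupledDataset, cfg: FitConfig) -> FactorModel:
    """Fit the basic CMTF by ALS.

    Iterates :func:`als_sweep` until the relative change of the
    reconstruction RMSE falls below ``cfg.tol`` or ``cfg.max_iter``
    sweeps have run; records the RMSE trace.  Deterministic for a fixed
    seed.  A zero previous RMSE (exact fit) counts as converged.
    """
    model = init_factors(data.dims, cfg.R, seed=cfg.seed, init=cfg.init)
    trace: list[float] = []
    prev = None
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        model = als_sweep(data, model, coupled_a_update=cfg.coupled_a_update)
        rmse = _stopping_rmse(data, model, cfg.rmse_on)
        trace.append(rmse)
        if prev is not None:
            if prev == 0.0 or abs(rmse - prev) / prev <= cfg.tol:
                converged = True
                break
        prev = rmse
    model = _standardize(model)
    return replace(model, rmse_trace=trace, converged=converged, n_iter=n_iter)
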