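"""Weighted coupled matrix-tensor factorization fitted by quasi-Newton descent.

Unlike the basic shared-factor model, each latent factor here carries a
separate weight per data block:

    T ~ sum_r lambda_r a_r o b_r o c_r        M ~ sum_r sigma_r a_r o v_r

so a factor can drive the tensor (microbiome) block, the matrix
(metabolome) block, or both.  The objective combines the two squared
reconstruction errors with a smoothed-L1 penalty on the weights (which
shrinks block-specific weights toward zero, exposing unshared factors)
and a column-centering penalty on the factor matrices:

    f = |T - That|^2 + |M - Mhat|^2
        + beta * sum_r sqrt(lambda_r^2 + eps) + beta * sum_r sqrt(sigma_r^2 + eps)
        + (alpha/2) * sum_{columns x of a,b,c,v} |x - mean(x)|^2

The smoothing constant ``eps`` makes the L1 terms differentiable at
zero; the centering penalty regularizes the scale/offset indeterminacy
of the factors.  All parameters are flattened into one vector and
minimized with a BFGS-family solver using the analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .datasets import CoupledDataset
from .tensor_ops import cp_reconstruct, khatri_rao, matricize, matrix_reconstruct

__all__ = [
    "WeightedFactorModel",
    "AdvancedConfig",
    "advanced_objective",
    "advanced_gradient",
    "fit_advanced",
    "block_weight_shares",
    "normalize_components",
]


@dataclass
class WeightedFactorModel:
    """Factor matrices plus per-component block weights.

    ``v`` is the metabolite factor matrix (the matrix-block analogue of
    ``d`` in the basic model); ``lam`` weights the tensor block and
    ``sig`` the matrix block, one entry per latent factor.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    v: np.ndarray
    lam: np.ndarray
    sig: np.ndarray
    R: int
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "v"):
            f = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if f.shape[1] != self.R:
                raise ValueError(f"factor {name} has {f.shape[1]} columns, expected R={self.R}")
            setattr(self, name, f)
        for name in ("lam", "sig"):
            w = np.asarray(getattr(self, name), dtype=float).ravel()
            if w.size != self.R:
                raise ValueError(f"weight vector {name} has length {w.size}, expected R={self.R}")
            if not np.all(np.isfinite(w)):
                raise ValueError(f"non-finite entries in {name}")
            setattr(self, name, w)

    def reconstruct(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            cp_reconstruct(self.a, self.b, self.c, weights=self.lam),
            matrix_reconstruct(self.a, self.v, weights=self.sig),
        )


@dataclass
class AdvancedConfig:
    """Penalty and solver settings for the weighted fit.

    alpha scales the factor-column centering penalty, beta the
    smoothed-L1 weight penalty, eps the L1 smoothing constant.  The
    solver is any quasi-Newton method accepted by
    ``scipy.optimize.minimize``; ``n_starts`` seeded restarts are run
    and the best objective kept.
    """

    R: int = 3
    alpha: float = 1.0
    beta: float = 1.0
    eps: float = 1e-8
    solver: str = "L-BFGS-B"
    gtol: float = 1e-6
    max_iter: int = 500
    seed: int | None = 0
    n_starts: int = 3
    # "als" seeds the first start from a short coupled-ALS fit (the
    # standard initialization for gradient-based CMTF solvers; the
    # remaining starts stay random); "random" uses random starts only
    init: str = "random"
    # stop launching restarts once a start explains the data this well
    # (best objective / squared data norm); the remaining starts cannot
    # improve meaningfully on a near-exact fit
    early_stop_rel: float = 1e-8

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.init not in ("random", "als"):
            raise ValueError(f"unknown init {self.init!r}")


def _center_penalty(x: np.ndarray) -> float:
    centered = x - x.mean(axis=0, keepdims=True)
    return float(np.sum(centered**2))


def advanced_objective(
    data: CoupledDataset, model: WeightedFactorModel, cfg: AdvancedConfig
) -> float:
    """Evaluate the penalized weighted-CMTF objective."""
    that, mhat = model.reconstruct()
    sse = float(np.sum((data.tensor - that) ** 2)) + float(np.sum((data.matrix - mhat) ** 2))
    l1 = float(np.sum(np.sqrt(model.lam**2 + cfg.eps)) + np.sum(np.sqrt(model.sig**2 + cfg.eps)))
    center = sum(_center_penalty(f) for f in (model.a, model.b, model.c, model.v))
    return sse + cfg.beta * l1 + (cfg.alpha / 2.0) * center


def _precompute_unfoldings(data: CoupledDataset) -> dict[str, np.ndarray]:
    """Mode-n unfoldings of the data tensor, computed once per fit."""
    return {
        "t1": matricize(data.tensor, 1),
        "t2": matricize(data.tensor, 2),
        "t3": matricize(data.tensor, 3),
        "m": data.matrix,
    }


def _value_and_grad(
    pre: dict[str, np.ndarray], model: WeightedFactorModel, cfg: AdvancedConfig
) -> tuple[float, dict[str, np.ndarray]]:
    """Objective and its analytic gradient, sharing one residual pass.

    Works in matricized form throughout: the mode-n unfolding of the
    weighted CP reconstruction is (X_n * lam) kr(...)' for factor X_n of
    mode n, so residual unfoldings come from three small matrix products
    instead of building the dense tensor.
    """
    a, b, c, v = model.a, model.b, model.c, model.v
    lam, sig = model.lam, model.sig

    kr_cb = khatri_rao(c, b)
    kr_ca = khatri_rao(c, a)
    kr_ba = khatri_rao(b, a)
    e1 = (a * lam) @ kr_cb.T - pre["t1"]
    e2 = (b * lam) @ kr_ca.T - pre["t2"]
    e3 = (c * lam) @ kr_ba.T - pre["t3"]
    em = (a * sig) @ v.T - pre["m"]

    sse = float(np.sum(e1**2) + np.sum(em**2))
    l1 = float(np.sum(np.sqrt(lam**2 + cfg.eps)) + np.sum(np.sqrt(sig**2 + cfg.eps)))
    cen = lambda x: x - x.mean(axis=0, keepdims=True)
    center = sum(float(np.sum(cen(f) ** 2)) for f in (a, b, c, v))
    f = sse + cfg.beta * l1 + (cfg.alpha / 2.0) * center

    p_t = e1 @ kr_cb  # <E(1), kr basis>: shared by the a and lambda gradients
    p_m = em @ v
    g_a = 2.0 * p_t * lam + 2.0 * p_m * sig + cfg.alpha * cen(a)
    g_b = 2.0 * (e2 @ kr_ca) * lam + cfg.alpha * cen(b)
    g_c = 2.0 * (e3 @ kr_ba) * lam + cfg.alpha * cen(c)
    g_v = 2.0 * (em.T @ a) * sig + cfg.alpha * cen(v)
    g_lam = 2.0 * np.einsum("ir,ir->r", p_t, a) + cfg.beta * lam / np.sqrt(lam**2 + cfg.eps)
    g_sig = 2.0 * np.einsum("ir,ir->r", p_m, a) + cfg.beta * sig / np.sqrt(sig**2 + cfg.eps)
    return f, {"a": g_a, "b": g_b, "c": g_c, "v": g_v, "lam": g_lam, "sig": g_sig}


def advanced_gradient(
    data: CoupledDataset, model: WeightedFactorModel, cfg: AdvancedConfig
) -> dict[str, np.ndarray]:
    """Analytic gradient of :func:`advanced_objective`.

    Returns gradients keyed ``a, b, c, v, lam, sig``.  The residual
    terms follow the standard CP/Khatri-Rao identities; the centering
    penalty differentiates to ``alpha * (x - column mean)`` because the
    centering projector is idempotent; the smoothed L1 differentiates
    to ``beta * w / sqrt(w^2 + eps)``.
    """
    return _value_and_grad(_precompute_unfoldings(data), model, cfg)[1]


def _pack(model: WeightedFactorModel) -> np.ndarray:
    return np.concatenate(
        [f.ravel() for f in (model.a, model.b, model.c, model.v)] + [model.lam, model.sig]
    )


def _unpack(x: np.ndarray, dims: tuple[int, int, int, int], R: int) -> WeightedFactorModel:
    ns, nb, nc, nv = dims
    sizes = [ns * R, nb * R, nc * R, nv * R, R, R]
    parts = np.split(x, np.cumsum(sizes)[:-1])
    return WeightedFactorModel(
        a=parts[0].reshape(ns, R),
        b=parts[1].reshape(nb, R),
        c=parts[2].reshape(nc, R),
        v=parts[3].reshape(nv, R),
        lam=parts[4],
        sig=parts[5],
        R=R,
    )


def fit_advanced(data: CoupledDataset, cfg: AdvancedConfig) -> WeightedFactorModel:
    """Minimize the weighted objective over all factors and weights jointly.

    Runs ``cfg.n_starts`` seeded random restarts of the quasi-Newton
    solver and keeps the best objective.  On solver failure the
    best-so-far model is returned with ``converged=False``.
    """
    dims = data.dims
    R = cfg.R

    last_f = [np.inf]
    pre = _precompute_unfoldings(data)

    def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
        m = _unpack(x, dims, R)
        f, g = _value_and_grad(pre, m, cfg)
        grad = np.concatenate(
            [g[k].ravel() for k in ("a", "b", "c", "v")] + [g["lam"], g["sig"]]
        )
        last_f[0] = f
        return f, grad

    if cfg.solver.upper() == "BFGS":
        options = {"maxiter": cfg.max_iter, "gtol": cfg.gtol}
    elif cfg.solver.upper() == "L-BFGS-B":
        options = {"maxiter": cfg.max_iter, "gtol": cfg.gtol, "ftol": 1e-14, "maxcor": 20}
    else:
        options = {"maxiter": cfg.max_iter}

    master = np.random.default_rng(cfg.seed)
    data_sq = float(np.sum(data.tensor**2) + np.sum(data.matrix**2))
    best: WeightedFactorModel | None = None
    best_obj = np.inf
    for start in range(cfg.n_starts):
        if best_obj <= cfg.early_stop_rel * max(data_sq, 1.0):
            break
        sub = np.random.default_rng(master.integers(2**31 - 1))
        if cfg.init == "als" and start == 0:
            x0 = _pack(_als_start(data, R, seed=cfg.seed))
        else:
            x0 = np.concatenate(
                [sub.standard_normal(n * R) for n in dims] + [np.ones(R), np.ones(R)]
            )
        trace: list[float] = []
        res = minimize(
            fun,
            x0,
            jac=True,
            method=cfg.solver,
            options=options,
            callback=lambda xk: trace.append(last_f[0]),
        )
        if res.fun < best_obj:
            best_obj = float(res.fun)
            best = replace(
                _unpack(res.x, dims, R),
                objective_trace=trace,
                converged=bool(res.success),
                n_iter=int(res.nit),
            )
    assert best is not None
    return best


def _als_start(data: CoupledDataset, R: int, seed: int | None) -> WeightedFactorModel:
    """Build a starting point from a short coupled-ALS fit.

    The ALS factors are carried over with unit block weights; the
    optimizer then refines factors and weights against the penalized
    objective.
    """
    from .basic_cmtf import FitConfig, fit_basic

    fm = fit_basic(data, FitConfig(R=R, seed=seed, tol=1e-9, max_iter=300))
    return WeightedFactorModel(
        a=fm.a, b=fm.b, c=fm.c, v=fm.d, lam=np.ones(R), sig=np.ones(R), R=R
    )


def block_weight_shares(model: WeightedFactorModel) -> dict[str, np.ndarray]:
    """Per-factor share of total absolute weight held by each block.

    share(tensor, r) = |lambda_r| / (sum|lambda| + sum|sigma|) and
    likewise for sigma; all 2R shares sum to 1.
    """
    total = float(np.sum(np.abs(model.lam)) + np.sum(np.abs(model.sig)))
    if total == 0.0:
        raise ValueError("all component weights are zero")
    return {
        "tensor": np.abs(model.lam) / total,
        "matrix": np.abs(model.sig) / total,
    }


def normalize_components(model: WeightedFactorModel) -> WeightedFactorModel:
    """Rescale factor columns to unit norm, folding scales into the weights.

    Resolves the scale indeterminacy of the weighted CP model:
    after normalization ``lam_r`` carries |a_r||b_r||c_r| times the old
    weight and ``sig_r`` carries |a_r||v_r| times the old weight, so
    weight vectors of two fits become directly comparable.
    """
    norms = {
        name: np.linalg.norm(getattr(model, name), axis=0)
        for name in ("a", "b", "c", "v")
    }
    for name, n in norms.items():
        if np.any(n == 0):
            raise ValueError(f"factor {name} has a zero column; cannot normalize")
    return replace(
        model,
        a=model.a / norms["a"],
        b=model.b / norms["b"],
        c=model.c / norms["c"],
        v=model.v / norms["v"],
        lam=model.lam * norms["a"] * norms["b"] * norms["c"],
        sig=model.sig * norms["a"] * norms["v"],
    )
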