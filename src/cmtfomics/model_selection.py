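"""Masked-entry cross-validation for choosing the number of latent factors.

Entries of the coupled tensor/matrix pair are randomly split into
training and test sets through binary masks; held-out entries are
zeroed before fitting (the missing-as-zero scheme — see the caveat on
``fit_masked``) and errors on both sets are reported as a size-weighted
relative squared error:

    error = W_t * |mask_t * (T - That)|^2 / |mask_t * T|^2
          + W_m * |mask_m * (M - Mhat)|^2 / |mask_m * M|^2

with W_t = size(T) / (size(T) + size(M)) and W_m = 1 - W_t.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .basic_cmtf import FactorModel, FitConfig, als_sweep, fit_basic, init_factors
from .datasets import CoupledDataset

__all__ = ["MaskPair", "CVResult", "make_mask_pair", "masked_error", "fit_masked", "cross_validate"]


@dataclass
class MaskPair:
    """Binary inclusion masks (1 = training entry) for the two blocks."""

    omega_t: np.ndarray
    omega_m: np.ndarray
    holdout_fraction: float
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("omega_t", "omega_m"):
            m = np.asarray(getattr(self, name))
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{name} must be binary")
            setattr(self, name, m.astype(float))

    def block_weights(self) -> tuple[float, float]:
        """(W_t, W_m): each block's share of the total entry count."""
        nt, nm = self.omega_t.size, self.omega_m.size
        return nt / (nt + nm), nm / (nt + nm)


@dataclass
class CVResult:
    """Cross-validation table plus the block weights used."""

    table: pd.DataFrame  # columns: R, train_error, test_error, seed, fraction
    W_t: float
    W_m: float


def make_mask_pair(
    shapes: tuple[tuple[int, int, int], tuple[int, int]],
    fraction: float = 0.2,
    seed: int | None = 0,
) -> MaskPair:
    """Assign each entry independently to the test set with the given probability."""
    if not 0 < fraction < 1:
        raise ValueError("holdout fraction must lie in (0, 1)")
    t_shape, m_shape = shapes
    rng = np.random.default_rng(seed)
    omega_t = (rng.random(t_shape) >= fraction).astype(float)
    omega_m = (rng.random(m_shape) >= fraction).astype(float)
    return MaskPair(omega_t=omega_t, omega_m=omega_m, holdout_fraction=fraction, seed=seed)


def masked_error(
    data: CoupledDataset,
    model: FactorModel,
    mask: MaskPair,
    which: str = "train",
) -> float:
    """Size-weighted relative squared error over masked entries.

    ``which='train'`` uses the inclusion masks, ``'test'`` their
    complements.  Despite sometimes being called an "rmse" in the CV
    context this is a ratio of squared norms (no square root).
    """
    if which not in ("train", "test"):
        raise ValueError("which must be 'train' or 'test'")
    that, mhat = model.reconstruct()
    w_t, w_m = mask.block_weights()
    om_t = mask.omega_t if which == "train" else 1.0 - mask.omega_t
    om_m = mask.omega_m if which == "train" else 1.0 - mask.omega_m
    denom_t = float(np.sum((om_t * data.tensor) ** 2))
    denom_m = float(np.sum((om_m * data.matrix) ** 2))
    if denom_t == 0.0 or denom_m == 0.0:
        raise ZeroDivisionError(f"{which} entries of a block are all zero")
    err_t = float(np.sum((om_t * (data.tensor - that)) ** 2)) / denom_t
    err_m = float(np.sum((om_m * (data.matrix - mhat)) ** 2)) / denom_m
    return w_t * err_t + w_m * err_m


def _zero_masked(data: CoupledDataset, mask: MaskPair) -> CoupledDataset:
    return replace(
        data,
        tensor=data.tensor * mask.omega_t,
        matrix=data.matrix * mask.omega_m,
    )


def fit_masked(data: CoupledDataset, mask: MaskPair, cfg: FitConfig) -> FactorModel:
    """Fit the basic model with held-out entries replaced by zero.

    Zeroing conflates "missing" with "true zero": the factorization
    sees the held-out positions as zeros rather than ignoring them.
    This keeps the fit a plain ALS.  (An EM flavor that iteratively
    imputes held-out entries with the current reconstruction is
    available via :func:`cross_validate`'s ``em_impute`` flag.)
    """
    return fit_basic(_zero_masked(data, mask), cfg)


def _fit_em(data: CoupledDataset, mask: MaskPair, cfg: FitConfig, n_outer: int = 10) -> FactorModel:
    """EM-style fit: alternate imputing held-out entries and refitting."""
    work = _zero_masked(data, mask)
    model = fit_basic(work, cfg)
    for _ in range(n_outer):
        that, mhat = model.reconstruct()
        work = replace(
            work,
            tensor=data.tensor * mask.omega_t + that * (1 - mask.omega_t),
            matrix=data.matrix * mask.omega_m + mhat * (1 - mask.omega_m),
        )
        model = fit_basic(work, cfg)
    return model


def cross_validate(
    data: CoupledDataset,
    R_grid: list[int],
    fraction: float = 0.2,
    seed: int | None = 0,
    cfg: FitConfig | None = None,
    em_impute: bool = False,
    warm_start: bool = True,
) -> CVResult:
    """Train/test error per candidate component count.

    One mask pair is drawn per R (all from ``seed``); the basic model is
    fitted on the training entries and both errors recorded.  With
    ``warm_start`` the fit for each R after the first starts from the
    previous R's factors plus one small random column, which makes the
    training error effectively non-increasing in R (each larger model
    starts at least as good as the smaller one).
    """
    if not R_grid:
        raise ValueError("R grid is empty")
    base = cfg or FitConfig()
    rows = []
    w_t = w_m = None
    prev: FactorModel | None = None
    rng = np.random.default_rng(seed)
    for R in R_grid:
        mask = make_mask_pair(data.shapes, fraction, seed=seed)
        run_cfg = replace(base, R=R)
        if em_impute:
            model = _fit_em(data, mask, run_cfg)
        elif warm_start and prev is not None and R > prev.R:
            model = _fit_warm(data, mask, run_cfg, prev, rng)
        else:
            model = fit_masked(data, mask, run_cfg)
        rows.append(
            {
                "R": R,
                "train_error": masked_error(data, model, mask, "train"),
                "test_error": masked_error(data, model, mask, "test"),
                "seed": seed,
                "fraction": fraction,
            }
        )
        prev = model
        w_t, w_m = mask.block_weights()
    return CVResult(table=pd.DataFrame(rows), W_t=w_t, W_m=w_m)


def _grow_factors(model: FactorModel, n_new: int, rng: np.random.Generator) -> FactorModel:
    """Append small random columns so a rank-R model seeds a rank-R' fit."""
    scale = 1e-3
    new = {}
    for name in ("a", "b", "c", "d"):
        f = getattr(model, name)
        extra = scale * rng.standard_normal((f.shape[0], n_new))
        new[name] = np.hstack([f, extra])
    return FactorModel(R=model.R + n_new, **new)


def _fit_warm(
    data: CoupledDataset,
    mask: MaskPair,
    cfg: FitConfig,
    prev: FactorModel,
    rng: np.random.Generator,
) -> FactorModel:
    from .basic_cmtf import _standardize, _stopping_rmse

    work = _zero_masked(data, mask)
    model = _grow_factors(prev, cfg.R - prev.R, rng)
    trace: list[float] = []
    prev_rmse = None
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        model = als_sweep(work, model, coupled_a_update=cfg.coupled_a_update)
        rmse = _stopping_rmse(work, model, cfg.rmse_on)
        trace.append(rmse)
        if prev_rmse is not None:
            if prev_rmse == 0.0 or abs(rmse - prev_rmse) / prev_rmse <= cfg.tol:
                converged = True
                break
        prev_rmse = rmse
    model = _standardize(model)
    return replace(model, rmse_trace=trace, converged=converged, n_iter=n_iter)
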