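"""Synthetic coupled tensor/matrix data with known ground truth.

Two study designs are generated:

* a pure-noise design where every entry of the tensor and matrix is
  drawn i.i.d. from N(1, 1) — there is no latent structure, so any
  apparent factor is an overfitting artifact; used to probe
  cross-validation behaviour; and
* a weighted low-rank design built from known factor matrices with
  entries ~ N(1, 1) and per-component block weights (defaults
  lambda = [1, 0.5, 1] for the tensor, sigma = [1, 1, 0.5] for the
  matrix), so the two blocks do not share all components uniformly;
  used for parameter-recovery and basic-vs-advanced comparisons.

Default dimensions are 40 samples x 50 microbes x 30 pathways with 20
metabolites for both designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import CoupledDataset
from .tensor_ops import cp_reconstruct, matrix_reconstruct

__all__ = [
    "SyntheticTruth",
    "simulate_noise_dataset",
    "simulate_weighted_dataset",
    "simulate_equal_weights_dataset",
    "DEFAULT_DIMS",
]

DEFAULT_DIMS = (40, 50, 30, 20)


@dataclass
class SyntheticTruth:
    """Ground-truth factors and weights behind a simulated dataset."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    lam: np.ndarray
    sig: np.ndarray
    noise_sd: float
    seed: int | None
    dims: tuple[int, int, int, int]


def _labelled(tensor: np.ndarray, matrix: np.ndarray) -> CoupledDataset:
    ns, nb, nc = tensor.shape
    nv = matrix.shape[1]
    return CoupledDataset(
        tensor=tensor,
        matrix=matrix,
        sample_ids=[f"S{i:03d}" for i in range(ns)],
        microbe_ids=[f"microbe_{j:03d}" for j in range(nb)],
        pathway_ids=[f"PWY-{k:03d}" for k in range(nc)],
        metabolite_ids=[f"metab_{v:03d}" for v in range(nv)],
    )


def simulate_noise_dataset(
    dims: tuple[int, int, int, int] = DEFAULT_DIMS, seed: int | None = 0
) -> CoupledDataset:
    """Structure-free coupled data: every entry i.i.d. N(1, 1)."""
    if any(d < 1 for d in dims):
        raise ValueError("all dims must be positive")
    ns, nb, nc, nv = dims
    rng = np.random.default_rng(seed)
    tensor = rng.normal(1.0, 1.0, (ns, nb, nc))
    matrix = rng.normal(1.0, 1.0, (ns, nv))
    return _labelled(tensor, matrix)


def simulate_weighted_dataset(
    dims: tuple[int, int, int, int] = DEFAULT_DIMS,
    R: int = 3,
    lam: np.ndarray | list[float] = (1.0, 0.5, 1.0),
    sig: np.ndarray | list[float] = (1.0, 1.0, 0.5),
    factor_mean: float = 1.0,
    factor_sd: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> tuple[CoupledDataset, SyntheticTruth]:
    """Low-rank coupled data with distinct per-block component weights.

    T = sum_r lam_r a_r o b_r o c_r (+ noise), M = sum_r sig_r a_r o d_r
    (+ noise), with factor entries i.i.d. N(factor_mean, factor_sd^2).
    """
    lam = np.asarray(lam, dtype=float).ravel()
    sig = np.asarray(sig, dtype=float).ravel()
    if lam.size != R or sig.size != R:
        raise ValueError(f"weights must have length R={R}")
    ns, nb, nc, nv = dims
    rng = np.random.default_rng(seed)
    a, b, c, d = (rng.normal(factor_mean, factor_sd, (n, R)) for n in dims)
    tensor = cp_reconstruct(a, b, c, weights=lam)
    matrix = matrix_reconstruct(a, d, weights=sig)
    if noise_sd > 0:
        tensor = tensor + rng.normal(0.0, noise_sd, tensor.shape)
        matrix = matrix + rng.normal(0.0, noise_sd, matrix.shape)
    truth = SyntheticTruth(
        a=a, b=b, c=c, d=d, lam=lam, sig=sig, noise_sd=noise_sd, seed=seed, dims=tuple(dims)
    )
    return _labelled(tensor, matrix), truth


def simulate_equal_weights_dataset(
    dims: tuple[int, int, int, int] = DEFAULT_DIMS,
    R: int = 3,
    weights: np.ndarray | list[float] = (1.0, 0.5, 1.0),
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> tuple[CoupledDataset, SyntheticTruth]:
    """Weighted design with identical tensor and matrix weights (lam = sig)."""
    return simulate_weighted_dataset(
        dims=dims, R=R, lam=weights, sig=weights, noise_sd=noise_sd, seed=seed
    )
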