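"""Matching recovered latent components against reference components.

CP-type factorizations are identified only up to permutation and
per-component scaling, so recovered factors must be aligned with a
reference before comparison.  Components are matched by the factor
congruence coefficient (the product over modes of the cosine similarity
between corresponding columns), assigned one-to-one by the Hungarian
algorithm on -|congruence|.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["congruence_matrix", "match_components"]


def _unit_cols(m: np.ndarray) -> np.ndarray:
    m = np.atleast_2d(np.asarray(m, dtype=float))
    norms = np.linalg.norm(m, axis=0)
    norms[norms == 0] = 1.0
    return m / norms


def congruence_matrix(est: list[np.ndarray], ref: list[np.ndarray]) -> np.ndarray:
    """Pairwise congruence between estimated and reference components.

    ``est`` and ``ref`` are lists of factor matrices over the same modes
    (e.g. ``[a, b, c]``); entry (r, s) is the product over modes of the
    cosine between estimated column r and reference column s.
    """
    if len(est) != len(ref):
        raise ValueError("est and ref must cover the same modes")
    out = None
    for e, r in zip(est, ref):
        cos = _unit_cols(e).T @ _unit_cols(r)
        out = cos if out is None else out * cos
    return out


def match_components(
    est: list[np.ndarray], ref: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """One-to-one component assignment maximizing total |congruence|.

    Returns (permutation, congruences): ``permutation[s]`` is the index
    of the estimated component matched to reference component ``s``, and
    ``congruences[s]`` the signed congruence of that pair.
    """
    cong = congruence_matrix(est, ref)
    rows, cols = linear_sum_assignment(-np.abs(cong))
    perm = np.empty(cong.shape[1], dtype=int)
    matched = np.empty(cong.shape[1])
    for r, s in zip(rows, cols):
        perm[s] = r
        matched[s] = cong[r, s]
    return perm, matched
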