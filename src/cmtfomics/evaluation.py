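"""Group-separation statistics and biomarker ranking in latent-factor space.

After factorization, samples live in an R-dimensional latent space (the
rows of the sample factor matrix).  Separation between two groups is
quantified on the two highest-variance factors with the squared
Mahalanobis distance between group centroids under the pooled
within-group covariance; its scaled form is the two-sample Hotelling
T^2 statistic, which follows an F distribution under multivariate
normality.  Features (microbes, pathways, metabolites) are ranked as
biomarker candidates by the absolute loading on a chosen factor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .advanced_cmtf import WeightedFactorModel
from .basic_cmtf import FactorModel

__all__ = [
    "SeparationResult",
    "BiomarkerRanking",
    "explained_variance",
    "project_top2",
    "mahalanobis_separation",
    "top_loadings",
    "top_k_hit_ratio",
    "hit_ratio_curve",
]

log = logging.getLogger(__name__)


@dataclass
class SeparationResult:
    """Two-group separation test in a 2D latent projection.

    D2 is the squared Mahalanobis distance between centroids, f the
    derived F statistic with (df1, df2) degrees of freedom, p its
    upper-tail probability; s1 and s2 are the group sizes.
    """

    D2: float
    f: float
    df1: int
    df2: int
    p: float
    s1: int
    s2: int


@dataclass
class BiomarkerRanking:
    """Features of one mode ordered by |loading| on one latent factor."""

    table: pd.DataFrame  # columns: feature, loading, abs_rank, sign
    mode: str
    factor: int
    k: int


def _component_norms(model: FactorModel | WeightedFactorModel) -> np.ndarray:
    if isinstance(model, WeightedFactorModel):
        na = np.sum(model.a**2, axis=0)
        nb = np.sum(model.b**2, axis=0)
        nc = np.sum(model.c**2, axis=0)
        nv = np.sum(model.v**2, axis=0)
        return model.lam**2 * na * nb * nc + model.sig**2 * na * nv
    return model.component_sq_norms()


def explained_variance(model: FactorModel | WeightedFactorModel) -> np.ndarray:
    """Share of the total reconstruction norm carried by each component.

    share_r = squared norm of component r's joint (tensor + matrix)
    reconstruction / sum over components.  Shares sum to 1; when
    components are mutually orthogonal they coincide with the fractions
    of the full reconstruction's squared norm.
    """
    norms = _component_norms(model)
    total = float(norms.sum())
    if total == 0.0:
        raise ValueError("model reconstructs to zero; explained variance undefined")
    return norms / total


def project_top2(model: FactorModel | WeightedFactorModel) -> np.ndarray:
    """Sample scores on the two highest-variance factors, in variance order."""
    if model.R < 2:
        raise ValueError("need at least two latent factors to project")
    order = np.argsort(explained_variance(model))[::-1][:2]
    return model.a[:, order]


def mahalanobis_separation(scores: np.ndarray, groups: np.ndarray) -> SeparationResult:
    """Two-sample Hotelling-type test for centroid separation.

    D^2 = (ybar - xbar)' S_pooled^-1 (ybar - xbar) with the pooled
    within-group covariance S_pooled = ((s1-1)S1 + (s2-1)S2)/(s1+s2-2);

    f = [(s1+s2-n-1) / (n (s1+s2-2))] * [s1 s2 / (s1+s2)] * D^2

    follows F(n, s1+s2-n-1) under the null of equal means, with n the
    projection dimensionality (2 here).
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {list(levels)}")
    x = scores[groups == levels[0]]
    y = scores[groups == levels[1]]
    s1, s2 = len(x), len(y)
    if min(s1, s2) < 3:
        raise ValueError("each group needs at least 3 samples")
    n = scores.shape[1]
    S1 = np.cov(x, rowvar=False)
    S2 = np.cov(y, rowvar=False)
    pooled = ((s1 - 1) * S1 + (s2 - 1) * S2) / (s1 + s2 - 2)
    diff = y.mean(axis=0) - x.mean(axis=0)
    try:
        sol = np.linalg.solve(pooled, diff)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; consider jittering the scores or "
            "inspecting degenerate factors"
        ) from exc
    d2 = float(diff @ sol)
    df1 = n
    df2 = s1 + s2 - n - 1
    f = (df2 / (n * (s1 + s2 - 2))) * (s1 * s2 / (s1 + s2)) * d2
    p = float(stats.f.sf(f, df1, df2))
    return SeparationResult(D2=d2, f=f, df1=df1, df2=df2, p=p, s1=s1, s2=s2)


_MODE_ATTR = {"microbe": "b", "pathway": "c", "metabolite": ("d", "v")}


def top_loadings(
    model: FactorModel | WeightedFactorModel,
    mode: str,
    factor: int,
    k: int,
    feature_ids: list[str] | None = None,
) -> BiomarkerRanking:
    """Rank the ``k`` features with largest |loading| on one factor.

    ``mode`` is one of microbe / pathway / metabolite; ``factor`` is a
    0-based component index.  Signs are preserved (negative loadings
    mean negative association with the factor).  Ties in |loading| are
    broken by feature id.
    """
    if mode not in _MODE_ATTR:
        raise ValueError(f"mode must be one of {sorted(_MODE_ATTR)}, got {mode!r}")
    attr = _MODE_ATTR[mode]
    if isinstance(attr, tuple):
        attr = attr[1] if isinstance(model, WeightedFactorModel) else attr[0]
    mat = getattr(model, attr)
    if not 0 <= factor < model.R:
        raise ValueError(f"factor index {factor} out of range for R={model.R}")
    loadings = mat[:, factor]
    ids = feature_ids if feature_ids is not None else [f"{mode}_{i}" for i in range(len(loadings))]
    if len(ids) != len(loadings):
        raise ValueError("feature_ids length does not match the factor matrix")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(loadings):
        warnings.warn(
            f"k={k} exceeds the {len(loadings)} available features; truncating", stacklevel=2
        )
        k = len(loadings)
    df = pd.DataFrame({"feature": ids, "loading": loadings})
    df["abs_loading"] = df["loading"].abs()
    df = df.sort_values(["abs_loading", "feature"], ascending=[False, True], kind="mergesort")
    df = df.head(k).reset_index(drop=True)
    df["abs_rank"] = np.arange(1, len(df) + 1)
    df["sign"] = np.sign(df["loading"]).astype(int)
    return BiomarkerRanking(
        table=df[["feature", "loading", "abs_rank", "sign"]], mode=mode, factor=factor, k=k
    )


def top_k_hit_ratio(ranking: BiomarkerRanking, validated: set[str], k: int) -> float:
    """Fraction of the top-k ranked features that belong to the validated set."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranking.table):
        raise ValueError(f"k={k} exceeds the ranking length {len(ranking.table)}")
    if not validated:
        warnings.warn("validated set is empty; hit ratio is 0", stacklevel=2)
        return 0.0
    top = ranking.table["feature"].head(k)
    return float(top.isin(validated).sum()) / k


def hit_ratio_curve(
    ranking: BiomarkerRanking, validated: set[str], k_max: int | None = None
) -> pd.DataFrame:
    """Hit ratio for every k up to ``k_max`` (defaults to the ranking length)."""
    k_max = k_max or len(ranking.table)
    ks = np.arange(1, k_max + 1)
    hits = ranking.table["feature"].head(k_max).isin(validated).to_numpy()
    return pd.DataFrame({"k": ks, "hit_ratio": np.cumsum(hits) / ks})
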