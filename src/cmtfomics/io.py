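"""Readers and writers for the tab-separated formats the toolkit consumes.

Inputs are the stratified pathway-abundance dialect produced by
metagenomic functional profilers (rows ``pathway|taxon``, columns
samples), generic feature tables (features x samples), and a sample
metadata table (sample, subject, group).  Outputs are one TSV of
loadings per mode, a weights TSV for weighted models, and a JSON run
summary that captures the configuration and seed of a run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .advanced_cmtf import WeightedFactorModel, block_weight_shares
from .basic_cmtf import FactorModel
from .datasets import StratifiedProfile

__all__ = [
    "read_stratified_pathabundance",
    "read_feature_table",
    "read_metadata",
    "write_model",
    "read_factor_table",
]

log = logging.getLogger(__name__)

_EXCLUDE_PREFIXES = ("UNMAPPED", "UNINTEGRATED")
FLOAT_FMT = "%.10g"


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an id column plus at least one sample column")
    # pandas pads ragged short rows with NaN; reject them explicitly
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # +2: header and 1-based
        raise ValueError(f"{path}: ragged or empty cell near line {bad}")
    return df


def read_stratified_pathabundance(
    path: str | Path, drop_unintegrated: bool = True
) -> StratifiedProfile:
    """Parse a stratified pathway-abundance TSV into long-format records.

    Only stratified rows (feature ids containing ``|``) are kept; the id
    is split into pathway and taxon at the first ``|``.  Rows whose
    pathway is UNMAPPED or UNINTEGRATED are dropped by default.
    """
    df = _read_tsv(path)
    id_col = df.columns[0]
    samples = list(df.columns[1:])
    stratified = df[df[id_col].str.contains(r"\|", regex=True)]
    n_unstrat = len(df) - len(stratified)
    if n_unstrat:
        log.info("%s: skipped %d unstratified rows", path, n_unstrat)
    if drop_unintegrated:
        keep = ~stratified[id_col].str.upper().str.startswith(_EXCLUDE_PREFIXES)
        n_dropped = int((~keep).sum())
        if n_dropped:
            log.info("%s: dropped %d UNMAPPED/UNINTEGRATED rows", path, n_dropped)
        stratified = stratified[keep]
    if stratified.empty:
        raise ValueError(f"{path}: no stratified rows found")
    long = stratified.melt(
        id_vars=[id_col], value_vars=samples, var_name="sample", value_name="abundance"
    )
    long["pathway"] = long[id_col].str.split("|", n=1).str[0]
    long["taxon"] = long[id_col].str.split("|", n=1).str[1]
    try:
        long["abundance"] = long["abundance"].astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric abundance: {exc}") from exc
    return StratifiedProfile(long[["pathway", "taxon", "sample", "abundance"]])


def read_feature_table(
    path: str | Path, samples_in_columns: bool = True
) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a numeric feature table.

    With the default orientation the file is features x samples; the
    returned matrix is always samples x features.

    Returns (matrix, sample_ids, feature_ids).
    """
    df = _read_tsv(path)
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dups = df[id_col][df[id_col].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate feature ids {dups}")
    body = df.set_index(id_col)
    try:
        values = body.to_numpy(dtype=float)
    except ValueError:
        for i, col in enumerate(body.columns):
            for j, cell in enumerate(body[col]):
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at row {body.index[j]!r}, "
                        f"column {col!r}"
                    ) from None
        raise
    if samples_in_columns:
        return values.T, list(body.columns), list(body.index)
    return values, list(body.index), list(body.columns)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a metadata TSV with columns sample, subject and optional group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "subject"):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} missing")
    extra = [c for c in df.columns if c not in ("sample", "subject", "group")]
    if extra:
        log.info("%s: ignoring extra metadata columns %s", path, extra)
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample rows")
    return df


def _factor_frame(mat: np.ndarray, ids: list[str] | None, prefix: str) -> pd.DataFrame:
    r = mat.shape[1]
    index = ids if ids is not None else [f"{prefix}_{i}" for i in range(mat.shape[0])]
    return pd.DataFrame(mat, index=index, columns=[f"factor_{j + 1}" for j in range(r)])


def write_model(
    model: FactorModel | WeightedFactorModel,
    outdir: str | Path,
    ids: dict[str, list[str]] | None = None,
    config: dict | None = None,
) -> dict[str, Path]:
    """Write factor matrices (one TSV per mode) and a run-summary JSON.

    ``ids`` maps mode names (sample/microbe/pathway/metabolite) to label
    lists.  Weighted models additionally get a weights TSV with lambda,
    sigma and block shares per factor.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = ids or {}
    is_weighted = isinstance(model, WeightedFactorModel)
    modes = {
        "sample": model.a,
        "microbe": model.b,
        "pathway": model.c,
        "metabolite": model.v if is_weighted else model.d,
    }
    written: dict[str, Path] = {}
    for mode, mat in modes.items():
        p = outdir / f"loadings_{mode}.tsv"
        _factor_frame(mat, ids.get(mode), mode).to_csv(
            p, sep="\t", float_format=FLOAT_FMT, index_label="id"
        )
        written[mode] = p
    if is_weighted:
        shares = block_weight_shares(model)
        wdf = pd.DataFrame(
            {
                "factor": np.arange(1, model.R + 1),
                "lambda": model.lam,
                "sigma": model.sig,
                "tensor_share": shares["tensor"],
                "matrix_share": shares["matrix"],
            }
        )
        p = outdir / "weights.tsv"
        wdf.to_csv(p, sep="\t", float_format=FLOAT_FMT, index=False)
        written["weights"] = p
    summary = {
        "model": "advanced" if is_weighted else "basic",
        "R": model.R,
        "n_iter": model.n_iter,
        "converged": model.converged,
        "final_error": (
            model.objective_trace[-1]
            if is_weighted and model.objective_trace
            else (model.rmse_trace[-1] if not is_weighted and model.rmse_trace else None)
        ),
        "config": _jsonable(config) if config else None,
    }
    p = outdir / "run_summary.json"
    p.write_text(json.dumps(summary, indent=2) + "\n")
    written["summary"] = p
    return written


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_factor_table(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read back a loadings TSV written by :func:`write_model`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.index.astype(str))
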