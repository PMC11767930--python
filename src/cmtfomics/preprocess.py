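"""Preprocessing: from raw omics tables to the coupled tensor/matrix pair.

Stratified pathway abundances are scaled with "logstack" scaling (the
per-pathway community total is log-transformed and taxon contributions
are linearly rescaled inside that log total) and metabolite intensities
are mapped to unconstrained space with a per-sample centered log-ratio
(CLR) transform, the standard device for compositional data.  Repeated
samples of the same subject are averaged so that microbiome and
metabolome blocks can be joined on a shared subject-level mode.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datasets import CoupledDataset, StratifiedProfile

__all__ = [
    "logstack_scale",
    "clr_transform",
    "collapse_to_subjects",
    "assemble_coupled",
]

log = logging.getLogger(__name__)


def logstack_scale(
    profile: StratifiedProfile, base: float = 10.0, pseudo: float = 1.0
) -> StratifiedProfile:
    """Logstack-scale a stratified profile.

    For each (pathway, sample) cell with taxon contributions ``y_t`` and
    community total ``Y = sum_t y_t``, the scaled contribution is

        y'_t = (y_t / Y) * log_base(1 + Y)

    so contributions keep their within-cell proportions while the cell
    total becomes the log-transformed community abundance.  All-zero
    cells stay zero.  ``pseudo`` sets the offset inside the log (the
    ``1`` above is ``pseudo`` scaled: ``log_base(1 + Y/pseudo)``).
    """
    if pseudo <= 0:
        raise ValueError("pseudo must be positive")
    rec = profile.records.copy()
    totals = rec.groupby(["pathway", "sample"])["abundance"].transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(totals > 0, rec["abundance"] / totals, 0.0)
    log_total = np.log1p(totals.to_numpy() / pseudo) / np.log(base)
    rec["abundance"] = frac * log_total
    return StratifiedProfile(rec)


def clr_transform(m: np.ndarray, pseudo: float | None = None) -> np.ndarray:
    """Centered log-ratio transform, one composition per row (sample).

    Each row ``x`` becomes ``log(x + pseudo) - mean(log(x + pseudo))``,
    so every output row sums to zero.  When ``pseudo`` is None it
    defaults to half the smallest nonzero entry of the whole matrix if
    zeros are present, else 0.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("CLR requires non-negative intensities")
    if pseudo is None:
        if np.any(m == 0):
            nonzero = m[m > 0]
            if nonzero.size == 0:
                raise ValueError("all-zero matrix cannot be CLR-transformed")
            pseudo = float(nonzero.min()) / 2.0
        else:
            pseudo = 0.0
    if pseudo == 0.0 and np.any(m == 0):
        raise ValueError("zeros present: a positive pseudo-count is required")
    logged = np.log(m + pseudo)
    return logged - logged.mean(axis=1, keepdims=True)


def _mean_by_subject(
    values: np.ndarray, sample_ids: list[str], mapping: dict[str, str]
) -> tuple[np.ndarray, list[str]]:
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise KeyError(f"samples not in subject mapping: {missing}")
    subjects = sorted({mapping[s] for s in sample_ids})
    index = {subj: i for i, subj in enumerate(subjects)}
    out = np.zeros((len(subjects),) + values.shape[1:])
    counts = np.zeros(len(subjects))
    for row, s in enumerate(sample_ids):
        i = index[mapping[s]]
        out[i] += values[row]
        counts[i] += 1
    out /= counts.reshape((-1,) + (1,) * (values.ndim - 1))
    return out, subjects


def collapse_to_subjects(
    data: CoupledDataset, mapping: dict[str, str]
) -> CoupledDataset:
    """Average all samples of the same subject, blockwise.

    Subjects are ordered by sorted id.  Group labels carry over from any
    member sample (they must agree within a subject).
    """
    tensor, subjects = _mean_by_subject(data.tensor, data.sample_ids, mapping)
    matrix, subjects_m = _mean_by_subject(data.matrix, data.sample_ids, mapping)
    assert subjects == subjects_m
    groups = None
    if data.group_labels is not None:
        groups = {}
        for s in data.sample_ids:
            subj = mapping[s]
            g = data.group_labels.get(s)
            if subj in groups and groups[subj] != g:
                raise ValueError(f"subject {subj!r} has conflicting group labels")
            groups[subj] = g
    return CoupledDataset(
        tensor=tensor,
        matrix=matrix,
        sample_ids=subjects,
        microbe_ids=data.microbe_ids,
        pathway_ids=data.pathway_ids,
        metabolite_ids=data.metabolite_ids,
        group_labels=groups,
    )


def assemble_coupled(
    profile: StratifiedProfile,
    metab: np.ndarray,
    metab_sample_ids: list[str],
    metabolite_ids: list[str],
    metadata: pd.DataFrame | None = None,
    subject_map: dict[str, str] | None = None,
) -> CoupledDataset:
    """Join a stratified profile and a metabolite table on the sample mode.

    The tensor is zero-filled for (pathway, taxon) pairs absent from a
    sample.  Only samples present in BOTH blocks are kept (inner join),
    in sorted order.  When ``subject_map`` is given, each block is
    averaged to subject level before the join and the shared mode
    becomes subjects.  ``metadata`` (columns ``sample`` and optionally
    ``group``) attaches group labels to the shared mode.
    """
    if len(set(metabolite_ids)) != len(metabolite_ids):
        raise ValueError("duplicate metabolite ids")
    metab = np.asarray(metab, dtype=float)
    if metab.shape != (len(metab_sample_ids), len(metabolite_ids)):
        raise ValueError("metabolite matrix shape does not match its labels")

    rec = profile.records
    prof_samples = list(profile.samples)
    taxa = profile.taxa
    pathways = profile.pathways

    # dense tensor over the profile's own samples, zero-filled
    s_idx = {s: i for i, s in enumerate(prof_samples)}
    t_idx = {t: i for i, t in enumerate(taxa)}
    p_idx = {p: i for i, p in enumerate(pathways)}
    tensor = np.zeros((len(prof_samples), len(taxa), len(pathways)))
    tensor[
        rec["sample"].map(s_idx).to_numpy(),
        rec["taxon"].map(t_idx).to_numpy(),
        rec["pathway"].map(p_idx).to_numpy(),
    ] = rec["abundance"].to_numpy(dtype=float)

    if subject_map is not None:
        tensor, prof_samples = _mean_by_subject(tensor, prof_samples, subject_map)
        metab, metab_sample_ids = _mean_by_subject(metab, metab_sample_ids, subject_map)

    shared = sorted(set(prof_samples) & set(metab_sample_ids))
    if not shared:
        raise ValueError("no shared sample/subject ids between the two blocks")
    dropped = (set(prof_samples) | set(metab_sample_ids)) - set(shared)
    if dropped:
        log.info("dropping %d ids present in only one block: %s", len(dropped), sorted(dropped))

    tensor = tensor[[prof_samples.index(s) for s in shared]]
    matrix = np.asarray(metab)[[list(metab_sample_ids).index(s) for s in shared]]

    groups = None
    if metadata is not None and "group" in metadata.columns:
        key = "subject" if subject_map is not None and "subject" in metadata.columns else "sample"
        lookup = dict(zip(metadata[key], metadata["group"]))
        groups = {s: lookup.get(s) for s in shared}

    return CoupledDataset(
        tensor=tensor,
        matrix=matrix,
        sample_ids=shared,
        microbe_ids=taxa,
        pathway_ids=pathways,
        metabolite_ids=list(metabolite_ids),
        group_labels=groups,
    )
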