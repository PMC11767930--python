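"""In-memory containers for coupled multi-omics data.

``CoupledDataset`` pairs a 3-way tensor of stratified microbial pathway
abundances (sample x microbe x pathway) with a metabolite intensity
matrix (sample x metabolite); the two blocks share the sample mode.
``StratifiedProfile`` is the long-format view of a stratified functional
profile (one record per pathway/taxon/sample triple) as produced by
metagenomic functional annotation pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StratifiedProfile", "CoupledDataset"]


@dataclass
class StratifiedProfile:
    """Long-format stratified functional profile.

    ``records`` has columns ``pathway``, ``taxon``, ``sample``,
    ``abundance`` with non-negative abundances and unique
    (pathway, taxon, sample) triples.
    """

    records: pd.DataFrame

    REQUIRED = ("pathway", "taxon", "sample", "abundance")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"profile records missing columns: {missing}")
        ab = self.records["abundance"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ab)):
            raise ValueError("non-finite abundance in profile")
        if np.any(ab < 0):
            raise ValueError("negative abundance in profile")
        if self.records.duplicated(["pathway", "taxon", "sample"]).any():
            raise ValueError("duplicate (pathway, taxon, sample) triples")

    @property
    def pathways(self) -> list[str]:
        return sorted(self.records["pathway"].unique())

    @property
    def taxa(self) -> list[str]:
        return sorted(self.records["taxon"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample"].unique())


@dataclass
class CoupledDataset:
    """A tensor/matrix pair sharing the first (sample) mode.

    tensor : (n_samples, n_microbes, n_pathways) array
    matrix : (n_samples, n_metabolites) array
    """

    tensor: np.ndarray
    matrix: np.ndarray
    sample_ids: list[str]
    microbe_ids: list[str]
    pathway_ids: list[str]
    metabolite_ids: list[str]
    group_labels: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.tensor.ndim != 3:
            raise ValueError("tensor must be 3-way")
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-way")
        if self.tensor.shape[0] != self.matrix.shape[0]:
            raise ValueError(
                "tensor and matrix disagree on sample count: "
                f"{self.tensor.shape[0]} vs {self.matrix.shape[0]}"
            )
        labels = {
            "sample_ids": (self.sample_ids, self.tensor.shape[0]),
            "microbe_ids": (self.microbe_ids, self.tensor.shape[1]),
            "pathway_ids": (self.pathway_ids, self.tensor.shape[2]),
            "metabolite_ids": (self.metabolite_ids, self.matrix.shape[1]),
        }
        for name, (ids, n) in labels.items():
            if len(ids) != n:
                raise ValueError(f"{name} has {len(ids)} labels for axis of length {n}")
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate ids in {name}")
        if not (np.all(np.isfinite(self.tensor)) and np.all(np.isfinite(self.matrix))):
            raise ValueError("non-finite entries in coupled data")

    @property
    def shapes(self) -> tuple[tuple[int, int, int], tuple[int, int]]:
        return self.tensor.shape, self.matrix.shape

    @property
    def dims(self) -> tuple[int, int, int, int]:
        """(n_samples, n_microbes, n_pathways, n_metabolites)."""
        return (*self.tensor.shape, self.matrix.shape[1])

    def groups_array(self) -> np.ndarray | None:
        """Per-sample group labels aligned with the sample axis, or None."""
        if self.group_labels is None:
            return None
        return np.array([self.group_labels.get(s) for s in self.sample_ids], dtype=object)
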