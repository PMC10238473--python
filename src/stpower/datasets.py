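"""In-memory containers: spot-level, bulk-cohort and ROI-level count data.

Counts are dense integer numpy arrays (genes x columns) with pandas indexes
and metadata frames alongside; the datasets here are small enough that a
dense layout keeps every downstream operation simple and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

SPOT_CLASSES = ("niche", "hepatocyte", "other")
BULK_GROUPS = ("stable", "progressor", "regressor")


def _check_counts(counts: np.ndarray, what: str) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError(f"{what} counts must be a 2-D matrix")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.all(np.equal(np.mod(counts, 1), 0)):
            raise ValueError(f"{what} counts must be integral")
        counts = counts.astype(np.int64)
    if counts.size and counts.min() < 0:
        raise ValueError(f"{what} counts must be non-negative")
    return counts


@dataclass
class SpotDataset:
    """Gene x spot counts on a grid, with per-spot and per-gene metadata.

    ``spot_meta`` is indexed by spot id and carries ``sample_id``, integer
    grid coordinates ``row``/``col`` (physical positions are col x spacing,
    row x spacing) and, for synthetic data, the planted ``true_class``.
    ``gene_meta`` is indexed by gene id with ``marker_set``, ``panel_member``,
    ``background_probe`` and ``composite`` flags.
    """

    counts: np.ndarray
    genes: pd.Index
    spot_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    spot_diameter_um: float = 55.0
    spot_spacing_um: float = 100.0

    def __post_init__(self):
        self.counts = _check_counts(self.counts, "spot")
        self.genes = pd.Index(self.genes, name="gene")
        if self.counts.shape != (len(self.genes), len(self.spot_meta)):
            raise ValueError("counts shape does not match genes x spot_meta")
        if self.genes.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.spot_meta.index.has_duplicates:
            raise ValueError("duplicate spot ids")
        for col in ("sample_id", "row", "col"):
            if col not in self.spot_meta.columns:
                raise ValueError(f"spot_meta must carry column {col!r}")
        dup = self.spot_meta.duplicated(subset=["sample_id", "row", "col"])
        if dup.any():
            raise ValueError("(row, col) must be unique within a sample")
        if not self.gene_meta.index.equals(self.genes):
            raise ValueError("gene_meta index must equal the gene axis")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_ids(self) -> list:
        return list(pd.unique(self.spot_meta["sample_id"]))

    def copy(self) -> "SpotDataset":
        return SpotDataset(
            counts=self.counts.copy(),
            genes=self.genes.copy(),
            spot_meta=self.spot_meta.copy(),
            gene_meta=self.gene_meta.copy(),
            spot_diameter_um=self.spot_diameter_um,
            spot_spacing_um=self.spot_spacing_um,
        )

    def subset_spots(self, mask) -> "SpotDataset":
        mask = np.asarray(mask)
        return SpotDataset(
            counts=self.counts[:, mask],
            genes=self.genes,
            spot_meta=self.spot_meta.loc[mask],
            gene_meta=self.gene_meta,
            spot_diameter_um=self.spot_diameter_um,
            spot_spacing_um=self.spot_spacing_um,
        )

    def subset_genes(self, keep) -> "SpotDataset":
        keep = np.asarray(keep)
        return SpotDataset(
            counts=self.counts[keep, :],
            genes=self.genes[keep],
            spot_meta=self.spot_meta,
            gene_meta=self.gene_meta.iloc[keep],
            spot_diameter_um=self.spot_diameter_um,
            spot_spacing_um=self.spot_spacing_um,
        )


@dataclass
class BulkCohort:
    """Gene x subject counts with outcome group and histology covariates."""

    counts: np.ndarray
    genes: pd.Index
    subject_meta: pd.DataFrame  # group, fibrosis_stage, NAS

    def __post_init__(self):
        self.counts = _check_counts(self.counts, "bulk")
        self.genes = pd.Index(self.genes, name="gene")
        if self.counts.shape != (len(self.genes), len(self.subject_meta)):
            raise ValueError("counts shape does not match genes x subjects")
        bad = set(self.subject_meta["group"]) - set(BULK_GROUPS)
        if bad:
            raise ValueError(f"unknown bulk group labels: {sorted(bad)}")

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[1]


@dataclass
class ROIDataset:
    """Gene x ROI counts mimicking a GeoMx experiment on one tissue class."""

    counts: np.ndarray
    genes: pd.Index
    roi_meta: pd.DataFrame  # patient_id, group, tissue_class, diameter_um,
    #                         n_spots_aggregated, source_sample_id
    gene_meta: pd.DataFrame

    def __post_init__(self):
        self.counts = _check_counts(self.counts, "ROI")
        self.genes = pd.Index(self.genes, name="gene")
        if self.counts.shape != (len(self.genes), len(self.roi_meta)):
            raise ValueError("counts shape does not match genes x ROIs")
        if not self.gene_meta.index.equals(self.genes):
            raise ValueError("gene_meta index must equal the gene axis")
        if len(self.roi_meta):
            if self.roi_meta["tissue_class"].nunique() > 1:
                raise ValueError("all ROIs of one dataset must share tissue_class")
            if self.roi_meta["diameter_um"].nunique() > 1:
                raise ValueError("all ROIs of one dataset must share diameter")

    @property
    def n_rois(self) -> int:
        return self.counts.shape[1]

    def subset_rois(self, mask) -> "ROIDataset":
        mask = np.asarray(mask)
        return ROIDataset(
            counts=self.counts[:, mask],
            genes=self.genes,
            roi_meta=self.roi_meta.loc[mask],
            gene_meta=self.gene_meta,
        )
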