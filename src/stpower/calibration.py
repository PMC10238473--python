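"""Spike-in calibration: translate a bulk-tissue log2 fold change into a
compartment-level spike-in fraction.

A spike-in with fraction r adds r x (per-sample class median count of the
target gene) to every target-class spot.  Summing all spots per sample gives
pseudobulk "tissue"; the paired NB fold change between spiked and unmodified
pseudobulk, evaluated over a grid of r, forms a calibration curve whose
inversion picks the r that reproduces a bulk-cohort effect size inside the
compartment.  Because the fibrotic niche covers a few percent of spots while
hepatocytes cover about two thirds, a niche-restricted signal is diluted in
pseudobulk and needs a much larger r for the same bulk fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import half_up
from .config import SpikeSpec
from .datasets import SpotDataset
from .discovery import SegmentationResult, median_of_ratios_size_factors
from .nbmodels import LN2, fit_nb_glm


def apply_spike(
    spots: SpotDataset,
    spec: SpikeSpec,
    labels: SegmentationResult,
    integer: bool = True,
) -> SpotDataset:
    """Add r x per-sample class-median counts of the target gene to every
    target-class spot.

    The median is taken over the unmodified counts (the spike is not
    self-referential).  Increments are rounded half-up to keep counts
    integral; ``integer=False`` keeps fractional values for sensitivity
    checks.  Samples with no target-class spots are skipped with a warning.
    """
    if spec.gene not in spots.genes:
        raise KeyError(f"gene {spec.gene!r} not in dataset")
    lab = labels.labels.reindex(spots.spot_meta.index)
    if lab.isna().any():
        raise ValueError("labels are not aligned to the spot axis")
    gi = spots.genes.get_loc(spec.gene)
    out_counts = spots.counts.astype(float) if not integer else spots.counts.copy()
    sample = spots.spot_meta["sample_id"].to_numpy()
    lab = lab.to_numpy()
    for s in pd.unique(sample):
        mask = (sample == s) & (lab == spec.target_class)
        if not mask.any():
            warnings.warn(f"sample {s!r}: no {spec.target_class!r} spots; skipped")
            continue
        med = float(np.median(spots.counts[gi, mask]))
        inc = spec.r * med
        if integer:
            inc = half_up(inc)
        out_counts[gi, mask] += inc
    out = spots.copy()
    # fractional mode bypasses the dataclass integer validation on purpose
    out.counts = out_counts
    return out


def pseudobulk(
    spots: SpotDataset,
    labels: Optional[SegmentationResult] = None,
    tissue_class: Optional[str] = None,
) -> pd.DataFrame:
    """Sum spot counts per sample; optionally restricted to one tissue class.

    Returns a genes x samples DataFrame of integer sums.
    """
    include = np.ones(spots.n_spots, dtype=bool)
    if tissue_class is not None:
        if labels is None:
            raise ValueError("tissue_class restriction requires labels")
        include = labels.labels.reindex(spots.spot_meta.index).to_numpy() == tissue_class
    sample = spots.spot_meta["sample_id"].to_numpy()
    cols = {}
    for s in pd.unique(sample):
        m = include & (sample == s)
        cols[s] = spots.counts[:, m].sum(axis=1)
    return pd.DataFrame(cols, index=spots.genes)


def paired_nb_log2fc(
    bulk_a: pd.DataFrame, bulk_b: pd.DataFrame, gene: str
) -> tuple[float, float, float]:
    """Paired NB fold change of one gene between two pseudobulk conditions.

    Fits an NB log-linear model of the gene's counts on condition plus a
    sample fixed effect, with log median-of-ratios size factors (computed
    across all 2n columns of the combined matrix) as offset and ML
    dispersion.  Returns (log2FC, SE, Wald p) for condition b vs a.
    """
    if list(bulk_a.columns) != list(bulk_b.columns):
        raise ValueError("both conditions must cover the same samples")
    if gene not in bulk_a.index:
        raise KeyError(f"gene {gene!r} not in pseudobulk matrix")
    combined = np.concatenate([bulk_a.to_numpy(), bulk_b.to_numpy()], axis=1)
    sf = median_of_ratios_size_factors(combined)
    n = bulk_a.shape[1]
    y = np.concatenate([bulk_a.loc[gene].to_numpy(), bulk_b.loc[gene].to_numpy()])
    if np.all(y == 0):
        warnings.warn(f"gene {gene!r} has zero counts in all columns")
        return (np.nan, np.nan, np.nan)
    cond = np.r_[np.zeros(n), np.ones(n)]
    sample_d = np.tile(np.eye(n)[:, 1:], (2, 1))  # n-1 sample dummies
    X = np.column_stack([np.ones(2 * n), cond, sample_d])
    fit = fit_nb_glm(y.astype(float), X, offset=np.log(sf))
    from scipy import stats

    z = fit.coef[1] / fit.se[1]
    p = 2.0 * stats.norm.sf(abs(z))
    return (fit.coef[1] / LN2, fit.se[1] / LN2, float(p))


@dataclass
class CalibrationCurve:
    gene: str
    target_class: str
    r_grid: np.ndarray
    lfc: np.ndarray
    se: np.ndarray

    def __post_init__(self):
        self.r_grid = np.asarray(self.r_grid, float)
        self.lfc = np.asarray(self.lfc, float)
        self.se = np.asarray(self.se, float)
        if np.any(np.diff(self.r_grid) <= 0):
            raise ValueError("r_grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.r_grid, "lfc": self.lfc, "se": self.se})


DEFAULT_R_GRID = np.round(np.arange(0.0, 4.0 + 1e-9, 0.1), 10)


def build_calibration_curve(
    spots: SpotDataset,
    labels: SegmentationResult,
    gene: str,
    target_class: str,
    r_grid: Sequence[float] = DEFAULT_R_GRID,
) -> CalibrationCurve:
    """Calibration curve: pseudobulk log2FC induced by each spike fraction r."""
    r_grid = np.asarray(r_grid, float)
    if not np.any(r_grid == 0):
        raise ValueError("r_grid must include 0")
    base = pseudobulk(spots)
    lfcs, ses = [], []
    for r in r_grid:
        spiked = apply_spike(spots, SpikeSpec(gene=gene, r=float(r),
                                              target_class=target_class), labels)
        lfc, se, _ = paired_nb_log2fc(base, pseudobulk(spiked), gene)
        lfcs.append(lfc)
        ses.append(se)
    return CalibrationCurve(gene, target_class, r_grid, lfcs, ses)


def invert_calibration(curve: CalibrationCurve, target_lfc: float) -> float:
    """Smallest r on the curve whose interpolated log2FC equals target_lfc.

    Linear interpolation between the first pair of grid points bracketing the
    target; raises if the target lies outside the curve's range.
    """
    lfc = curve.lfc
    if not (np.nanmin(lfc) <= target_lfc <= np.nanmax(lfc)):
        raise ValueError(
            f"target log2FC {target_lfc} outside curve range "
            f"[{np.nanmin(lfc):.3g}, {np.nanmax(lfc):.3g}]; extend r_grid"
        )
    for i in range(lfc.size - 1):
        lo, hi = lfc[i], lfc[i + 1]
        if (lo <= target_lfc <= hi) or (hi <= target_lfc <= lo):
            if hi == lo:
                return float(curve.r_grid[i])
            frac = (target_lfc - lo) / (hi - lo)
            return float(curve.r_grid[i] + frac * (curve.r_grid[i + 1] - curve.r_grid[i]))
    # only reachable when the extremum is at a single grid point
    return float(curve.r_grid[int(np.nanargmin(np.abs(lfc - target_lfc)))])
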