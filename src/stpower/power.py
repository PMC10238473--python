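"""Power engine: run the simulation grid and summarize rejection rates.

Each grid cell (endpoint x N patients x N ROIs x ROI diameter) is evaluated
by repeatedly assembling a synthetic two-group ROI dataset, computing TMM
effective library sizes, testing the endpoint gene's group effect and
recording (p, log2FC, convergence).  Power is the rejection fraction at
level alpha among converged repeats, with the convergence rate reported
alongside; log2FC is summarized as median and IQR.  Every repeat draws its
seed from (master seed, condition key, repeat index), so cells are
independent and grid order is irrelevant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .config import Condition, DropoutSpec, RunConfig
from .datasets import ROIDataset, SpotDataset
from .geomx import apply_dropout, assemble_dataset
from .nbmodels import TestResult, fit_nb_glmm, lrt_test, tmm_effective_libsize, wald_test

logger = logging.getLogger(__name__)


@dataclass
class PowerResult:
    condition: Condition
    method: str
    power: float
    median_lfc: float
    lfc_iqr_lo: float
    lfc_iqr_hi: float
    convergence_rate: float
    n_reps: int
    seed: int

    def to_row(self) -> dict:
        c = self.condition
        return {
            "endpoint": c.endpoint,
            "method": self.method,
            "n_patients": c.n_patients_per_group,
            "n_rois": c.n_rois_per_patient,
            "diameter_um": c.roi_diameter_um,
            "power": self.power,
            "median_lfc": self.median_lfc,
            "lfc_q1": self.lfc_iqr_lo,
            "lfc_q3": self.lfc_iqr_hi,
            "convergence_rate": self.convergence_rate,
            "n_reps": self.n_reps,
            "seed": self.seed,
        }


def _test_dataset(ds: ROIDataset, gene: str, methods, plugin) -> dict:
    """Run each requested test on the endpoint gene of one ROI dataset."""
    gm = ds.gene_meta
    model_genes = (gm["panel_member"] & ~gm["composite"]).to_numpy()
    libs = tmm_effective_libsize(ds.counts[model_genes])
    offset = np.log(libs.effective)
    y = ds.counts[ds.genes.get_loc(gene)].astype(float)
    group = (ds.roi_meta["group"] == "spiked").to_numpy(float)
    patient = ds.roi_meta["patient_id"].to_numpy()

    out = {}
    for m in methods:
        if m == "wald_glmm":
            out[m] = wald_test(fit_nb_glmm(y, group, patient, offset))
        elif m == "lrt_glmm":
            out[m] = lrt_test(y, group, patient, offset)
        elif m == "plugin":
            out[m] = plugin(y, group, patient, offset)
        else:  # pragma: no cover - validated in RunConfig
            raise ValueError(f"unknown method {m!r}")
    return out


def run_condition(
    cond: Condition,
    pool_control: SpotDataset,
    pool_spiked: SpotDataset,
    cfg: RunConfig,
    dropout: Optional[DropoutSpec] = None,
) -> list[PowerResult]:
    """Monte-Carlo power estimate for one grid condition (one per method)."""
    collected: dict = {m: [] for m in cfg.methods}
    for rep in range(cfg.n_reps):
        rep_seed = derive_seed(cfg.seed, cond.key(), rep)
        rng = np.random.default_rng(rep_seed)
        ds = assemble_dataset(cond, pool_control, pool_spiked, rng)
        if dropout is not None and dropout.n_remove > 0:
            ds = apply_dropout(
                ds, DropoutSpec(dropout.n_remove,
                                seed=derive_seed(rep_seed, "dropout"))
            )
        results = _test_dataset(ds, cond.spike.gene, cfg.methods, cfg.plugin)
        for m, res in results.items():
            collected[m].append(res)

    out = []
    for m, results in collected.items():
        conv = [r for r in results if r.converged and np.isfinite(r.p)]
        n_conv = len(conv)
        if n_conv == 0:
            out.append(PowerResult(cond, m, np.nan, np.nan, np.nan, np.nan,
                                   0.0, cfg.n_reps, cfg.seed))
            continue
        rejections = sum(r.p < cfg.alpha for r in conv)
        denom = cfg.n_reps if cfg.count_nonconverged_as_failures else n_conv
        lfcs = np.array([r.lfc for r in conv], float)
        q1, med, q3 = np.percentile(lfcs, [25, 50, 75])
        out.append(PowerResult(
            condition=cond, method=m, power=rejections / denom,
            median_lfc=med, lfc_iqr_lo=q1, lfc_iqr_hi=q3,
            convergence_rate=n_conv / cfg.n_reps,
            n_reps=cfg.n_reps, seed=cfg.seed,
        ))
    return out


def run_grid(
    grid: Sequence[Condition],
    pools: dict,
    cfg: RunConfig,
) -> pd.DataFrame:
    """Run every condition of a grid.

    ``pools`` maps endpoint name -> (control pool, spiked pool).  Per-cell
    failures are logged and reported as NaN rows without aborting the grid.
    Returns a long-format table suitable for power-surface plotting.
    """
    keys = {c.key() for c in grid}
    if len(keys) != len(grid):
        raise ValueError("grid conditions must be unique")
    rows = []
    for cond in grid:
        logger.info(
            "condition endpoint=%s n_patients=%d n_rois=%d diameter=%g",
            cond.endpoint, cond.n_patients_per_group,
            cond.n_rois_per_patient, cond.roi_diameter_um,
        )
        try:
            pool_c, pool_s = pools[cond.endpoint]
            for res in run_condition(cond, pool_c, pool_s, cfg):
                rows.append(res.to_row())
        except Exception as exc:  # keep the grid going
            logger.error("condition %s failed: %s", cond.key(), exc)
            for m in cfg.methods:
                rows.append({
                    "endpoint": cond.endpoint, "method": m,
                    "n_patients": cond.n_patients_per_group,
                    "n_rois": cond.n_rois_per_patient,
                    "diameter_um": cond.roi_diameter_um,
                    "power": np.nan, "median_lfc": np.nan,
                    "lfc_q1": np.nan, "lfc_q3": np.nan,
                    "convergence_rate": np.nan,
                    "n_reps": cfg.n_reps, "seed": cfg.seed,
                })
    return pd.DataFrame(rows)


def required_n(results: pd.DataFrame, target_power: float = 0.8):
    """Smallest n_patients whose power meets the target; None if never met.

    ``results`` must be a single method/ROI/diameter slice with a power
    column indexed over a contiguous range of n_patients.
    """
    if results.empty:
        raise ValueError("empty results table")
    df = results.sort_values("n_patients")
    met = df.loc[df["power"] >= target_power, "n_patients"]
    return int(met.iloc[0]) if len(met) else None


def dropout_sensitivity(
    cond: Condition,
    dropout: DropoutSpec,
    pool_control: SpotDataset,
    pool_spiked: SpotDataset,
    cfg: RunConfig,
) -> list[PowerResult]:
    """Power under random ROI loss ("failed quality control") that never
    fully depletes a patient."""
    total = 2 * cond.n_patients_per_group * cond.n_rois_per_patient
    if total - dropout.n_remove < 2 * cond.n_patients_per_group:
        raise ValueError("dropout infeasible: some patient must lose all ROIs")
    return run_condition(cond, pool_control, pool_spiked, cfg, dropout=dropout)


def sample_budget(
    n_patients_endpoint1: int,
    n_rois_1: int,
    n_patients_endpoint2: int,
    n_rois_2: int,
    n_groups: int,
    paired_followup: bool = False,
) -> int:
    """Total sequenced samples for a two-endpoint design.

    (n1 x r1 + n2 x r2) x groups, doubled when paired follow-up biopsies of
    the same patients and tissue areas are profiled.
    """
    for v in (n_patients_endpoint1, n_rois_1, n_patients_endpoint2, n_rois_2,
              n_groups):
        if v < 0:
            raise ValueError("design counts must be non-negative")
    total = (n_patients_endpoint1 * n_rois_1
             + n_patients_endpoint2 * n_rois_2) * n_groups
    return total * 2 if paired_followup else total


def alpha_adjust(base_alpha: float = 0.05, n_endpoints: int = 2,
                 n_genes: int = 1) -> float:
    """Bonferroni-style split of the significance level over endpoints and,
    optionally, a transcriptome-wide gene count (0.05/2 -> 0.025;
    0.05/2/2000 -> 1.25e-05)."""
    if base_alpha <= 0 or n_endpoints <= 0 or n_genes <= 0:
        raise ValueError("inputs must be positive")
    return base_alpha / (n_endpoints * n_genes)
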