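"""Reading and writing of spot, bulk and ROI datasets, and the end-to-end
pipeline runner.

Spot data uses the 10x-style triplet dialect — ``matrix.mtx`` (MatrixMarket,
genes x spots) plus headerless ``genes.tsv`` and ``spots.tsv`` — or a dense
CSV with coordinate columns.  All other tables are UTF-8 comma-delimited CSV
with a mandatory header row.  Grid coordinates are 0-based (row, col);
physical positions are col x spacing, row x spacing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datasets import BulkCohort, ROIDataset, SpotDataset

logger = logging.getLogger(__name__)

_GENE_COLS = ["gene", "marker_set", "panel_member", "background_probe", "composite"]
_SPOT_COLS = ["spot_id", "sample_id", "row", "col", "true_class"]


def write_spot_dataset(spots: SpotDataset, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(spots.counts))
    gm = spots.gene_meta.reset_index()
    gm.columns = _GENE_COLS
    gm.to_csv(outdir / "genes.tsv", sep="\t", header=False, index=False)
    sm = spots.spot_meta.reset_index()
    if "true_class" not in sm.columns:
        sm["true_class"] = ""
    sm[_SPOT_COLS].to_csv(outdir / "spots.tsv", sep="\t", header=False, index=False)
    meta = {"spot_diameter_um": spots.spot_diameter_um,
            "spot_spacing_um": spots.spot_spacing_um}
    (outdir / "dataset.json").write_text(json.dumps(meta))
    return outdir


def _coerce_integer_matrix(dense: np.ndarray, path) -> np.ndarray:
    frac = np.mod(dense, 1) != 0
    if frac.any():
        g, s = np.argwhere(frac)[0]
        raise ValueError(
            f"{path}: non-integer count {dense[g, s]} at matrix entry "
            f"(gene {g + 1}, column {s + 1})"
        )
    return dense.astype(np.int64)


def read_spot_matrix(path) -> SpotDataset:
    """Load a SpotDataset from an MTX triplet directory or a dense CSV.

    The CSV dialect is genes x spots with a ``gene`` first column; spot
    metadata is read from a sibling ``spots.csv`` (spot_id, sample_id, row,
    col[, true_class]) and gene metadata from an optional ``genes.csv``.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        for req in (mtx, path / "genes.tsv", path / "spots.tsv"):
            if not req.exists():
                raise FileNotFoundError(f"{req}: missing from MTX triplet")
        try:
            mat = spio.mmread(mtx)
        except Exception as exc:
            raise ValueError(f"{mtx}: malformed MatrixMarket file ({exc})") from exc
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        counts = _coerce_integer_matrix(dense, mtx)
        gm = pd.read_csv(path / "genes.tsv", sep="\t", header=None,
                         names=_GENE_COLS)
        if gm["gene"].duplicated().any():
            dup = gm["gene"][gm["gene"].duplicated()].iloc[0]
            raise ValueError(f"{path / 'genes.tsv'}: duplicate gene id {dup!r}")
        sm = pd.read_csv(path / "spots.tsv", sep="\t", header=None,
                         names=_SPOT_COLS)
        if counts.shape != (len(gm), len(sm)):
            raise ValueError(
                f"{mtx}: matrix is {counts.shape} but genes.tsv/spots.tsv "
                f"describe ({len(gm)}, {len(sm)})"
            )
        kwargs = {}
        meta_file = path / "dataset.json"
        if meta_file.exists():
            kwargs = json.loads(meta_file.read_text())
        return SpotDataset(
            counts=counts,
            genes=pd.Index(gm["gene"]),
            spot_meta=sm.set_index("spot_id"),
            gene_meta=gm.set_index("gene"),
            **kwargs,
        )

    # dense CSV dialect
    df = pd.read_csv(path)
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: first column of a dense CSV must be 'gene'")
    values = df.set_index("gene")
    arr = values.to_numpy(dtype=float)
    frac = np.mod(arr, 1) != 0
    if frac.any():
        g, s = np.argwhere(frac)[0]
        raise ValueError(
            f"{path}: non-integer count {arr[g, s]} at line {g + 2}, "
            f"column {values.columns[s]!r}"
        )
    spots_file = path.parent / "spots.csv"
    if not spots_file.exists():
        raise FileNotFoundError(f"{spots_file}: spot metadata required")
    sm = pd.read_csv(spots_file).set_index("spot_id")
    genes_file = path.parent / "genes.csv"
    if genes_file.exists():
        gm = pd.read_csv(genes_file).set_index("gene")
    else:
        gm = pd.DataFrame(
            {"marker_set": "none", "panel_member": True,
             "background_probe": False, "composite": False},
            index=values.index,
        )
    return SpotDataset(
        counts=arr.astype(np.int64),
        genes=values.index,
        spot_meta=sm.loc[values.columns],
        gene_meta=gm,
    )


def write_bulk_cohort(bulk: BulkCohort, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(bulk.counts, index=bulk.genes,
                 columns=bulk.subject_meta.index).to_csv(outdir / "bulk_counts.csv")
    bulk.subject_meta.to_csv(outdir / "bulk_covariates.csv")
    return outdir


def read_bulk_cohort(counts_csv, covariates_csv) -> BulkCohort:
    counts = pd.read_csv(counts_csv, index_col=0)
    meta = pd.read_csv(covariates_csv, index_col=0)
    if list(counts.columns) != list(meta.index):
        raise ValueError("bulk counts columns do not match covariate subjects")
    return BulkCohort(counts=counts.to_numpy(), genes=counts.index,
                      subject_meta=meta)


def write_roi_dataset(ds: ROIDataset, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ds.counts, index=ds.genes,
                 columns=ds.roi_meta.index).to_csv(outdir / "roi_counts.csv")
    ds.roi_meta.to_csv(outdir / "roi_meta.csv")
    ds.gene_meta.to_csv(outdir / "roi_genes.csv")
    return outdir


def read_gene_sets(path) -> dict:
    """Gene sets as a JSON mapping name -> list, or a one-column text file."""
    path = Path(path)
    if path.suffix == ".json":
        return json.loads(path.read_text())
    genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return {path.stem: genes}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline


DEFAULT_PIPELINE_CONFIG = {
    "master_seed": 0,
    "simulate": {"grid_rows": 24, "grid_cols": 24, "n_genes": 300,
                 "n_samples": 3, "marker_fold": 6.0},
    "calibrate": {"r_grid_max": 4.0, "r_grid_step": 0.5},
    "power": {"alpha": 0.025, "n_reps": 5, "methods": ["wald_glmm"],
              "n_patients": [4], "n_rois": [2], "diameters": [165.0]},
    "sensitivity": {"n_remove": 2},
}


def run_pipeline(config: dict, output_dir) -> Path:
    """Execute simulate -> discover -> calibrate -> power -> sensitivity.

    Each stage persists its outputs under ``output_dir``; a manifest records
    the master seed, config hash and the stage list.  Any stage failure
    raises with the stage name after partial outputs are on disk.
    """
    from . import __version__
    from .calibration import apply_spike, build_calibration_curve, invert_calibration
    from .config import (Condition, DropoutSpec, RunConfig, SimConfig, SpikeSpec)
    from .discovery import kuppe_score, normalize_counts, candidate_gene_screen, segment_spots
    from .geomx import restrict_to_class
    from .power import dropout_sensitivity, run_grid
    from .synth import generate_bulk_cohort, generate_spot_dataset

    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = {**DEFAULT_PIPELINE_CONFIG, **config}
    seed = int(cfg["master_seed"])
    stages_done = []
    stage = "simulate"
    try:
        sim = SimConfig(seed=seed, **cfg.get("simulate", {}))
        spots = generate_spot_dataset(sim)
        bulk = generate_bulk_cohort(sim)
        write_spot_dataset(spots, outdir / "spots")
        write_bulk_cohort(bulk, outdir / "bulk")
        stages_done.append(stage)

        stage = "discover"
        sets = sim.resolved_marker_sets()
        norm_bulk = normalize_counts(bulk.counts, genes=bulk.genes,
                                     columns=bulk.subject_meta.index)
        screen = candidate_gene_screen(norm_bulk, bulk.subject_meta)
        screen.to_csv(outdir / "screen.csv")
        norm_spots = normalize_counts(spots.counts, genes=spots.genes,
                                      columns=spots.spot_meta.index,
                                      size_factor_method="poscounts")
        hep = kuppe_score(norm_spots, sets["hepatocyte"], name="hepatocyte")
        ecm = kuppe_score(norm_spots, sets["ecm"], name="ecm")
        seg = segment_spots(spots, hep, ecm)
        seg.labels.to_frame().assign(seed=seed).to_csv(outdir / "labels.csv")
        stages_done.append(stage)

        stage = "calibrate"
        cal_cfg = cfg.get("calibrate", {})
        r_grid = np.round(np.arange(0.0, cal_cfg.get("r_grid_max", 4.0) + 1e-9,
                                    cal_cfg.get("r_grid_step", 0.5)), 10)
        endpoints = {}
        for endpoint, gene, target_class, contrast in (
            ("primary", "PON1", "hepatocyte", "lfc_regr"),
            ("secondary", "FLNA", "niche", "lfc_prog"),
        ):
            curve = build_calibration_curve(spots, seg, gene, target_class, r_grid)
            curve.to_frame().assign(gene=gene, seed=seed).to_csv(
                outdir / f"calibration_{endpoint}.csv", index=False)
            target_lfc = float(screen.loc[gene, contrast])
            target_lfc = float(np.clip(target_lfc, np.nanmin(curve.lfc),
                                       np.nanmax(curve.lfc)))
            r_star = invert_calibration(curve, target_lfc)
            spiked = apply_spike(spots, SpikeSpec(gene, r_star, target_class), seg)
            endpoints[endpoint] = {
                "gene": gene, "target_class": target_class,
                "target_lfc": target_lfc, "r_star": r_star,
                "pools": (restrict_to_class(spots, seg, target_class),
                          restrict_to_class(spiked, seg, target_class)),
            }
        stages_done.append(stage)

        stage = "power"
        pcfg = cfg.get("power", {})
        run_cfg = RunConfig(alpha=pcfg.get("alpha", 0.025),
                            n_reps=pcfg.get("n_reps", 5),
                            methods=tuple(pcfg.get("methods", ["wald_glmm"])),
                            seed=seed)
        grid = []
        for endpoint, info in endpoints.items():
            for n_p in pcfg.get("n_patients", [4]):
                for n_r in pcfg.get("n_rois", [2]):
                    for d in pcfg.get("diameters", [165.0]):
                        grid.append(Condition(
                            endpoint=endpoint, n_patients_per_group=n_p,
                            n_rois_per_patient=n_r, roi_diameter_um=d,
                            spike=SpikeSpec(info["gene"], info["r_star"],
                                            info["target_class"]),
                        ))
        pools = {e: info["pools"] for e, info in endpoints.items()}
        results = run_grid(grid, pools, run_cfg)
        results.to_csv(outdir / "power_results.csv", index=False)
        stages_done.append(stage)

        stage = "sensitivity"
        scfg = cfg.get("sensitivity", {})
        cond = grid[0]
        sens = dropout_sensitivity(
            cond, DropoutSpec(scfg.get("n_remove", 2), seed=seed),
            *pools[cond.endpoint], run_cfg)
        pd.DataFrame([r.to_row() for r in sens]).to_csv(
            outdir / "sensitivity_results.csv", index=False)
        stages_done.append(stage)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed after {stages_done}: {exc}"
        ) from exc

    manifest = {
        "master_seed": seed,
        "config_hash": config_hash(cfg),
        "alpha": cfg.get("power", {}).get("alpha", 0.025),
        "stages": stages_done,
        "version": __version__,
        "endpoints": {
            e: {k: v for k, v in info.items() if k != "pools"}
            for e, info in endpoints.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
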