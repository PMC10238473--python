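"""Synthetic spot-level and bulk-cohort count generators.

The spot generator emulates Visium-like liver sections: a square grid of
55 µm spots at 100 µm centre spacing, partitioned into a small fibrotic-niche
compartment (contiguous blobs), a large hepatocyte compartment and a
remainder of mixed/other tissue.  Counts are negative binomial with
log-normal per-spot library sizes; marker genes are elevated in their home
compartment so compartment summary scores separate the classes.  Spots are
exchangeable given class and sample: no extra within-sample correlation is
planted, mirroring spatial reference data in which within-patient spot
profiles correlated no more strongly than between-patient ones.

The bulk generator emulates a longitudinal fibrosis cohort (28 stable / 15
progressor / 15 regressor subjects) with baseline fibrosis stage and NAS
covariates and opposite-direction planted effects on the lipid and
cytoskeleton gene sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .config import SimConfig
from .datasets import BulkCohort, SpotDataset

#: Home compartment of each default marker set.  Hepatocyte-program genes are
#: additionally given intermediate expression in "other" spots (those spots
#: are mixed tissue, not hepatocyte-free), which makes the niche the clear
#: low-hepatocyte extreme that percentile segmentation relies on.
_HOME_CLASS = {
    "hepatocyte": "hepatocyte",
    "lipid": "hepatocyte",
    "ecm": "niche",
    "mesenchyme": "niche",
    "cytoskeleton": "niche",
}

_CLASSES = ("niche", "hepatocyte", "other")


def _grow_blobs(rng, rows, cols, target, occupied, blob_size_range=None):
    """Mark ``target`` unoccupied grid cells via seeded contiguous growth.

    Blobs grow by repeatedly adding a random frontier cell (4-adjacency).
    Multiple blobs are grown until the target count is reached, so the
    compartment is contiguous locally but may consist of several patches.
    Returns a boolean (rows x cols) mask; ``occupied`` is not modified.
    """
    taken = occupied.copy()
    mask = np.zeros((rows, cols), dtype=bool)
    placed = 0
    while placed < target:
        free = np.flatnonzero(~taken)
        if free.size == 0:
            raise ValueError("grid too small to host requested fractions")
        if blob_size_range is None:
            size = target - placed
        else:
            lo, hi = blob_size_range
            size = min(int(rng.integers(lo, hi + 1)), target - placed)
        seed = int(rng.choice(free))
        frontier = [seed]
        grown = 0
        while frontier and grown < size:
            idx = frontier.pop(int(rng.integers(len(frontier))))
            r, c = divmod(idx, cols)
            if taken[r, c]:
                continue
            taken[r, c] = True
            mask[r, c] = True
            grown += 1
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= rr < rows and 0 <= cc < cols and not taken[rr, cc]:
                    frontier.append(rr * cols + cc)
        placed += grown
    return mask


def _build_gene_table(config: SimConfig, rng) -> tuple[pd.Index, pd.DataFrame, np.ndarray]:
    """Gene axis, metadata and per-class relative expression (G x 3)."""
    sets = config.resolved_marker_sets()
    gene_ids: list[str] = []
    marker_set: list[str] = []
    for name, ids in sets.items():
        gene_ids.extend(ids)
        marker_set.extend([name] * len(ids))
    n_other = config.n_genes - len(gene_ids)
    gene_ids.extend(f"OTH{i:04d}" for i in range(1, n_other + 1))
    marker_set.extend(["none"] * n_other)
    genes = pd.Index(gene_ids, name="gene")

    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    marker_set_arr = np.array(marker_set)
    bg = marker_set_arr == "background"
    if bg.any():
        # background probes: well below a tenth of the global median signal
        base[bg] = (np.median(base) / 20.0) * rng.lognormal(0.0, 0.2, bg.sum())

    rel = np.tile(base[:, None], (1, 3))  # columns ordered as _CLASSES
    fold = config.marker_fold
    for set_name, home in _HOME_CLASS.items():
        members = marker_set_arr == set_name
        if not members.any():
            continue
        j = _CLASSES.index(home)
        rel[members, j] *= fold
        if home == "hepatocyte":
            rel[members, _CLASSES.index("other")] *= np.sqrt(fold)
    # per-class composition: relative expression sums to 1 in each class
    rel /= rel.sum(axis=0, keepdims=True)

    panel = np.ones(config.n_genes, dtype=bool)
    unannotated = np.flatnonzero(marker_set_arr == "none")
    n_off = int(round(config.panel_exclude_fraction * unannotated.size))
    if n_off:
        panel[rng.choice(unannotated, size=n_off, replace=False)] = False
    gene_meta = pd.DataFrame(
        {
            "marker_set": marker_set_arr,
            "panel_member": panel,
            "background_probe": bg,
            "composite": False,
        },
        index=genes,
    )
    return genes, gene_meta, rel


def generate_spot_dataset(config: SimConfig) -> SpotDataset:
    """Generate a deterministic synthetic spot dataset from ``config``."""
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed, "spots"))
    genes, gene_meta, rel = _build_gene_table(config, rng)

    rows, cols = config.grid_rows, config.grid_cols
    n_spots = rows * cols
    theta = config.dispersion

    all_counts = []
    meta_rows = []
    for s in range(1, config.n_samples + 1):
        sample_id = f"S{s}"
        jn = config.niche_fraction_jitter
        jh = config.hepatocyte_fraction_jitter
        niche_target = int(round(
            n_spots * config.niche_fraction * rng.uniform(1 - jn, 1 + jn)
        ))
        hep_target = int(round(
            n_spots * config.hepatocyte_fraction * rng.uniform(1 - jh, 1 + jh)
        ))
        occupied = np.zeros((rows, cols), dtype=bool)
        niche_mask = _grow_blobs(
            rng, rows, cols, niche_target, occupied, blob_size_range=(10, 40)
        )
        hep_mask = _grow_blobs(rng, rows, cols, hep_target, occupied | niche_mask)
        labels = np.full((rows, cols), "other", dtype=object)
        labels[niche_mask] = "niche"
        labels[hep_mask] = "hepatocyte"
        labels_flat = labels.ravel()
        class_idx = np.array([_CLASSES.index(c) for c in labels_flat])

        depth = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, n_spots)
        mu = rel[:, class_idx] * depth[None, :]
        counts = rng.negative_binomial(n=theta, p=theta / (theta + mu))
        all_counts.append(counts)
        rr, cc = np.divmod(np.arange(n_spots), cols)
        for i in range(n_spots):
            meta_rows.append(
                (f"{sample_id}_r{rr[i]}_c{cc[i]}", sample_id, int(rr[i]), int(cc[i]),
                 labels_flat[i])
            )

    spot_meta = pd.DataFrame(
        meta_rows, columns=["spot_id", "sample_id", "row", "col", "true_class"]
    ).set_index("spot_id")
    return SpotDataset(
        counts=np.concatenate(all_counts, axis=1).astype(np.int64),
        genes=genes,
        spot_meta=spot_meta,
        gene_meta=gene_meta,
        spot_diameter_um=config.spot_diameter_um,
        spot_spacing_um=config.spot_spacing_um,
    )


def generate_bulk_cohort(config: SimConfig) -> BulkCohort:
    """Generate the bulk fibrosis cohort with planted gene-set effects.

    Expected counts: mu_gj = depth_j * rel_g * 2^(effects), where a planted
    set with signed log2FC d is multiplied by 2^d in progressors and 2^-d in
    regressors, and ECM/mesenchyme genes additionally scale with fibrosis
    stage (a known confounder the screen must adjust away).
    """
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed, "bulk"))
    sets = config.resolved_marker_sets()

    gene_ids: list[str] = []
    marker_set: list[str] = []
    for name, ids in sets.items():
        gene_ids.extend(ids)
        marker_set.extend([name] * len(ids))
    n_other = config.n_genes - len(gene_ids)
    gene_ids.extend(f"OTH{i:04d}" for i in range(1, n_other + 1))
    marker_set.extend(["none"] * n_other)
    genes = pd.Index(gene_ids, name="gene")
    marker_arr = np.array(marker_set)

    rel = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    rel /= rel.sum()

    groups, stages, nas = [], [], []
    for grp, n in config.bulk_n_per_group.items():
        if n < 1:
            raise ValueError(f"group {grp!r} must have at least one subject")
        groups.extend([grp] * n)
        stages.extend(rng.choice(["F1", "F2", "F3", "F4"], size=n,
                                 p=[0.30, 0.35, 0.25, 0.10]))
        nas.extend(np.clip(rng.poisson(4.0, size=n), 0, 8))
    n_subj = len(groups)
    subject_meta = pd.DataFrame(
        {"group": groups, "fibrosis_stage": stages, "NAS": np.array(nas, int)},
        index=pd.Index([f"P{i:03d}" for i in range(1, n_subj + 1)], name="subject"),
    )

    log2fc = np.zeros((config.n_genes, n_subj))
    grp_arr = subject_meta["group"].to_numpy()
    for set_name, delta in config.bulk_effect_log2fc.items():
        members = marker_arr == set_name
        log2fc[np.ix_(members, grp_arr == "progressor")] += delta
        log2fc[np.ix_(members, grp_arr == "regressor")] -= delta
    stage_step = subject_meta["fibrosis_stage"].str[1].astype(int).to_numpy() - 1
    fibro = np.isin(marker_arr, ["ecm", "mesenchyme"])
    log2fc[fibro, :] += config.bulk_stage_log2fc * stage_step[None, :]

    depth = rng.lognormal(config.bulk_libsize_log_mean,
                          config.bulk_libsize_log_sd, n_subj)
    mu = rel[:, None] * depth[None, :] * np.exp2(log2fc)
    theta = config.bulk_dispersion
    counts = rng.negative_binomial(n=theta, p=theta / (theta + mu))
    return BulkCohort(counts=counts.astype(np.int64), genes=genes,
                      subject_meta=subject_meta)
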