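"""Synthetic GeoMx-like ROI datasets from spot populations.

A GeoMx region of illumination (ROI) with a larger diameter than a 55 µm
spot is mimicked by summing counts over neighbouring same-class spots: the
diameter-area relationship is quadratic, so 80 / 110 / 165 µm ROIs aggregate
2 / 4 / 9 spots.  ROIs are drawn with replacement from the fixed spot
population (population-resampling semantics) and randomly partitioned into
synthetic patients; no patient-level effect is planted, consistent with the
observed exchangeability of spots across patients in reference data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import half_up
from .config import Condition, DropoutSpec
from .datasets import ROIDataset, SpotDataset
from .discovery import SegmentationResult


def diameter_to_spot_count(diameter_um: float, base_diameter_um: float = 55.0) -> int:
    """Number of base-diameter spots whose area matches a larger ROI diameter.

    k = round((d / base)^2); 80, 110 and 165 µm map to 2, 4 and 9 spots.
    """
    if diameter_um < base_diameter_um:
        raise ValueError(
            f"ROI diameter {diameter_um} µm is below the base spot diameter "
            f"{base_diameter_um} µm"
        )
    return half_up((diameter_um / base_diameter_um) ** 2)


def restrict_to_class(
    spots: SpotDataset, labels: SegmentationResult, tissue_class: str
) -> SpotDataset:
    """Subset a spot dataset to one segmented tissue class (an ROI pool)."""
    lab = labels.labels.reindex(spots.spot_meta.index)
    mask = (lab == tissue_class).to_numpy()
    if not mask.any():
        raise ValueError(f"no spots of class {tissue_class!r}")
    pool = spots.subset_spots(mask)
    pool.spot_meta = pool.spot_meta.assign(tissue_class=tissue_class)
    return pool


class _PoolSampler:
    """Draw grid-contiguous k-spot patches from a class-restricted pool."""

    def __init__(self, pool: SpotDataset, k: int):
        self.pool = pool
        self.k = k
        self.by_sample = {}
        meta = pool.spot_meta
        for s, sub in meta.groupby("sample_id", sort=False):
            if len(sub) >= k:
                coords = sub[["row", "col"]].to_numpy()
                pos = pool.spot_meta.index.get_indexer(sub.index)
                local_map = {tuple(rc): i for i, rc in enumerate(coords)}
                self.by_sample[s] = (pos, coords, local_map)
        if not self.by_sample:
            raise ValueError(
                f"no sample contains {k} spots of class "
                f"{meta['tissue_class'].iat[0] if 'tissue_class' in meta else '?'}"
            )
        self.samples = list(self.by_sample)

    def draw(self, rng) -> tuple[str, np.ndarray]:
        """One ROI: sample id and the column indexes of its k spots."""
        s = self.samples[int(rng.integers(len(self.samples)))]
        pos, coords, local_map = self.by_sample[s]
        seed_i = int(rng.integers(len(pos)))
        chosen = [seed_i]
        chosen_set = {seed_i}
        frontier = [seed_i]
        while len(chosen) < self.k and frontier:
            i = frontier.pop(int(rng.integers(len(frontier))))
            r, c = coords[i]
            for rc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                j = local_map.get(rc)
                if j is not None and j not in chosen_set:
                    chosen.append(j)
                    chosen_set.add(j)
                    frontier.append(j)
                    if len(chosen) == self.k:
                        break
        if len(chosen) < self.k:
            # thin classes: fall back to the k nearest class spots by grid
            # distance from the seed
            d2 = ((coords - coords[seed_i]) ** 2).sum(axis=1)
            order = np.argsort(d2, kind="stable")
            chosen = list(order[: self.k])
        return s, pos[np.asarray(chosen)]


def sample_rois(
    pool: SpotDataset, k: int, n_rois: int, rng
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw ``n_rois`` ROIs of ``k`` aggregated spots from a one-class pool.

    Each ROI sums counts over k distinct same-sample spots forming a
    grid-adjacent patch when possible (falling back to the k nearest class
    spots); spot reuse across ROIs is allowed.  Returns the genes x n_rois
    count matrix and a provenance frame (source sample, spot ids).
    """
    sampler = _PoolSampler(pool, k)
    counts = np.empty((pool.n_genes, n_rois), dtype=np.int64)
    prov = []
    for i in range(n_rois):
        s, cols = sampler.draw(rng)
        counts[:, i] = pool.counts[:, cols].sum(axis=1)
        prov.append((s, tuple(pool.spot_meta.index[cols])))
    return counts, pd.DataFrame(prov, columns=["source_sample_id", "spot_ids"])


def assemble_dataset(
    cond: Condition,
    pool_control: SpotDataset,
    pool_spiked: SpotDataset,
    rng,
) -> ROIDataset:
    """Build one synthetic two-group ROI dataset for a grid condition.

    Control-group ROIs come from the unmodified pool, spiked-group ROIs from
    the spiked pool; freshly drawn ROIs are randomly partitioned into
    patients with exactly ``n_rois_per_patient`` each.  Genes are restricted
    to the measurement panel, always keeping the endpoint gene and the
    background probes.
    """
    if not pool_control.genes.equals(pool_spiked.genes):
        raise ValueError("pools must share the gene axis")
    k = diameter_to_spot_count(cond.roi_diameter_um,
                               pool_control.spot_diameter_um)
    n_per_group = cond.n_patients_per_group * cond.n_rois_per_patient

    blocks, meta_rows = [], []
    for group, pool in (("control", pool_control), ("spiked", pool_spiked)):
        counts, prov = sample_rois(pool, k, n_per_group, rng)
        blocks.append(counts)
        order = rng.permutation(n_per_group)
        patient_of = np.empty(n_per_group, dtype=object)
        for p in range(cond.n_patients_per_group):
            sl = order[p * cond.n_rois_per_patient:(p + 1) * cond.n_rois_per_patient]
            patient_of[sl] = f"{group[0].upper()}{p + 1:02d}"
        for i in range(n_per_group):
            meta_rows.append(
                (patient_of[i], group, prov.loc[i, "source_sample_id"])
            )

    counts = np.concatenate(blocks, axis=1)
    tissue_class = cond.spike.target_class
    roi_meta = pd.DataFrame(
        meta_rows, columns=["patient_id", "group", "source_sample_id"],
        index=pd.Index([f"ROI{i + 1:04d}" for i in range(2 * n_per_group)],
                       name="roi_id"),
    )
    roi_meta["tissue_class"] = tissue_class
    roi_meta["diameter_um"] = cond.roi_diameter_um
    roi_meta["n_spots_aggregated"] = k

    gm = pool_control.gene_meta
    keep = (
        gm["panel_member"].to_numpy()
        | gm["background_probe"].to_numpy()
        | (pool_control.genes == cond.spike.gene)
    )
    return ROIDataset(
        counts=counts[keep], genes=pool_control.genes[keep],
        roi_meta=roi_meta, gene_meta=gm.loc[keep],
    )


def apply_dropout(ds: ROIDataset, spec: DropoutSpec) -> ROIDataset:
    """Remove a uniformly random set of ROIs, rejection-sampled so that no
    patient loses all of its ROIs."""
    n = ds.n_rois
    if spec.n_remove == 0:
        return ds
    if spec.n_remove >= n:
        raise ValueError("n_remove must be smaller than the number of ROIs")
    patients = ds.roi_meta["patient_id"].to_numpy()
    n_patients = len(pd.unique(patients))
    if n - spec.n_remove < n_patients:
        raise ValueError(
            f"removing {spec.n_remove} of {n} ROIs cannot leave every one of "
            f"{n_patients} patients with an ROI"
        )
    rng = np.random.default_rng(spec.seed)
    for _ in range(100000):
        drop = rng.choice(n, size=spec.n_remove, replace=False)
        keep = np.ones(n, dtype=bool)
        keep[drop] = False
        if len(set(patients[keep])) == n_patients:
            return ds.subset_rois(keep)
    raise ValueError("could not satisfy the dropout constraint")


def sum_gene_set(ds, gene_set, name: str) -> "ROIDataset | SpotDataset":
    """Append a composite gene: the column-wise raw-count sum of a gene set.

    Works for both ROI and spot datasets; member genes are retained and the
    composite is flagged (``composite=True``, off the panel) so library-size
    computations can exclude it.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene set must be non-empty")
    missing = [g for g in gene_set if g not in ds.genes]
    if missing:
        raise KeyError(f"genes not in dataset: {missing[:5]}")
    idx = ds.genes.get_indexer(gene_set)
    composite = ds.counts[idx].sum(axis=0, keepdims=True)
    counts = np.concatenate([ds.counts, composite], axis=0)
    genes = ds.genes.append(pd.Index([name]))
    extra = pd.DataFrame(
        {"marker_set": "composite", "panel_member": False,
         "background_probe": False, "composite": True},
        index=pd.Index([name], name="gene"),
    )
    gene_meta = pd.concat([ds.gene_meta, extra])
    if isinstance(ds, ROIDataset):
        return ROIDataset(counts=counts, genes=genes, roi_meta=ds.roi_meta,
                          gene_meta=gene_meta)
    return SpotDataset(
        counts=counts, genes=genes, spot_meta=ds.spot_meta, gene_meta=gene_meta,
        spot_diameter_um=ds.spot_diameter_um, spot_spacing_um=ds.spot_spacing_um,
    )
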