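"""Configuration objects for the simulation and power-analysis pipeline.

All configs are plain dataclasses that round-trip through JSON
(`to_dict` / `from_dict`) so runs can be described by a single structured
file and reproduced from it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

#: Marker-set sizes used when no explicit gene lists are supplied.  The lipid
#: (44 genes) and cytoskeleton (89 genes) sizes match the two endpoint gene
#: sets of the liver-fibrosis study design this package emulates; the first
#: member of each is named after its representative endpoint gene.
DEFAULT_MARKER_SIZES = {
    "hepatocyte": 30,
    "ecm": 30,
    "mesenchyme": 20,
    "lipid": 44,
    "cytoskeleton": 89,
    "background": 50,
}

_SET_PREFIX = {
    "hepatocyte": "HEP",
    "ecm": "ECM",
    "mesenchyme": "MES",
    "lipid": "LIP",
    "cytoskeleton": "CYT",
    "background": "BG",
}

#: Representative endpoint genes: PON1 stands in for the hepatocyte/lipid
#: signal, FLNA for the fibrotic-niche/cytoskeleton signal.
ENDPOINT_GENES = {"lipid": "PON1", "cytoskeleton": "FLNA"}


def default_marker_sets(sizes: Optional[dict] = None) -> dict:
    """Build named, pairwise-disjoint marker gene-id lists."""
    sizes = dict(DEFAULT_MARKER_SIZES if sizes is None else sizes)
    sets = {}
    for name, n in sizes.items():
        prefix = _SET_PREFIX.get(name, name[:3].upper())
        ids = [f"{prefix}{i:04d}" for i in range(1, n + 1)]
        if name in ENDPOINT_GENES:
            ids[0] = ENDPOINT_GENES[name]
        sets[name] = ids
    return sets


@dataclass
class SimConfig:
    """Parameters of the synthetic spot-level and bulk-cohort generators.

    The defaults describe the study conditions the downstream power analysis
    assumes: 5 tissue samples on a spot grid (55 µm spots, 100 µm centre
    spacing), a fibrotic-niche compartment near 5% of spots (per-sample
    jitter keeps realizations inside the 2.6–7.1% range), a hepatocyte
    compartment near 65.5% (realized 63–68%), log-normal per-spot library
    sizes, NB(θ) counts, and a bulk cohort of 28 stable / 15 progressor /
    15 regressor subjects with opposite-direction planted gene-set effects.
    """

    seed: int = 0
    # --- spot-level ---
    n_samples: int = 5
    grid_rows: int = 60
    grid_cols: int = 60
    n_genes: int = 1000
    niche_fraction: float = 0.05
    hepatocyte_fraction: float = 0.655
    niche_fraction_jitter: float = 0.15
    hepatocyte_fraction_jitter: float = 0.04
    libsize_log_mean: float = math.log(5000.0)
    libsize_log_sd: float = 0.35
    dispersion: float = 2.0  # NB size parameter theta
    marker_fold: float = 4.0
    marker_sets: Optional[dict] = None  # name -> list of gene ids
    panel_exclude_fraction: float = 0.05  # unannotated genes off the panel
    spot_diameter_um: float = 55.0
    spot_spacing_um: float = 100.0
    # --- bulk cohort ---
    bulk_n_per_group: dict = field(
        default_factory=lambda: {"stable": 28, "progressor": 15, "regressor": 15}
    )
    # signed log2FC per planted gene set: progressors get +lfc, regressors -lfc
    bulk_effect_log2fc: dict = field(
        default_factory=lambda: {"lipid": -0.42, "cytoskeleton": 1.5}
    )
    bulk_stage_log2fc: float = 0.2  # per fibrosis-stage step, ECM/mesenchyme sets
    bulk_libsize_log_mean: float = math.log(2.0e6)
    bulk_libsize_log_sd: float = 0.25
    bulk_dispersion: float = 8.0

    def resolved_marker_sets(self) -> dict:
        return (
            default_marker_sets() if self.marker_sets is None else self.marker_sets
        )

    def validate(self) -> None:
        if self.niche_fraction < 0 or self.hepatocyte_fraction < 0:
            raise ValueError("compartment fractions must be non-negative")
        if self.niche_fraction + self.hepatocyte_fraction > 1:
            raise ValueError(
                "niche_fraction + hepatocyte_fraction must not exceed 1"
            )
        for name in ("n_samples", "grid_rows", "grid_cols", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dispersion <= 0 or self.bulk_dispersion <= 0:
            raise ValueError("dispersion (NB size) must be > 0")
        if not (0 <= self.niche_fraction_jitter <= 0.2):
            raise ValueError("niche_fraction_jitter must lie in [0, 0.2]")
        if not (0 <= self.hepatocyte_fraction_jitter <= 0.2):
            raise ValueError("hepatocyte_fraction_jitter must lie in [0, 0.2]")
        sets = self.resolved_marker_sets()
        seen: dict = {}
        for name, ids in sets.items():
            for g in ids:
                if g in seen:
                    raise ValueError(
                        f"marker sets must be pairwise disjoint: gene {g!r} "
                        f"appears in both {seen[g]!r} and {name!r}"
                    )
                seen[g] = name
        n_marker = len(seen)
        if n_marker > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {n_marker} marker genes"
            )
        n_spots = self.grid_rows * self.grid_cols
        hi_niche = self.niche_fraction * (1 + self.niche_fraction_jitter)
        hi_hep = self.hepatocyte_fraction * (1 + self.hepatocyte_fraction_jitter)
        if self.niche_fraction > 0 and round(n_spots * self.niche_fraction) < 1:
            raise ValueError(
                "grid too small to host the requested niche fraction: "
                f"{n_spots} spots x {self.niche_fraction} < 1 spot"
            )
        if hi_niche + hi_hep > 1:
            raise ValueError(
                "compartment fractions plus jitter may exceed the grid; "
                "reduce fractions or jitter"
            )
        for grp, n in self.bulk_n_per_group.items():
            if n < 1:
                raise ValueError(f"bulk group {grp!r} must have >= 1 subject")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class SpikeSpec:
    """Additive spike-in: each target-class spot of sample i gains
    r x median(gene counts over target-class spots of sample i)."""

    gene: str
    r: float
    target_class: str  # "niche" or "hepatocyte"

    def __post_init__(self):
        if self.r < 0:
            raise ValueError("spike-in fraction r must be >= 0")
        if self.target_class not in ("niche", "hepatocyte"):
            raise ValueError("target_class must be 'niche' or 'hepatocyte'")


#: ROI diameters (µm) evaluated in the simulation design.
SUPPORTED_DIAMETERS = (80.0, 110.0, 165.0)


@dataclass
class Condition:
    """One cell of the simulation grid."""

    endpoint: str  # "primary" or "secondary"
    n_patients_per_group: int
    n_rois_per_patient: int
    roi_diameter_um: float
    spike: SpikeSpec

    def __post_init__(self):
        if self.n_patients_per_group < 2:
            raise ValueError("n_patients_per_group must be >= 2")
        if self.n_rois_per_patient < 1:
            raise ValueError("n_rois_per_patient must be >= 1")
        if float(self.roi_diameter_um) not in SUPPORTED_DIAMETERS:
            raise ValueError(
                f"roi_diameter_um must be one of {SUPPORTED_DIAMETERS}"
            )

    def key(self) -> str:
        """Stable identifier used for per-cell seed derivation."""
        return (
            f"{self.endpoint}|{self.n_patients_per_group}|"
            f"{self.n_rois_per_patient}|{self.roi_diameter_um}|"
            f"{self.spike.gene}|{self.spike.r}|{self.spike.target_class}"
        )


@dataclass
class DropoutSpec:
    """Remove ROIs at random without fully depleting any patient."""

    n_remove: int
    seed: int = 0

    def __post_init__(self):
        if self.n_remove < 0:
            raise ValueError("n_remove must be >= 0")


@dataclass
class RunConfig:
    """Settings of a power run.

    ``alpha`` defaults to 0.025, i.e. 0.05 split over two endpoints.
    """

    alpha: float = 0.025
    n_reps: int = 100
    methods: tuple = ("wald_glmm",)
    seed: int = 0
    target_power: float = 0.8
    count_nonconverged_as_failures: bool = False
    plugin: Optional[Callable] = None  # (y, group, patient, offset) -> TestResult

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        known = {"wald_glmm", "lrt_glmm", "plugin"}
        for m in self.methods:
            if m not in known:
                raise ValueError(f"unknown method {m!r}; choose from {sorted(known)}")
        if "plugin" in self.methods and self.plugin is None:
            raise ValueError("method 'plugin' requires a plugin callable")


def load_json_config(path, cls):
    with open(path) as fh:
        return cls.from_dict(json.load(fh))
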