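"""Endpoint discovery: normalization, candidate screen, summary scores,
co-localization and percentile segmentation of spots into compartments.

The normalization is a depth-corrected log transform, log2(count/sf + 1)
with median-of-ratios size factors — a deliberately simple stand-in that
preserves the log-scale, depth-corrected semantics the downstream screen
and scores need.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import SpotDataset


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormalizedMatrix:
    """log2((count / size_factor) + pseudocount), genes x columns."""

    values: np.ndarray
    genes: pd.Index
    columns: pd.Index
    size_factors: np.ndarray
    pseudocount: float


def median_of_ratios_size_factors(
    counts: np.ndarray, method: str = "median_of_ratios"
) -> np.ndarray:
    """Per-column size factors: median of ratios to per-gene geometric means.

    With the default method only genes with nonzero counts in every column
    contribute, as in the standard median-of-ratios estimator.  For sparse
    matrices (spot resolution) where no such gene exists, ``"poscounts"``
    computes geometric means over the positive counts of each gene and takes
    per-column medians over that column's positive entries.
    """
    counts = np.asarray(counts, dtype=float)
    if method == "median_of_ratios":
        expressed = (counts > 0).all(axis=1)
        if not expressed.any():
            raise ValueError(
                "no gene has nonzero counts in all columns; filter "
                "low-coverage genes or columns before computing size "
                "factors, or use the 'poscounts' method"
            )
        logc = np.log(counts[expressed])
        log_geo = logc.mean(axis=1, keepdims=True)
        return np.exp(np.median(logc - log_geo, axis=0))
    if method == "poscounts":
        pos = counts > 0
        any_pos = pos.any(axis=1)
        counts = counts[any_pos]
        pos = pos[any_pos]
        with np.errstate(divide="ignore"):
            logc = np.where(pos, np.log(counts), 0.0)
        log_geo = logc.sum(axis=1) / pos.sum(axis=1)
        ratios = np.where(pos, logc - log_geo[:, None], np.nan)
        sf = np.exp(np.nanmedian(ratios, axis=0))
        if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
            raise ValueError("poscounts size factors undefined for a column "
                             "with no positive counts")
        return sf
    raise ValueError(f"unknown size-factor method {method!r}")


def normalize_counts(
    counts: np.ndarray,
    pseudocount: float = 1.0,
    genes: Optional[pd.Index] = None,
    columns: Optional[pd.Index] = None,
    size_factor_method: str = "median_of_ratios",
) -> NormalizedMatrix:
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    counts = np.asarray(counts, dtype=float)
    sf = median_of_ratios_size_factors(counts, method=size_factor_method)
    values = np.log2(counts / sf[None, :] + pseudocount)
    genes = pd.Index(range(counts.shape[0])) if genes is None else pd.Index(genes)
    columns = (
        pd.Index(range(counts.shape[1])) if columns is None else pd.Index(columns)
    )
    return NormalizedMatrix(values, genes, columns, sf, pseudocount)


# ---------------------------------------------------------------------------
# candidate gene screen


def candidate_gene_screen(
    norm: NormalizedMatrix,
    subject_meta: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene OLS of normalized expression on outcome group + fibrosis stage.

    One model per gene with two treatment contrasts against the stable group;
    a gene is selected when its progressor and regressor log2FCs point in
    opposite directions and both raw p-values are below ``alpha``.
    Returns a DataFrame indexed by gene with columns lfc_prog, lfc_regr,
    p_prog, p_regr, selected, direction.
    """
    meta = subject_meta
    for grp in ("stable", "progressor", "regressor"):
        if (meta["group"] == grp).sum() < 2:
            raise ValueError(f"need >= 2 subjects in group {grp!r}")
    if "fibrosis_stage" not in meta.columns:
        raise ValueError("subject_meta must carry fibrosis_stage")

    n = len(meta)
    prog = (meta["group"] == "progressor").to_numpy(float)
    regr = (meta["group"] == "regressor").to_numpy(float)
    stage_d = pd.get_dummies(meta["fibrosis_stage"], drop_first=True).to_numpy(float)
    X = np.column_stack([np.ones(n), prog, regr, stage_d])
    rank = np.linalg.matrix_rank(X)
    Y = norm.values  # genes x subjects

    if rank < X.shape[1]:
        warnings.warn("rank-deficient screen design; results flagged as NA")
        out = pd.DataFrame(
            {
                "lfc_prog": np.nan,
                "lfc_regr": np.nan,
                "p_prog": np.nan,
                "p_regr": np.nan,
                "selected": False,
                "direction": pd.NA,
            },
            index=norm.genes,
        )
        return out

    pinv = np.linalg.pinv(X)
    B = Y @ pinv.T  # genes x p
    resid = Y - B @ X.T
    dof = n - X.shape[1]
    sigma2 = (resid**2).sum(axis=1) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    with np.errstate(invalid="ignore", divide="ignore"):
        se_prog = np.sqrt(sigma2 * xtx_inv[1, 1])
        se_regr = np.sqrt(sigma2 * xtx_inv[2, 2])
        t_prog = B[:, 1] / se_prog
        t_regr = B[:, 2] / se_regr
    p_prog = 2 * stats.t.sf(np.abs(t_prog), dof)
    p_regr = 2 * stats.t.sf(np.abs(t_regr), dof)

    opposite = np.sign(B[:, 1]) * np.sign(B[:, 2]) < 0
    selected = opposite & (p_prog < alpha) & (p_regr < alpha)
    direction = np.where(B[:, 1] > 0, "up_in_progressors", "up_in_regressors")
    out = pd.DataFrame(
        {
            "lfc_prog": B[:, 1],
            "lfc_regr": B[:, 2],
            "p_prog": p_prog,
            "p_regr": p_regr,
            "selected": selected,
            "direction": direction,
        },
        index=norm.genes,
    )
    out.loc[~selected, "direction"] = pd.NA
    return out


# ---------------------------------------------------------------------------
# summary scores


@dataclass
class SummaryScore:
    gene_set_name: str
    retained_genes: list
    values: np.ndarray  # one value per column of the normalized matrix
    columns: pd.Index
    corr_threshold: float


def _row_corr(values: np.ndarray, ref: np.ndarray, method: str) -> np.ndarray:
    """Correlation of each row of ``values`` with ``ref`` (NaN if undefined)."""
    if method == "spearman":
        values = stats.rankdata(values, axis=1)
        ref = stats.rankdata(ref)
    vc = values - values.mean(axis=1, keepdims=True)
    rc = ref - ref.mean()
    denom = np.sqrt((vc**2).sum(axis=1) * (rc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (vc @ rc) / denom


def kuppe_score(
    norm: NormalizedMatrix,
    gene_set: Sequence[str],
    corr_threshold: float = 0.1,
    name: str = "score",
    method: str = "pearson",
) -> SummaryScore:
    """Gene-set summary score: mean normalized expression after one
    filter-and-update pass.

    The initial score is the plain mean over the set; member genes whose
    correlation with that mean is below ``corr_threshold`` are dropped and
    the mean recomputed once.  Genes with undefined correlation (constant
    rows) are retained, since no evidence of poor correlation exists.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    missing = [g for g in gene_set if g not in norm.genes]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    idx = norm.genes.get_indexer(gene_set)
    values = norm.values[idx]
    initial = values.mean(axis=0)
    corr = _row_corr(values, initial, method)
    keep = ~(corr < corr_threshold)  # NaN compares False -> retained
    if not keep.any():
        raise ValueError(
            f"all genes of set {name!r} filtered at corr_threshold="
            f"{corr_threshold}"
        )
    retained = [g for g, k in zip(gene_set, keep) if k]
    score = values[keep].mean(axis=0)
    return SummaryScore(name, retained, score, norm.columns, corr_threshold)


def score_association(score: SummaryScore, subject_meta: pd.DataFrame):
    """OLS of a summary score on group + fibrosis stage + NAS.

    Returns (group_table, fitted_results): the table holds the progressor
    and regressor coefficients versus the stable group with SEs and p-values.
    """
    import statsmodels.formula.api as smf

    y = np.asarray(score.values, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("score is constant; association model is undefined")
    df = subject_meta.copy()
    df["score"] = y
    model = smf.ols(
        "score ~ C(group, Treatment('stable')) + C(fibrosis_stage) + NAS", data=df
    )
    res = model.fit()
    rows = {}
    for grp in ("progressor", "regressor"):
        term = f"C(group, Treatment('stable'))[T.{grp}]"
        rows[grp] = {
            "coef": res.params[term],
            "se": res.bse[term],
            "p": res.pvalues[term],
        }
    return pd.DataFrame(rows).T, res


def colocalize_scores(
    score_a: SummaryScore,
    score_b: SummaryScore,
    by_sample: Optional[pd.Series] = None,
):
    """Spearman correlation of two aligned summary scores.

    With ``by_sample`` (a per-column sample label series aligned to the score
    columns) the correlation is computed within each sample separately,
    mirroring per-sample co-localization across the tissue area.
    """
    a = np.asarray(score_a.values, float)
    b = np.asarray(score_b.values, float)
    if a.shape != b.shape:
        raise ValueError("scores must share their column axis")

    def _rho(x, y):
        if len(x) < 3:
            warnings.warn("fewer than 3 observations; Spearman rho undefined")
            return np.nan
        return stats.spearmanr(x, y).statistic

    if by_sample is None:
        return _rho(a, b)
    by_sample = np.asarray(by_sample)
    return pd.Series(
        {s: _rho(a[by_sample == s], b[by_sample == s]) for s in pd.unique(by_sample)}
    )


# ---------------------------------------------------------------------------
# segmentation


@dataclass
class SegmentationParams:
    ecm_hi_pct: float = 85.0
    hep_lo_pct: float = 15.0
    hep_hi_pct: float = 20.0
    ecm_lo_pct: float = 80.0


@dataclass
class SegmentationResult:
    labels: pd.Series  # per spot: niche / hepatocyte / other
    params: SegmentationParams
    thresholds_used: pd.DataFrame  # per sample: ecm_hi, hep_lo, hep_hi, ecm_lo


def segment_spots(
    spots: SpotDataset,
    hep_score: SummaryScore,
    ecm_score: SummaryScore,
    params: Optional[SegmentationParams] = None,
) -> SegmentationResult:
    """Percentile segmentation of spots into fibrotic niche / hepatocyte / other.

    Per sample: niche spots are at or above the 85th ECM-score percentile and
    at or below the 15th hepatocyte-score percentile; hepatocyte spots are at
    or above the 20th hepatocyte percentile and at or below the 80th ECM
    percentile.  Ties at a threshold are included.  When both scores are
    constant within a sample the niche conjunction is unsatisfiable by
    convention and the sample yields no niche spots.
    """
    params = params or SegmentationParams()
    if len(hep_score.values) != spots.n_spots or len(ecm_score.values) != spots.n_spots:
        raise ValueError("scores must be computed on the same spots")
    hep = np.asarray(hep_score.values, float)
    ecm = np.asarray(ecm_score.values, float)
    sample = spots.spot_meta["sample_id"].to_numpy()

    labels = np.full(spots.n_spots, "other", dtype=object)
    thr_rows = {}
    for s in pd.unique(sample):
        m = sample == s
        h, e = hep[m], ecm[m]
        ecm_hi = np.percentile(e, params.ecm_hi_pct)
        hep_lo = np.percentile(h, params.hep_lo_pct)
        hep_hi = np.percentile(h, params.hep_hi_pct)
        ecm_lo = np.percentile(e, params.ecm_lo_pct)
        thr_rows[s] = {"ecm_hi": ecm_hi, "hep_lo": hep_lo,
                       "hep_hi": hep_hi, "ecm_lo": ecm_lo}
        if np.ptp(e) == 0 and np.ptp(h) == 0:
            niche = np.zeros(m.sum(), dtype=bool)
        else:
            niche = (e >= ecm_hi) & (h <= hep_lo)
        hepat = (h >= hep_hi) & (e <= ecm_lo) & ~niche
        lab = np.full(m.sum(), "other", dtype=object)
        lab[niche] = "niche"
        lab[hepat] = "hepatocyte"
        if not niche.any():
            warnings.warn(f"sample {s!r}: empty fibrotic niche")
        labels[m] = lab

    return SegmentationResult(
        labels=pd.Series(labels, index=spots.spot_meta.index, name="label"),
        params=params,
        thresholds_used=pd.DataFrame(thr_rows).T,
    )
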