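"""Normalization, candidate screen, summary scores, segmentation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stpower.config import SimConfig, default_marker_sets
from stpower.discovery import (
    NormalizedMatrix,
    SegmentationParams,
    candidate_gene_screen,
    colocalize_scores,
    kuppe_score,
    median_of_ratios_size_factors,
    normalize_counts,
    score_association,
    segment_spots,
)
from stpower.synth import generate_bulk_cohort


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([5, 10, 0, 3, 40])
        counts = np.tile(col[:, None], (1, 4))
        sf = median_of_ratios_size_factors(counts)
        np.testing.assert_allclose(sf, 1.0)

    def test_pairwise_scale_equivariance(self):
        """Column B = c x column A implies sf_B = c x sf_A: depth difference,
        not composition, is absorbed by the factors."""
        rng = np.random.default_rng(1)
        a = rng.poisson(20.0, size=100) + 1
        counts = np.column_stack([a, 3 * a, rng.poisson(20.0, size=100) + 1])
        sf = median_of_ratios_size_factors(counts)
        assert sf[1] / sf[0] == pytest.approx(3.0, rel=1e-12)

    def test_hand_computed_three_columns(self):
        counts = np.array([[1.0, 2.0, 4.0], [2.0, 4.0, 8.0], [10.0, 20.0, 40.0]])
        # all genes proportional: geometric mean g_i = cbrt(8) * x_i1, so the
        # ratio columns are exactly (1, 2, 4)/2 after geometric centring
        sf = median_of_ratios_size_factors(counts)
        np.testing.assert_allclose(sf, np.array([1.0, 2.0, 4.0]) / 2.0, rtol=1e-12)

    def test_all_zero_overlap_raises_and_suggests_poscounts(self):
        counts = np.array([[3, 0], [0, 7]])
        with pytest.raises(ValueError, match="poscounts"):
            median_of_ratios_size_factors(counts)

    def test_poscounts_matches_strict_method_on_dense_matrix(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(30.0, size=(200, 6)) + 1
        strict = median_of_ratios_size_factors(counts)
        pos = median_of_ratios_size_factors(counts, method="poscounts")
        np.testing.assert_allclose(pos, strict, rtol=1e-12)

    def test_poscounts_hand_example_with_zeros(self):
        counts = np.array([[4.0, 0.0], [2.0, 8.0]])
        # gene 1 positive only in col 0: geo mean 4, ratio col0 = 1
        # gene 2 positive in both: geo mean 4, ratios (1/2, 2)
        # col 0 median over {1, 1/2} = 0.75; col 1 median over {2} = 2
        sf = median_of_ratios_size_factors(counts, method="poscounts")
        np.testing.assert_allclose(sf, [np.exp(np.mean(np.log([1.0, 0.5]))), 2.0])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown size-factor method"):
            median_of_ratios_size_factors(np.ones((2, 2)), method="upperquartile")

    def test_normalize_counts_formula(self):
        counts = np.array([[1.0, 2.0], [3.0, 6.0]])
        norm = normalize_counts(counts, pseudocount=1.0)
        expected = np.log2(counts / norm.size_factors[None, :] + 1.0)
        np.testing.assert_allclose(norm.values, expected)
        with pytest.raises(ValueError, match="pseudocount"):
            normalize_counts(counts, pseudocount=0.0)


class TestCandidateScreen:
    @staticmethod
    def _norm(bulk):
        return normalize_counts(bulk.counts, genes=bulk.genes,
                                columns=bulk.subject_meta.index)

    @staticmethod
    def _membership(bulk):
        sets = default_marker_sets()
        member = pd.Series("none", index=bulk.genes)
        for name, ids in sets.items():
            member.loc[member.index.isin(ids)] = name
        return member

    def test_planted_sets_enriched_among_selected(self):
        cfg = SimConfig(seed=21, n_genes=400,
                        bulk_n_per_group={"stable": 60, "progressor": 40,
                                          "regressor": 40})
        bulk = generate_bulk_cohort(cfg)
        res = candidate_gene_screen(self._norm(bulk), bulk.subject_meta)
        member = self._membership(bulk)
        planted = member.isin(["lipid", "cytoskeleton"]).to_numpy()
        sel_planted = res.loc[planted, "selected"].mean()
        sel_null = res.loc[(member == "none").to_numpy(), "selected"].mean()
        assert sel_planted > 0.8
        # opposite-sign conjunction at alpha=0.05 twice: null rate well below 5%
        assert sel_null < 0.05
        cyt = res.loc[(member == "cytoskeleton").to_numpy()]
        assert (cyt.loc[cyt.selected, "direction"] == "up_in_progressors").all()
        lip = res.loc[(member == "lipid").to_numpy()]
        assert (lip.loc[lip.selected, "direction"] == "up_in_regressors").all()

    def test_matches_statsmodels_per_gene_ols(self, small_bulk):
        import statsmodels.formula.api as smf

        norm = self._norm(small_bulk)
        res = candidate_gene_screen(norm, small_bulk.subject_meta)
        rng = np.random.default_rng(3)
        for gi in rng.choice(len(norm.genes), 5, replace=False):
            df = small_bulk.subject_meta.copy()
            df["y"] = norm.values[gi]
            fit = smf.ols(
                "y ~ C(group, Treatment('stable')) + C(fibrosis_stage)", data=df
            ).fit()
            term = "C(group, Treatment('stable'))[T.progressor]"
            assert res["lfc_prog"].iloc[gi] == pytest.approx(fit.params[term],
                                                             rel=1e-8)
            assert res["p_prog"].iloc[gi] == pytest.approx(fit.pvalues[term],
                                                           rel=1e-6)

    def test_fibrosis_confounder_adjusted_away(self):
        """Genes that track fibrosis stage but not outcome group must not be
        selected: stage enters the screen design as a covariate."""
        cfg = SimConfig(seed=22, n_genes=400,
                        bulk_effect_log2fc={"lipid": 0.0, "cytoskeleton": 0.0},
                        bulk_stage_log2fc=0.6,
                        bulk_n_per_group={"stable": 60, "progressor": 40,
                                          "regressor": 40})
        bulk = generate_bulk_cohort(cfg)
        res = candidate_gene_screen(self._norm(bulk), bulk.subject_meta)
        member = self._membership(bulk)
        fibro = member.isin(["ecm", "mesenchyme"]).to_numpy()
        assert res.loc[fibro, "selected"].mean() < 0.1

    def test_tiny_group_rejected(self, small_bulk):
        keep = (small_bulk.subject_meta["group"] != "regressor").to_numpy()
        meta = small_bulk.subject_meta.loc[keep]
        norm = normalize_counts(small_bulk.counts[:, keep],
                                genes=small_bulk.genes, columns=meta.index)
        with pytest.raises(ValueError, match="regressor"):
            candidate_gene_screen(norm, meta)


class TestKuppeScore:
    def test_plain_mean_when_nothing_filtered(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=30)
        values = base[None, :] + rng.normal(scale=0.1, size=(5, 30))
        norm = NormalizedMatrix(values, pd.Index([f"g{i}" for i in range(5)]),
                                pd.Index(range(30)), np.ones(30), 1.0)
        score = kuppe_score(norm, [f"g{i}" for i in range(5)])
        assert score.retained_genes == [f"g{i}" for i in range(5)]
        np.testing.assert_allclose(score.values, values.mean(axis=0))

    def test_anticorrelated_member_dropped_once(self):
        rng = np.random.default_rng(5)
        base = np.linspace(0, 1, 40)
        good = base[None, :] + rng.normal(scale=0.05, size=(4, 40))
        bad = -base + rng.normal(scale=0.05, size=40)
        values = np.vstack([good, bad[None, :]])
        genes = pd.Index([f"g{i}" for i in range(5)])
        norm = NormalizedMatrix(values, genes, pd.Index(range(40)),
                                np.ones(40), 1.0)
        score = kuppe_score(norm, list(genes))
        assert score.retained_genes == [f"g{i}" for i in range(4)]
        np.testing.assert_allclose(score.values, good.mean(axis=0))

    def test_constant_gene_retained(self):
        rng = np.random.default_rng(6)
        values = np.vstack([np.linspace(0, 1, 20) + rng.normal(0, 0.05, 20),
                            np.linspace(0, 1, 20) + rng.normal(0, 0.05, 20),
                            np.full(20, 3.0)])
        genes = pd.Index(["a", "b", "const"])
        norm = NormalizedMatrix(values, genes, pd.Index(range(20)),
                                np.ones(20), 1.0)
        score = kuppe_score(norm, list(genes))
        assert "const" in score.retained_genes

    def test_all_filtered_raises(self):
        # two perfectly anti-correlated members: initial mean is constant-ish,
        # force the drop with a high threshold instead
        x = np.linspace(0, 1, 10)
        values = np.vstack([x, x[::-1]])
        norm = NormalizedMatrix(values, pd.Index(["a", "b"]),
                                pd.Index(range(10)), np.ones(10), 1.0)
        with pytest.raises(ValueError, match="filtered"):
            kuppe_score(norm, ["a", "b"], corr_threshold=1.01)

    def test_missing_gene_raises_keyerror(self):
        norm = NormalizedMatrix(np.ones((2, 3)), pd.Index(["a", "b"]),
                                pd.Index(range(3)), np.ones(3), 1.0)
        with pytest.raises(KeyError, match="nope"):
            kuppe_score(norm, ["a", "nope"])


class TestScoreAssociation:
    def test_recovers_planted_score_shift(self, small_bulk):
        rng = np.random.default_rng(7)
        meta = small_bulk.subject_meta
        y = rng.normal(size=len(meta)) + 2.0 * (meta["group"] == "progressor")
        from stpower.discovery import SummaryScore

        score = SummaryScore("s", ["g"], y.to_numpy(), meta.index, 0.1)
        table, res = score_association(score, meta)
        assert table.loc["progressor", "p"] < 1e-4
        assert table.loc["progressor", "coef"] == pytest.approx(2.0, abs=0.8)
        # NAS and stage are in the design
        assert any("NAS" in name for name in res.params.index)

    def test_constant_score_rejected(self, small_bulk):
        from stpower.discovery import SummaryScore

        meta = small_bulk.subject_meta
        score = SummaryScore("s", ["g"], np.ones(len(meta)), meta.index, 0.1)
        with pytest.raises(ValueError, match="constant"):
            score_association(score, meta)


class TestColocalization:
    def test_matches_scipy_spearman(self):
        from stpower.discovery import SummaryScore

        rng = np.random.default_rng(8)
        a = rng.normal(size=50)
        b = 0.5 * a + rng.normal(size=50)
        cols = pd.Index(range(50))
        rho = colocalize_scores(SummaryScore("a", [], a, cols, 0.1),
                                SummaryScore("b", [], b, cols, 0.1))
        assert rho == pytest.approx(stats.spearmanr(a, b).statistic)

    def test_per_sample_and_short_sample_nan(self):
        from stpower.discovery import SummaryScore

        rng = np.random.default_rng(9)
        a = rng.normal(size=22)
        b = rng.normal(size=22)
        by = pd.Series(["s1"] * 20 + ["s2"] * 2)
        cols = pd.Index(range(22))
        with pytest.warns(UserWarning, match="fewer than 3"):
            rho = colocalize_scores(SummaryScore("a", [], a, cols, 0.1),
                                    SummaryScore("b", [], b, cols, 0.1),
                                    by_sample=by)
        assert rho["s1"] == pytest.approx(
            stats.spearmanr(a[:20], b[:20]).statistic)
        assert np.isnan(rho["s2"])


class TestSegmentation:
    def test_recovers_true_classes(self, default_spots, default_segmentation):
        """Segmentation agrees with ground truth on >= 95% of true-niche
        spots.  Hepatocyte recall is structurally capped below that: the
        rule keeps only spots at or above the 20th within-sample hepatocyte
        percentile, and with hepatocytes near 65% of spots that cut removes
        a slice of genuine hepatocytes by construction."""
        truth = default_spots.spot_meta["true_class"]
        lab = default_segmentation.labels
        niche_recall = (lab[truth == "niche"] == "niche").mean()
        hep_recall = (lab[truth == "hepatocyte"] == "hepatocyte").mean()
        assert niche_recall >= 0.95
        assert hep_recall >= 0.80
        # and niche spots found are mostly genuine
        niche_precision = (truth[lab == "niche"] == "niche").mean()
        assert niche_precision >= 0.80

    def test_threshold_boundaries_inclusive(self, small_spots):
        """A spot exactly at the ECM 85th / hepatocyte 15th percentile is
        labelled niche (ties included)."""
        from stpower.discovery import SummaryScore

        n = small_spots.n_spots
        cols = small_spots.spot_meta.index
        rng = np.random.default_rng(10)
        # integer-valued scores force exact ties at the percentile thresholds
        hep = SummaryScore("h", [], rng.integers(0, 10, n).astype(float),
                           cols, 0.1)
        ecm = SummaryScore("e", [], rng.integers(0, 10, n).astype(float),
                           cols, 0.1)
        res = segment_spots(small_spots, hep, ecm)
        sample = small_spots.spot_meta["sample_id"].to_numpy()
        hit = 0
        for s, thr in res.thresholds_used.iterrows():
            m = sample == s
            e = np.asarray(ecm.values)[m]
            h = np.asarray(hep.values)[m]
            at_bound = (e == thr["ecm_hi"]) & (h <= thr["hep_lo"])
            if at_bound.any():
                hit += int(at_bound.sum())
                assert (res.labels[m][at_bound] == "niche").all()
        assert hit > 0

    def test_degenerate_constant_scores_yield_empty_niche(self, small_spots):
        from stpower.discovery import SummaryScore

        n = small_spots.n_spots
        cols = small_spots.spot_meta.index
        const = SummaryScore("c", [], np.zeros(n), cols, 0.1)
        with pytest.warns(UserWarning, match="empty fibrotic niche"):
            res = segment_spots(small_spots, const, const)
        assert (res.labels != "niche").all()

    def test_custom_percentiles_respected(self, small_spots, small_config):
        # a stricter niche definition selects a subset of the default niche
        sets = small_config.resolved_marker_sets()
        norm = normalize_counts(small_spots.counts, genes=small_spots.genes,
                                columns=small_spots.spot_meta.index,
                                size_factor_method="poscounts")
        hep = kuppe_score(norm, sets["hepatocyte"], name="hepatocyte")
        ecm = kuppe_score(norm, sets["ecm"], name="ecm")
        loose = segment_spots(small_spots, hep, ecm)
        strict = segment_spots(
            small_spots, hep, ecm,
            params=SegmentationParams(ecm_hi_pct=95.0, hep_lo_pct=5.0),
        )
        loose_n = set(loose.labels[loose.labels == "niche"].index)
        strict_n = set(strict.labels[strict.labels == "niche"].index)
        assert strict_n <= loose_n
        assert len(strict_n) < len(loose_n)

    def test_mismatched_scores_rejected(self, small_spots):
        from stpower.discovery import SummaryScore

        short = SummaryScore("s", [], np.zeros(3), pd.Index(range(3)), 0.1)
        with pytest.raises(ValueError, match="same spots"):
            segment_spots(small_spots, short, short)
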