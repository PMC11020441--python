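import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aneuml import features
from aneuml.io_model import feature_registry


class TestTissueRelativeZscore:
    def test_direct_evaluation(self):
        z = features.tissue_relative_zscore(pd.Series([1.0, 2.0, 3.0],
                                                      index=list("ABC")))
        # population sigma = sqrt(2/3)
        expected = np.array([-1.0, 0.0, 1.0]) / math.sqrt(2 / 3)
        assert np.allclose(z.to_numpy(), expected, atol=1e-4)

    def test_zero_spread_maps_to_zero(self):
        z = features.tissue_relative_zscore(pd.Series([5.0, 5.0, 5.0],
                                                      index=list("ABC")))
        assert (z == 0).all()

    def test_single_tissue_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            features.tissue_relative_zscore(pd.DataFrame({"A": [1.0, 2.0]}))

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=12).filter(
            lambda v: np.ptp(v) > 1e-6
        )
    )
    def test_moments(self, values):
        z = features.tissue_relative_zscore(
            pd.Series(values, index=[f"t{i}" for i in range(len(values))])
        )
        assert abs(z.mean()) < 1e-9
        assert abs(np.std(z.to_numpy()) - 1.0) < 1e-9


class TestAggregateArm:
    @pytest.mark.parametrize(
        "n,expected",
        [(10, 10.0), (20, 19.5), (5, 5.0)],  # ceil(0.1 n) genes kept
    )
    def test_top_decile_median(self, n, expected):
        s = pd.Series(np.arange(1.0, n + 1), index=[f"G{i:03d}" for i in range(n)])
        assert features.aggregate_arm(s) == expected

    def test_empty_scores_flag_missing(self):
        s = pd.Series([np.nan, np.nan], index=["G1", "G2"])
        assert math.isnan(features.aggregate_arm(s))

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=30),
        st.floats(0.1, 10),
    )
    def test_monotone_in_top_scores(self, values, bump):
        """Raising the maximal gene's score never lowers the arm value."""
        s = pd.Series(values, index=[f"G{i:02d}" for i in range(len(values))])
        before = features.aggregate_arm(s)
        s.iloc[int(np.argmax(s.to_numpy()))] += bump
        assert features.aggregate_arm(s) >= before


def test_density_feature_and_reordering():
    flags = np.zeros(40, dtype=bool)
    flags[:4] = True
    assert features.density_feature(flags) == pytest.approx(0.10)
    assert features.density_feature(np.zeros(5, dtype=bool)) == 0.0
    rng = np.random.default_rng(5)
    flags = rng.random(33) < 0.3
    d = features.density_feature(flags)
    assert d == pytest.approx(flags.sum() / 33)
    assert features.density_feature(rng.permutation(flags)) == pytest.approx(d)
    with pytest.raises(ValueError):
        features.density_feature([])


def test_neutral_restricted_median():
    assert features.neutral_restricted_median(
        [10, 20, 30], ["gain", "neutral", "neutral"]
    ) == 25
    assert math.isnan(
        features.neutral_restricted_median([10, 20], ["gain", "gain"])
    )
    rng = np.random.default_rng(11)
    vals = rng.normal(size=50)
    status = rng.choice(["gain", "loss", "neutral"], size=50)
    expected = np.median(vals[status == "neutral"])
    assert features.neutral_restricted_median(vals, status) == pytest.approx(expected)


def test_essentiality_orientation_is_involution():
    s = pd.Series([-0.8, 0.0, 1.2])
    out = features.essentiality_orientation(s)
    assert out.tolist() == [0.8, 0.0, -1.2]
    assert features.essentiality_orientation(out).tolist() == s.tolist()


def test_cancer_specific_essential_density():
    assert features.cancer_specific_essential_density(
        [0.6, 0.4, 0.7]
    ) == pytest.approx(2 / 3)
    assert features.cancer_specific_essential_density([0.1, 0.2]) == 0.0
    rng = np.random.default_rng(2)
    scores = rng.normal(0.4, 0.3, size=25)
    assert features.cancer_specific_essential_density(scores) == pytest.approx(
        (scores > 0.5).sum() / 25
    )


class TestPpiFeatures:
    @pytest.fixture()
    def tables(self):
        genes = ["G1", "G2", "G3", "G4", "P1"]
        tissues = [f"T{i}" for i in range(6)]
        expr = pd.DataFrame(5.0, index=genes, columns=tissues)
        expr.loc["G4"] = 0.5           # G4 expressed nowhere
        expr.loc["G3", tissues[1:]] = 0.2  # G3 only in T0 (narrow breadth)
        pref = pd.DataFrame(0.0, index=genes, columns=tissues)
        pref.loc["G2", "T0"] = 3.0
        diff = pd.DataFrame(1.0, index=genes, columns=tissues)
        return expr, pref, diff

    def test_unexpressed_gene_zeroed(self, tables):
        expr, pref, diff = tables
        out = features.ppi_features("G4", ["G1", "G2"], "T0", expr, pref, diff)
        assert out == (0.0, 0.0, 0.0, 0.0)

    def test_counts_match_brute_force(self, tables):
        expr, pref, diff = tables
        partners = ["G2", "G3", "G4"]
        n, ne, nts, md = features.ppi_features("G1", partners, "T0", expr, pref, diff)
        # brute force over the fixture
        expressed = [p for p in partners if expr.at[p, "T0"] > 1]
        assert n == len(expressed) == 2
        assert ne == sum(pref.at[p, "T0"] > 2 for p in partners) == 1
        narrow = [p for p in expressed
                  if (expr.loc[p] > 1).sum() <= 0.2 * expr.shape[1]]
        assert nts == len(narrow) == 1
        assert md == np.median([diff.at[p, "T0"] for p in partners])

    def test_all_partners_expressed_none_preferential(self, tables):
        expr, pref, diff = tables
        out = features.ppi_features("G1", ["G2", "P1", "G3"], "T0", expr,
                                    pref * 0, diff)
        assert out[0] == 3.0 and out[1] == 0.0


def test_tissue_specific_gene_density_planted():
    rng = np.random.default_rng(4)
    tissues = [f"T{i}" for i in range(10)]
    genes = [f"G{i}" for i in range(30)]
    expr = pd.DataFrame(rng.uniform(1, 2, size=(30, 10)), index=genes,
                        columns=tissues)
    expr.iloc[:3, 0] = 1000.0  # 3 of 30 genes spiked in T0 => z > 2 there
    assert features.tissue_specific_gene_density(expr, genes, "T0") == pytest.approx(0.1)
    assert features.tissue_specific_gene_density(expr, genes, "T5") == 0.0


class TestParalogCompensation:
    def test_identical_profiles_score_zero(self):
        expr = pd.Series([1.0, 5.0, 10.0], index=list("ABC"))
        score = features.paralog_compensation(expr, expr.copy())
        assert np.allclose(score, 0.0)

    def test_high_paralog_tissue_scores_maximal(self):
        tissues = list("ABCD")
        gene = pd.Series(4.0, index=tissues)
        par = pd.Series(4.0, index=tissues)
        par["A"] = 40.0  # paralog 10x higher in A only
        score = features.paralog_compensation(gene, par)
        assert score.idxmax() == "A"

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        g = pd.Series(rng.lognormal(1, 1, 6), index=[f"T{i}" for i in range(6)])
        p = pd.Series(rng.lognormal(1, 1, 6), index=g.index)
        fwd = features.paralog_compensation(g, p)
        # the reverse ratio is the reciprocal; after log-free z-scoring the
        # antisymmetry is approximate, so check sign structure via ranks
        rev = features.paralog_compensation(p, g)
        assert fwd.idxmax() == rev.idxmin()
        assert fwd.idxmin() == rev.idxmax()


class TestDevelopmentFeatures:
    def test_period_medians_and_variability(self):
        cols = ["4wpc", "8wpc", "newborn", "infant", "toddler", "school"]
        df = pd.DataFrame([[1, 1, 2, 2, 2, 3]], columns=cols, index=["G1"],
                          dtype=float)
        out = features.development_features(df)
        assert out.loc["G1", "fetal"] == 1
        assert out.loc["G1", "childhood"] == 2
        assert out.loc["G1", "young"] == 3
        assert out.loc["G1", "variability"] == pytest.approx(math.sqrt(2 / 3))

    def test_constant_expression_zero_variability(self):
        cols = ["4wpc", "newborn", "school"]
        df = pd.DataFrame([[7.0, 7.0, 7.0]], columns=cols, index=["G1"])
        assert features.development_features(df).loc["G1", "variability"] == 0

    def test_period_median_matches_brute_force(self):
        rng = np.random.default_rng(6)
        cols = list(features.PERIOD_OF_TIMEPOINT)
        df = pd.DataFrame(rng.normal(size=(5, len(cols))), columns=cols)
        out = features.development_features(df)
        fetal_cols = [c for c in cols if features.PERIOD_OF_TIMEPOINT[c] == "fetal"]
        assert np.allclose(out["fetal"], df[fetal_cols].median(axis=1))


class TestBuildFeatureTable:
    def test_full_grid_and_registry_columns(self, small_cohort, small_features):
        cfg = small_cohort.config
        assert small_features.shape == (cfg.n_arms * cfg.n_contexts, 20)
        assert list(small_features.columns) == [f.name for f in feature_registry()]
        assert not small_features.isna().any().any()

    def test_reduced_registry_warns_and_drops(self, small_cohort, caplog):
        reg = feature_registry()[:-1]
        with caplog.at_level("WARNING"):
            table = features.build_feature_table(small_cohort.bundle, reg)
        assert table.shape[1] == 19
        assert any("registry" in r.message for r in caplog.records)

    def test_gene_order_invariance(self, small_cohort, small_features):
        bundle = small_cohort.bundle
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(bundle.gene_annotations))
        shuffled = features.InputBundle(
            gene_annotations=bundle.gene_annotations.iloc[perm],
            context_map=bundle.context_map,
            normal_expression=bundle.normal_expression.iloc[perm],
            cancer_expression=bundle.cancer_expression.iloc[perm],
            crispr_scores=bundle.crispr_scores.iloc[perm],
            rnai_scores=bundle.rnai_scores.iloc[perm],
            ppi_partners=bundle.ppi_partners,
            preferential_expression=bundle.preferential_expression,
            differential_ppi=bundle.differential_ppi,
            process_activity=bundle.process_activity,
            eqtl_significance=bundle.eqtl_significance,
            development=bundle.development,
        )
        table2 = features.build_feature_table(shuffled)
        pd.testing.assert_frame_equal(small_features, table2, atol=1e-9,
                                      check_exact=False)

    def test_determinism(self, small_cohort, small_features):
        again = features.build_feature_table(small_cohort.bundle)
        pd.testing.assert_frame_equal(small_features, again)

    def test_whole_chromosome_grid(self, small_cohort):
        table = features.build_feature_table(small_cohort.bundle,
                                             by_chromosome=True)
        n_chrom = len(
            {a.rstrip("pq")
             for a in small_cohort.bundle.gene_annotations["arm"]}
        )
        assert table.shape == (n_chrom * small_cohort.config.n_contexts, 20)

    def test_unmapped_context_dropped(self, small_cohort, caplog):
        cmap = small_cohort.bundle.context_map.copy()
        cmap.loc[cmap.index[0], "tissue"] = "no_such_tissue"
        bundle = features.InputBundle(
            **{**small_cohort.bundle.__dict__, "context_map": cmap}
        )
        table = features.build_feature_table(bundle)
        n_ctx = small_cohort.config.n_contexts - 1
        assert table.shape[0] == small_cohort.config.n_arms * n_ctx


def test_collapse_subregions_median():
    df = pd.DataFrame(
        [[1.0, 3.0, 10.0]], columns=["skin|sun", "skin|nosun", "lung"]
    )
    out = features.collapse_subregions(df)
    assert out.loc[0, "skin"] == 2.0
    assert out.loc[0, "lung"] == 10.0
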