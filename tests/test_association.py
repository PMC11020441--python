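import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aneuml import association
from aneuml.io_model import GisticArmRecord


def _records(arms, gain_freq, loss_freq):
    return [
        GisticArmRecord(a, "C1", 0.5, 0.5, g, l)
        for a, g, l in zip(arms, gain_freq, loss_freq)
    ]


class TestFeatureFrequencyCorrelation:
    def test_perfect_monotone_relationships(self):
        arms = [f"{i}p" for i in range(1, 7)]
        feats = pd.DataFrame(
            {"up": np.arange(6.0), "down": -np.arange(6.0)},
            index=pd.MultiIndex.from_product([arms, ["C1"]],
                                             names=["arm", "context"]),
        )
        recs = _records(arms, np.linspace(0.1, 0.6, 6), np.linspace(0.6, 0.1, 6))
        res = {(r.feature_name, r.event): r
               for r in association.feature_frequency_correlation(feats, recs)}
        assert res[("up", "gain")].rho == pytest.approx(1.0)
        assert res[("up", "loss")].rho == pytest.approx(-1.0)
        assert res[("down", "gain")].rho == pytest.approx(-1.0)

    def test_matches_bruteforce_rank_correlation(self):
        """rho on a small vector equals the explicit rank-based formula."""
        x = np.array([3.0, 1.0, 2.0, 5.0, 4.0])
        y = np.array([0.30, 0.10, 0.20, 0.40, 0.35])
        rx = np.argsort(np.argsort(x))
        ry = np.argsort(np.argsort(y))
        brute = np.corrcoef(rx, ry)[0, 1]
        arms = [f"{i}q" for i in range(1, 6)]
        feats = pd.DataFrame(
            {"f": x},
            index=pd.MultiIndex.from_product([arms, ["C1"]],
                                             names=["arm", "context"]),
        )
        res = association.feature_frequency_correlation(feats, _records(arms, y, y))
        assert res[0].rho == pytest.approx(brute)

    def test_constant_vector_flagged(self):
        arms = [f"{i}q" for i in range(1, 6)]
        feats = pd.DataFrame(
            {"const": np.ones(5)},
            index=pd.MultiIndex.from_product([arms, ["C1"]],
                                             names=["arm", "context"]),
        )
        res = association.feature_frequency_correlation(
            feats, _records(arms, np.linspace(0.1, 0.5, 5), np.ones(5) * 0.2)
        )
        assert all(np.isnan(r.rho) for r in res)

    def test_too_few_arms_rejected(self):
        arms = ["1p", "1q", "2p"]
        feats = pd.DataFrame(
            {"f": [1.0, 2, 3]},
            index=pd.MultiIndex.from_product([arms, ["C1"]],
                                             names=["arm", "context"]),
        )
        with pytest.raises(ValueError, match=">=4 arms"):
            association.feature_frequency_correlation(
                feats, _records(arms, [0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
            )

    def test_rho_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        arms = [f"{i}q" for i in range(1, 9)]
        index = pd.MultiIndex.from_product([arms, ["C1"]],
                                           names=["arm", "context"])
        feats = pd.DataFrame({"f": rng.normal(size=8)}, index=index)
        recs = _records(arms, rng.uniform(0, 1, 8), rng.uniform(0, 1, 8))
        res1 = association.feature_frequency_correlation(feats, recs)
        res2 = association.feature_frequency_correlation(
            np.exp(feats / 4.0), recs  # strictly monotone transform
        )
        for a, b in zip(res1, res2):
            assert a.rho == pytest.approx(b.rho, abs=1e-12)


class TestBHAdjust:
    def test_hand_computed_example(self):
        # 0.01*3/1, 0.02*3/2, 0.03*3/3 with monotone enforcement
        out = association.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_trivial_cases(self):
        assert association.bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(association.bh_adjust([1.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            association.bh_adjust([1.5])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_stepup_properties_and_bruteforce(self, pvals):
        """BH output >= input, <= 1, order-preserving, and equals the
        explicit step-up formula."""
        out = association.bh_adjust(pvals)
        p = np.asarray(pvals)
        assert (out >= p - 1e-12).all() and (out <= 1 + 1e-12).all()
        # brute-force step-up: sort, p*(n/rank), cumulative min from the right
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        adj = p[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        brute = np.empty(n)
        brute[order] = np.minimum(adj, 1.0)
        assert np.allclose(out, brute, atol=1e-12)


class TestEssentialityGrouping:
    @pytest.mark.parametrize(
        "score,expected",
        [(-0.9, "essential"), (-0.5, "essential"), (-0.4, "intermediate"),
         (-0.3, "non-essential"), (-0.1, "non-essential"), (0.2, "non-essential")],
    )
    def test_thresholds(self, score, expected):
        g = association.essentiality_grouping(pd.Series({"G1": score}))
        assert g["G1"] == expected

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.uniform(-1.5, 0.5, 500),
                           index=[f"G{i}" for i in range(500)])
        groups = association.essentiality_grouping(scores)
        assert groups.isin(["essential", "intermediate", "non-essential"]).all()
        assert len(groups) == 500

    def test_missing_scores_excluded(self):
        g = association.essentiality_grouping(
            pd.Series({"G1": -0.9, "G2": float("nan")})
        )
        assert list(g.index) == ["G1"]


class TestParalogStatusAssociation:
    def test_chi_square_matches_hand_formula(self):
        groups = pd.Series(
            ["essential"] * 10 + ["non-essential"] * 10,
            index=[f"G{i}" for i in range(20)],
        )
        status = pd.Series(
            ["gain"] * 10 + ["loss"] * 10, index=[f"G{i}" for i in range(20)]
        )
        table, chi2, p = association.paralog_status_association(groups, status)
        # brute force on the informative 2x2 block: E = 5 everywhere
        obs = np.array([[10, 0], [0, 10]])
        expected = np.full((2, 2), 5.0)
        manual = ((obs - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(manual) == pytest.approx(20.0)
        assert table.loc["essential", "gain"] == 10
        assert table.shape == (3, 3)

    def test_uniform_table_statistic_zero(self):
        idx = [f"G{i}" for i in range(90)]
        groups = pd.Series(
            ["essential", "intermediate", "non-essential"] * 30, index=idx
        )
        status = pd.Series(["gain", "loss", "neutral"] * 30, index=idx)
        status = pd.Series(
            [["gain", "loss", "neutral"][i // 30] for i in range(90)], index=idx
        )
        _, chi2, _ = association.paralog_status_association(groups, status)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_planted_enrichment_detected(self):
        """Essential genes enriched for gained paralogs at n=2000 genes."""
        rng = np.random.default_rng(12)
        n = 2000
        groups = pd.Series(
            rng.choice(["essential", "intermediate", "non-essential"], n),
            index=[f"G{i}" for i in range(n)],
        )
        probs = {
            "essential": [0.45, 0.10, 0.45],
            "intermediate": [0.30, 0.30, 0.40],
            "non-essential": [0.10, 0.45, 0.45],
        }
        status = pd.Series(
            [rng.choice(["gain", "loss", "neutral"], p=probs[g]) for g in groups],
            index=groups.index,
        )
        table, chi2, p = association.paralog_status_association(groups, status)
        assert p < 0.01
        frac_lost = table["loss"] / table.sum(axis=1)
        assert frac_lost["essential"] < frac_lost["non-essential"]


class TestKSTest:
    def test_identical_samples(self):
        x = np.arange(10.0)
        stat, p = association.essentiality_distribution_test(x, x)
        assert stat == 0.0

    def test_disjoint_supports(self):
        stat, _ = association.essentiality_distribution_test(
            np.arange(5.0), np.arange(10.0, 15.0)
        )
        assert stat == 1.0

    def test_matches_bruteforce_cdf_gap(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=9)
        b = rng.normal(0.5, 1, size=8)
        stat, _ = association.essentiality_distribution_test(a, b)
        grid = np.concatenate([a, b])
        gaps = [
            abs((a <= t).mean() - (b <= t).mean()) for t in grid
        ]
        assert stat == pytest.approx(max(gaps))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            association.essentiality_distribution_test([], [1.0])


def test_paralog_arm_status_resolution(small_cohort):
    from aneuml import labeling

    ann = small_cohort.bundle.gene_annotations
    labels = labeling.label_table(small_cohort.records)
    ctx = small_cohort.bundle.context_map.index[0]
    status = association.paralog_arm_status(ann, labels, ctx)
    assert status.isin(["gain", "loss", "neutral"]).all()
    # spot-check one gene against a manual lookup
    gene = status.index[0]
    par = ann.at[gene, "paralog"]
    par_arm = ann.at[par, "arm"]
    manual = next(l.label for l in labels
                  if l.arm_id == par_arm and l.context_id == ctx)
    assert status[gene] == manual
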