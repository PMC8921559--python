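import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aelink.downstream import (
    DEFAULT_RISK_COEFFICIENTS,
    RiskModel,
    RiskScoreModel,
    confirmation_summary,
    hic_confirm,
    hypergeom_enrich,
    logrank_test,
    optimal_cutoff,
    risk_score,
)


def _links(rows):
    return pd.DataFrame(rows, columns=["chrom", "enh_start", "enh_end", "tss"])


def _tads(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _loops(rows):
    return pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    )


class TestHicConfirm:
    def test_containment_within_one_tad(self):
        out = hic_confirm(
            _links([("chr1", 1_000, 2_000, 50_000)]),
            _tads([("chr1", 0, 100_000)]),
            _loops([]),
        )
        assert bool(out["tad_confirmed"].iloc[0])

    def test_boundary_spanning_pair_unconfirmed(self):
        out = hic_confirm(
            _links([("chr1", 1_000, 2_000, 150_000)]),
            _tads([("chr1", 0, 100_000), ("chr1", 100_000, 200_000)]),
            _loops([]),
        )
        assert not bool(out["confirmed"].iloc[0])

    def test_loop_anchors_either_orientation(self):
        links = _links(
            [("chr1", 1_000, 2_000, 500_000), ("chr1", 499_000, 501_000, 1_500)]
        )
        loops = _loops([("chr1", 900, 2_100, "chr1", 498_000, 502_000)])
        out = hic_confirm(links, _tads([]), loops)
        assert out["loop_confirmed"].tolist() == [True, True]

    def test_overlapping_tads_any_single_containing(self):
        out = hic_confirm(
            _links([("chr1", 1_000, 2_000, 90_000)]),
            _tads([("chr1", 0, 50_000), ("chr1", 0, 95_000)]),
            _loops([]),
        )
        assert bool(out["tad_confirmed"].iloc[0])

    def test_matches_brute_force_all_tads_scan(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            tad_rows = []
            for _ in range(int(rng.integers(1, 8))):
                s = int(rng.integers(0, 900_000))
                tad_rows.append(("chrA", s, s + int(rng.integers(50_000, 400_000))))
            link_rows = []
            for _ in range(int(rng.integers(1, 12))):
                es = int(rng.integers(0, 990_000))
                link_rows.append(("chrA", es, es + 1_000, int(rng.integers(0, 1_000_000))))
            out = hic_confirm(_links(link_rows), _tads(tad_rows), _loops([]))
            for i, (chrom, es, ee, tss) in enumerate(link_rows):
                center = (es + ee) // 2
                expected = any(
                    s <= center < e and s <= tss < e for (_, s, e) in tad_rows
                )
                assert bool(out["tad_confirmed"].iloc[i]) == expected

    def test_summary_fractions(self):
        out = hic_confirm(
            _links([("chr1", 1_000, 2_000, 50_000), ("chr1", 1_000, 2_000, 950_000)]),
            _tads([("chr1", 0, 100_000)]),
            _loops([]),
        )
        summary = confirmation_summary(out)
        assert summary["frac_tad"] == 0.5
        assert summary["frac_either"] == 0.5


class TestHypergeom:
    def test_hand_enumerated_example(self):
        # N=10, K=4, n=3, k=2 -> P(X>=2) = 40/120 = 1/3
        background = [f"b{i}" for i in range(10)]
        sets = {"S": set(background[:4])}
        query = [background[0], background[1], background[5]]
        out = hypergeom_enrich(query, sets, background)
        assert out["k"].iloc[0] == 2
        assert out["p"].iloc[0] == pytest.approx(1 / 3)

    def test_zero_overlap_gives_p_one(self):
        background = [f"b{i}" for i in range(8)]
        out = hypergeom_enrich(background[4:6], {"S": set(background[:3])}, background)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_saturated_query(self):
        background = [f"b{i}" for i in range(6)]
        out = hypergeom_enrich(background, {"S": set(background[:4])}, background)
        assert out["k"].iloc[0] == 4
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_universe(self):
        """p equals the exact fraction of query draws with >= k overlap,
        enumerated over all C(N, n) subsets for N <= 12."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            N = int(rng.integers(5, 13))
            background = [f"b{i}" for i in range(N)]
            K = int(rng.integers(1, N))
            members = set(rng.choice(background, size=K, replace=False))
            n = int(rng.integers(1, N))
            query = list(rng.choice(background, size=n, replace=False))
            k_obs = len(members & set(query))
            out = hypergeom_enrich(query, {"S": members}, background)
            count = sum(
                1
                for combo in itertools.combinations(background, n)
                if len(members & set(combo)) >= k_obs
            )
            from math import comb

            assert out["p"].iloc[0] == pytest.approx(count / comb(N, n))

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(["a"], {"S": {"a"}}, [])


class TestRiskScore:
    def _expr(self, value):
        return pd.DataFrame(
            {"pt1": [value] * 6}, index=list(DEFAULT_RISK_COEFFICIENTS)
        )

    def test_zero_expression_zero_score(self):
        assert risk_score(self._expr(0.0))["pt1"] == 0.0

    def test_unit_expression_sums_coefficients(self):
        assert risk_score(self._expr(1.0))["pt1"] == pytest.approx(0.3433)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(5, 1, size=(6, 4)),
            index=list(DEFAULT_RISK_COEFFICIENTS),
            columns=[f"pt{i}" for i in range(4)],
        )
        assert np.allclose(risk_score(expr * 2), risk_score(expr) * 2)

    def test_missing_gene_named_in_error(self):
        expr = self._expr(1.0).drop(index="RAB26")
        with pytest.raises(ValueError, match="RAB26"):
            risk_score(expr)


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([5.0, 10.0, 15.0])
        e = np.array([1, 1, 0])
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_six_patient_toy_matches_hand_computation(self):
        """Alternating event times 1..6; O-E and the hypergeometric variance
        were computed by hand for this configuration."""
        ta, ea = np.array([1.0, 3.0, 5.0]), np.array([1, 1, 1])
        tb, eb = np.array([2.0, 4.0, 6.0]), np.array([1, 1, 1])
        chi2, p = logrank_test(ta, ea, tb, eb)
        # hand: O_A=3, E_A = 0.5+0.4+0.5+1/3+0.5 = 2.2333; V = 1.21222
        assert chi2 == pytest.approx((3 - 2.23333) ** 2 / 1.21222, abs=1e-4)
        assert p == pytest.approx(stats.chi2.sf(chi2, 1))

    def test_agrees_with_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(1)
        ta = rng.exponential(100, 40)
        tb = rng.exponential(60, 35)
        ea = (rng.random(40) < 0.8).astype(int)
        eb = (rng.random(35) < 0.8).astype(int)
        chi2, p = logrank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert p == pytest.approx(ref.p_value, rel=1e-6)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        ta = rng.exponential(100, 20)
        ea = np.ones(20, dtype=int)
        tb = rng.exponential(50, 20)
        eb = np.ones(20, dtype=int)
        chi2_1, _ = logrank_test(ta, ea, tb, eb)
        perm = rng.permutation(20)
        chi2_2, _ = logrank_test(ta[perm], ea[perm], tb, eb)
        assert chi2_1 == pytest.approx(chi2_2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(np.array([]), np.array([]), np.array([1.0]), np.array([1]))


class TestOptimalCutoff:
    def _threshold_cohort(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        scores = pd.Series(rng.normal(0, 1, n), index=[f"pt{i}" for i in range(n)])
        threshold = float(scores.quantile(0.6))
        hazard = np.where(scores > threshold, 6.0 / 1_000, 1.0 / 1_000)
        time = rng.exponential(1 / hazard)
        censor = rng.uniform(500, 3_000, n)
        obs = np.minimum(time, censor)
        event = (time <= censor).astype(int)
        return scores, pd.Series(obs, index=scores.index), pd.Series(event, index=scores.index), threshold

    def test_recovers_planted_hazard_threshold(self):
        scores, time, event, threshold = self._threshold_cohort()
        cutoff, groups = optimal_cutoff(scores, time, event)
        gaps = np.diff(np.sort(scores.to_numpy()))
        neighborhood = np.sort(scores.to_numpy())
        idx = np.searchsorted(neighborhood, threshold)
        local_gap = gaps[max(0, idx - 1) : idx + 1].max() if len(gaps) else 0
        assert abs(cutoff - threshold) <= max(local_gap, 0.15)
        assert set(groups.unique()) == {"high", "low"}

    def test_rank_preserving_relabel_keeps_groups(self):
        scores, time, event, _ = self._threshold_cohort(seed=3)
        _, groups1 = optimal_cutoff(scores, time, event)
        transformed = pd.Series(np.exp(scores / 2), index=scores.index)
        _, groups2 = optimal_cutoff(transformed, time, event)
        assert (groups1 == groups2).all()

    def test_all_equal_scores_error(self):
        n = 20
        scores = pd.Series(np.ones(n))
        time = pd.Series(np.arange(1.0, n + 1))
        event = pd.Series(np.ones(n, dtype=int))
        with pytest.raises(ValueError):
            optimal_cutoff(scores, time, event)


class TestRiskScoreModel:
    def test_high_risk_group_has_worse_survival(self, default_study):
        res = RiskScoreModel(default_study.risk_expression, default_study.survival).fit()
        assert res.p < 0.01
        high = res.groups == "high"
        km_high = default_study.survival.loc[high, "time"].median()
        km_low = default_study.survival.loc[~high, "time"].median()
        assert km_high < km_low
        assert "log-rank" in res.summary()

    def test_fixed_cutoff_respected(self, default_study):
        model = RiskModel(cutoff=2.0)
        res = RiskScoreModel(
            default_study.risk_expression, default_study.survival, model
        ).fit()
        assert res.cutoff == 2.0
        assert ((res.scores > 2.0) == (res.groups == "high")).all()
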