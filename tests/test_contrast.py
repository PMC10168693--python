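"""DSMD / ESR design contrasts."""

import math

import numpy as np
import pytest

import metacontrast as mc
from metacontrast.contrast import DsmdResult, _disjoint
from metacontrast.pooling import PooledEstimate, PoolModel


def _pooled(point, se, k=3):
    return PooledEstimate(
        point=point, se=se, ci_low=point - 1.96 * se,
        ci_high=point + 1.96 * se, tau2=0.0, q=0.0, df=k - 1, k=k,
        model=PoolModel.random,
    )


def _dsmd_result(cid, d_single, se_s, d_multi, se_m):
    delta = d_single - d_multi
    se = math.sqrt(se_s**2 + se_m**2)
    return DsmdResult(
        comparison_id=cid, dsmd=delta, se=se,
        ci_low=delta - 1.959963984540054 * se,
        ci_high=delta + 1.959963984540054 * se,
        d_single=_pooled(d_single, se_s),
        d_multi=_pooled(d_multi, se_m, k=1),
    )


class TestDsmd:
    def test_hand_evaluated_example(self, small_corpus):
        comps, _ = small_corpus
        pools = (_pooled(1.0, 0.2), _pooled(0.3, 0.3, k=1))
        r = mc.dsmd(comps[0], pools=pools)
        assert r.dsmd == pytest.approx(0.7, abs=1e-12)
        assert r.se == pytest.approx(math.sqrt(0.13), abs=1e-12)
        assert r.ci_low == pytest.approx(0.7 - 1.959963984540054 * r.se)

    def test_null_contrast(self, small_corpus):
        comps, _ = small_corpus
        pools = (_pooled(0.5, 0.2), _pooled(0.5, 0.1, k=1))
        assert mc.dsmd(comps[0], pools=pools).dsmd == 0.0

    def test_antisymmetry(self, small_corpus):
        comps, _ = small_corpus
        fwd = mc.dsmd(comps[0], pools=(_pooled(1.2, 0.2), _pooled(0.3, 0.3)))
        rev = mc.dsmd(comps[0], pools=(_pooled(0.3, 0.3), _pooled(1.2, 0.2)))
        assert fwd.dsmd == pytest.approx(-rev.dsmd)
        assert fwd.se == pytest.approx(rev.se)

    def test_dsmd_matches_pool_difference(self, small_corpus):
        comps, _ = small_corpus
        for comp in comps:
            r = mc.dsmd(comp)
            assert r.dsmd == pytest.approx(
                r.d_single.point - r.d_multi.point, abs=1e-12
            )
            assert r.se**2 == pytest.approx(
                r.d_single.se**2 + r.d_multi.se**2, abs=1e-12
            )


class TestPoolDsmd:
    def test_single_comparison_identity(self):
        r = _dsmd_result("c1", 1.0, 0.2, 0.3, 0.3)
        p = mc.pool_dsmd([r])
        assert p.point == pytest.approx(r.dsmd)
        assert p.ci_low == pytest.approx(r.ci_low)

    def test_shares_random_pool_code_path(self, small_corpus):
        comps, _ = small_corpus
        results = [mc.dsmd(c) for c in comps]
        assert mc.pool_dsmd(results).point == pytest.approx(
            mc.random_pool(results).point, abs=1e-15
        )

    def test_equal_weighting_is_plain_mean(self):
        rs = [
            _dsmd_result("a", 1.0, 0.1, 0.2, 0.1),
            _dsmd_result("b", 0.4, 0.5, 0.1, 0.5),
        ]
        p = mc.pool_dsmd(rs, weighting="equal")
        assert p.point == pytest.approx(np.mean([r.dsmd for r in rs]))

    def test_zero_bias_corpus_recovers_zero(self):
        comps, _ = mc.simulate_corpus(
            mc.SimConfig(n_comparisons=200, bias_single=0.0, seed=11)
        )
        rep = mc.contrast_report(comps)
        p = rep.pooled_dsmd
        assert abs(p.point) < 3 * p.se


class TestEsr:
    def test_no_difference(self, small_corpus):
        comps, _ = small_corpus
        r = mc.esr(comps[0], pools=(_pooled(0.6, 0.1), _pooled(0.6, 0.1)))
        assert r.esr == pytest.approx(1.0)

    def test_plain_ratio(self, small_corpus):
        comps, _ = small_corpus
        r = mc.esr(comps[0], pools=(_pooled(0.8, 0.1), _pooled(0.2, 0.1)))
        assert r.esr == pytest.approx(4.0)

    def test_degenerate_denominator_flagged_and_excluded(self, small_corpus):
        comps, _ = small_corpus
        r = mc.esr(comps[0], pools=(_pooled(0.8, 0.1), _pooled(1e-12, 0.1)))
        assert r.degenerate and r.esr is None
        ok = mc.EsrResult("b", 2.0, 0.8, 0.4)
        med, rng_ = mc.median_esr([r, ok])
        assert med == 2.0 and rng_ == (2.0, 2.0)

    def test_sign_consistency_with_dsmd(self, small_corpus):
        comps, _ = small_corpus
        for comp in comps:
            d = mc.dsmd(comp)
            e = mc.esr(comp)
            if d.d_single.point > 0 and d.d_multi.point > 0:
                assert np.sign(d.dsmd) == np.sign(np.log(e.esr))

    def test_relabeling_inverts_ratio(self, small_corpus):
        comps, _ = small_corpus
        fwd = mc.esr(comps[0], pools=(_pooled(0.9, 0.1), _pooled(0.3, 0.1)))
        rev = mc.esr(comps[0], pools=(_pooled(0.3, 0.1), _pooled(0.9, 0.1)))
        assert fwd.esr == pytest.approx(1.0 / rev.esr)


class TestCounts:
    def test_direction_count_strict(self):
        rs = [
            _dsmd_result("a", 0.5, 0.1, 0.0, 0.1),
            _dsmd_result("b", 0.0, 0.1, 0.5, 0.1),
            _dsmd_result("c", 0.3, 0.1, 0.3, 0.1),
        ]
        positive, ties = mc.direction_count(rs)
        assert positive == 1 and ties == 1

    def test_all_negative(self):
        rs = [_dsmd_result(c, 0.0, 0.1, 0.1, 0.1) for c in "abc"]
        assert mc.direction_count(rs)[0] == 0

    @pytest.mark.parametrize(
        "multi_ci,single_ci,expected",
        [((0.0, 1.0), (2.0, 3.0), True),   # disjoint
         ((0.0, 2.0), (1.0, 3.0), False),  # overlapping
         ((1.5, 2.0), (1.0, 3.0), False)], # nested
    )
    def test_ci_disjointness(self, multi_ci, single_ci, expected):
        assert _disjoint(multi_ci, single_ci) is expected

    def test_nonoverlap_count(self):
        r1 = DsmdResult("a", 1.0, 0.1, 0.8, 1.2, _pooled(2.5, 0.1),
                        _pooled(0.5, 0.1))  # CIs (2.3,2.7) vs (0.3,0.7)
        r2 = DsmdResult("b", 0.1, 0.1, -0.1, 0.3, _pooled(0.6, 0.2),
                        _pooled(0.5, 0.2))
        assert mc.ci_nonoverlap_count([r1, r2]) == 1


class TestContrastReport:
    def test_report_counts_bounded(self, small_corpus):
        comps, _ = small_corpus
        rep = mc.contrast_report(comps)
        n = rep.n_comparisons
        assert rep.n_single_larger <= n
        assert rep.n_esr_gt_1 <= n
        assert rep.n_ci_nonoverlap <= n
        assert rep.esr_range[0] <= rep.median_esr <= rep.esr_range[1]
        assert len(rep.per_comparison_dsmd) == n
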