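"""Ground-truth synthetic corpora: determinism, noiseless limits,
calibration of the generator to its target study structure."""

import numpy as np
import pytest

import metacontrast as mc


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a, ta = mc.simulate_comparison(mc.SimConfig(seed=3), 5)
        b, tb = mc.simulate_comparison(mc.SimConfig(seed=3), 5)
        assert a.multilab.treatment_arm == b.multilab.treatment_arm
        assert [s.treatment_arm for s in a.singles] == [
            s.treatment_arm for s in b.singles
        ]
        assert ta == tb

    def test_different_seeds_differ(self):
        a, _ = mc.simulate_comparison(mc.SimConfig(seed=3), 5)
        b, _ = mc.simulate_comparison(mc.SimConfig(seed=4), 5)
        assert a.multilab.treatment_arm != b.multilab.treatment_arm

    def test_substreams_are_extensible(self):
        # comparison i is identical whether or not later ones are drawn
        cfg5 = mc.SimConfig(n_comparisons=5, seed=9)
        cfg8 = mc.SimConfig(n_comparisons=8, seed=9)
        c5, _ = mc.simulate_corpus(cfg5)
        c8, _ = mc.simulate_corpus(cfg8)
        for x, y in zip(c5, c8):
            assert x.multilab.treatment_arm == y.multilab.treatment_arm


class TestNoiselessLimit:
    def test_zero_variance_zero_bias_recovers_truth(self):
        cfg = mc.SimConfig(
            n_comparisons=4, mu_delta=0.8, tau_comparison=0.0,
            tau_center=0.0, tau_single=0.0, bias_single=0.0,
            n_per_arm_multi=(4000, 4000), n_per_arm_single=(4000, 4000),
            seed=2,
        )
        comps, truth = mc.simulate_corpus(cfg)
        rep = mc.contrast_report(comps)
        assert abs(rep.pooled_dsmd.point) < 0.05
        for e in rep.per_comparison_esr:
            assert e.esr == pytest.approx(1.0, abs=0.1)
        for comp, t in zip(comps, truth["comparisons"]):
            d = mc.study_effect(comp.multilab)
            assert d.point == pytest.approx(t["delta"], abs=0.1)


class TestCalibration:
    def test_sample_size_medians_near_targets(self):
        comps, _ = mc.simulate_corpus(mc.SimConfig(n_comparisons=150, seed=4))
        multi_n = [c.multilab.total_animals for c in comps]
        single_n = [s.total_animals for c in comps for s in c.singles]
        assert 90 <= np.median(multi_n) <= 135
        assert 14 <= np.median(single_n) <= 26
        assert all(len(c.singles) <= 10 for c in comps)

    def test_quality_flag_frequencies_converge(self):
        # law-of-large-numbers check at ~10,000 studies per design
        cfg = mc.SimConfig(n_comparisons=1400, n_singles=(7, 7), seed=6)
        comps, _ = mc.simulate_corpus(cfg)
        multi = np.array(
            [c.multilab.quality_flags.as_tuple() for c in comps]
        )
        single = np.array(
            [s.quality_flags.as_tuple() for c in comps for s in c.singles]
        )
        for mat, probs in (
            (multi, cfg.quality_probs_multi),
            (single, cfg.quality_probs_single),
        ):
            n = len(mat)
            for j, p in enumerate(probs):
                se = np.sqrt(p * (1 - p) / n)
                assert abs(mat[:, j].mean() - p) <= 3 * se + 1e-9


class TestSelection:
    def test_gate_inflates_small_study_effects(self):
        base = mc.SimConfig(
            n_comparisons=40, bias_single=0.0, n_per_arm_single=(5, 10),
            seed=13,
        )
        gated = mc.SimConfig(**{**base.__dict__, "selection": True})
        rep_base = mc.contrast_report(mc.simulate_corpus(base)[0])
        rep_gated = mc.contrast_report(mc.simulate_corpus(gated)[0])
        assert rep_gated.pooled_dsmd.point > rep_base.pooled_dsmd.point
        assert rep_gated.pooled_dsmd.point > 0

    def test_impossible_gate_stops_at_max_redraws(self):
        cfg = mc.SimConfig(
            n_comparisons=1, mu_delta=0.0, tau_comparison=0.0,
            bias_single=0.0, tau_single=0.0, selection=True,
            selection_alpha=1e-6, n_per_arm_single=(5, 5), max_redraws=3,
            seed=1,
        )
        comp, truth = mc.simulate_comparison(cfg, 0)
        assert len(comp.singles) >= 1  # studies kept despite unmet gate
        assert max(truth["redraw_counts"]) == 3


class TestRecoveryExperiment:
    def test_single_replicate_report(self):
        rep = mc.recovery_experiment(
            mc.SimConfig(n_comparisons=5, seed=1), n_replicates=1,
            keep_reports=True,
        )
        assert rep.n_replicates == 1
        assert len(rep.pooled_dsmds) == 1
        assert len(rep.per_replicate) == 1
        assert rep.coverage in (0.0, 1.0)

    def test_invalid_replicates_rejected(self):
        with pytest.raises(mc.ValidationError):
            mc.recovery_experiment(mc.SimConfig(), n_replicates=0)


class TestConfigValidation:
    def test_empty_range_rejected(self):
        with pytest.raises(mc.ValidationError):
            mc.SimConfig(n_centers=(5, 2))

    def test_negative_tau_rejected(self):
        with pytest.raises(mc.ValidationError):
            mc.SimConfig(tau_single=-0.1)

    def test_bad_quality_probs_rejected(self):
        with pytest.raises(mc.ValidationError):
            mc.SimConfig(quality_probs_multi=(0.5, 0.5))
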