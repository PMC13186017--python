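"""Synthetic compendium generation and recovery scoring."""

import math
from dataclasses import replace

import pytest

from phoscoreg.compendium import Direction, SiteKey, filter_class1, apply_directions, resolve_conflicts
from phoscoreg.coregulation import CategoryCounts, CoRegResult
from phoscoreg.pipeline import analyze_observations
from phoscoreg.synthetic_data import (
    SynthConfig,
    SyntheticTruth,
    evaluate_recovery,
    generate_compendium,
    null_calibration,
    target_site_keys,
)

SMALL = SynthConfig(n_studies=4, conditions_per_study=3, n_pos_partners=4,
                    n_neg_partners=4, n_background=4, seed=11)


class TestGenerate:
    def test_deterministic_under_fixed_seed(self):
        obs1, truth1 = generate_compendium(SMALL)
        obs2, truth2 = generate_compendium(SMALL)
        assert obs1 == obs2
        assert truth1.planted == truth2.planted

    def test_seed_changes_output(self):
        obs1, _ = generate_compendium(SMALL)
        obs2, _ = generate_compendium(replace(SMALL, seed=12))
        assert obs1 != obs2

    def test_truth_covers_every_psop_once(self):
        _, truth = generate_compendium(SMALL)
        assert len(truth.planted) == 8
        assert len(truth.background) == 4
        assert not set(truth.planted) & truth.background

    def test_perfect_concordance_construction(self):
        """With c=1, detect=1 and no dropouts, every planted positive partner's
        calls equal the target's calls in every informative condition."""
        cfg = replace(
            SMALL, concordance=1.0, detect_prob=1.0, subthreshold_frac=0.0,
            n_background=0, n_neg_partners=0, p_target_informative=1.0,
        )
        obs, truth = generate_compendium(cfg)
        calls = resolve_conflicts(apply_directions(filter_class1(obs)))
        targets = target_site_keys(cfg)
        by_cond: dict = {}
        for (study, site), d in calls.items():
            by_cond.setdefault(study, {})[site] = d
        for cond_sites in by_cond.values():
            dirs = {cond_sites[t] for t in targets}
            assert len(dirs) == 1  # shared regime across target sites
            regime = dirs.pop()
            for o in truth.planted:
                assert cond_sites[o] is regime

    def test_negative_partners_oppose_regime(self):
        cfg = replace(
            SMALL, concordance=1.0, detect_prob=1.0, subthreshold_frac=0.0,
            n_background=0, n_pos_partners=0, p_target_informative=1.0,
        )
        obs, truth = generate_compendium(cfg)
        calls = resolve_conflicts(apply_directions(filter_class1(obs)))
        target = target_site_keys(cfg)[0]
        by_cond: dict = {}
        for (study, site), d in calls.items():
            by_cond.setdefault(study, {})[site] = d
        for cond_sites in by_cond.values():
            for o in truth.planted:
                assert cond_sites[o] is cond_sites[target].opposite()

    def test_observation_count_within_binomial_noise(self):
        cfg = SynthConfig(seed=3)
        obs, _ = generate_compendium(cfg)
        diff_rows = sum(o.dataset_kind == "differential" for o in obs)
        n_sites = cfg.target_sites + cfg.n_pos_partners + cfg.n_neg_partners + cfg.n_background
        n_trials = cfg.n_studies * cfg.conditions_per_study * n_sites
        mean = n_trials * cfg.detect_prob
        sigma = math.sqrt(n_trials * cfg.detect_prob * (1 - cfg.detect_prob))
        assert abs(diff_rows - mean) <= 3 * sigma

    def test_subthreshold_rows_exercise_filter(self):
        obs, _ = generate_compendium(replace(SMALL, subthreshold_frac=0.3))
        kept = filter_class1(obs)
        assert len(kept) < len(obs)

    def test_impossible_config_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_studies=0, conditions_per_study=0, n_pos_partners=2)
        with pytest.raises(ValueError):
            SynthConfig(concordance=0.3)


def _report(results, truth):
    return evaluate_recovery(results, truth)


class TestEvaluateRecovery:
    M = SiteKey("MELK", "S", 356)

    def _truth(self):
        o_pos = SiteKey("POS001", "S", 101)
        o_bg = SiteKey("BGD001", "T", 301)
        return SyntheticTruth(
            planted={o_pos: ("positive", (self.M,))},
            background={o_bg},
            target_sites=(self.M,),
        ), o_pos, o_bg

    def _result(self, o, sign):
        return CoRegResult(
            m_site=self.M, o_site=o, counts=CategoryCounts(5, 0, 0, 5), fet_p=0.001,
            ratio_pos=math.inf, ratio_neg=0.0, n_conditions=10, n_pmids=3, sign=sign,
        )

    def test_all_recovered(self):
        truth, o_pos, o_bg = self._truth()
        rep = _report([self._result(o_pos, "positive")], truth)
        assert rep.precision["positive"] == rep.recall["positive"] == 1.0
        assert rep.null_fpr == 0.0

    def test_nothing_called(self):
        truth, o_pos, _ = self._truth()
        rep = _report([self._result(o_pos, "none")], truth)
        assert rep.recall["positive"] == 0.0
        assert math.isnan(rep.precision["positive"])

    def test_background_call_counts_as_fpr(self):
        truth, o_pos, o_bg = self._truth()
        rep = _report(
            [self._result(o_pos, "positive"), self._result(o_bg, "positive")], truth
        )
        assert rep.null_fpr == 1.0
        assert rep.precision["positive"] == 0.5

    def test_unknown_o_site_rejected(self):
        truth, _, _ = self._truth()
        alien = self._result(SiteKey("ALIEN", "S", 1), "positive")
        with pytest.raises(ValueError, match="absent from truth"):
            _report([alien], truth)


class TestRecoveryBehaviour:
    def _recall(self, concordance, seed=50, conditions=4):
        cfg = SynthConfig(
            n_studies=8, conditions_per_study=conditions, n_pos_partners=6,
            n_neg_partners=6, n_background=6, concordance=concordance, seed=seed,
        )
        obs, truth = generate_compendium(cfg)
        _, _, results = analyze_observations(
            obs, cfg.target_symbol, explicit_sites=list(truth.target_sites)
        )
        rep = evaluate_recovery(results, truth)
        return (rep.recall["positive"] + rep.recall["negative"]) / 2

    def test_recall_monotone_in_concordance(self):
        grid = [self._recall(c) for c in (0.6, 0.8, 1.0)]
        assert grid[1] >= grid[0] - 0.05 and grid[2] >= grid[1] - 0.05

    def test_recall_monotone_in_conditions(self):
        low = self._recall(0.9, conditions=2)
        high = self._recall(0.9, conditions=6)
        assert high >= low - 0.05

    def test_half_concordance_partners_behave_null(self):
        """At c=0.5 the planted 'partners' are statistically independent of the
        target, so their call rate must sit inside the null envelope."""
        cfg = SynthConfig(concordance=0.5, n_background=30, n_pos_partners=15,
                          n_neg_partners=15, seed=60)
        obs, truth = generate_compendium(cfg)
        _, _, results = analyze_observations(
            obs, cfg.target_symbol, explicit_sites=list(truth.target_sites)
        )
        rep = evaluate_recovery(results, truth)
        n_pairs = 3 * (len(truth.planted))
        called = rep.n_called["positive"] + rep.n_called["negative"]
        # pairs involving planted-at-c=0.5 partners plus background, all null
        total = n_pairs + 3 * len(truth.background)
        rate = called / total
        se = math.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 3 * se


class TestNullCalibration:
    def test_too_few_pairs_rejected(self):
        cfg = SynthConfig(n_pos_partners=0, n_neg_partners=0, n_background=2, seed=1)
        with pytest.raises(ValueError, match="increase replicates"):
            null_calibration(cfg, replicates=1)

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            null_calibration(SynthConfig(), replicates=0)

    def test_fpr_conservative_small(self):
        cfg = SynthConfig(n_background=40, seed=2)
        res = null_calibration(cfg, replicates=2)
        assert res.n_pairs == 240
        se = math.sqrt(0.05 * 0.95 / res.n_pairs)
        assert res.fpr <= 0.05 + 3 * se
        assert res.ci_low <= res.fpr <= res.ci_high
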