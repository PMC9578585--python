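"""The synthetic coalition generator: invariants, determinism, recall error."""

import math
from dataclasses import replace

import numpy as np
import pytest

from achnet.netbuild import build_networks, dyad
from achnet.synth import (
    SynthConfig,
    generate_site,
    generate_study,
    perturb_recall,
    recall_error_sensitivity,
    true_coefficients,
)


def small_config(**kw):
    defaults = dict(
        site_sizes=(12, 10),
        n_steering_per_site=(3, 2),
        response_rate=1.0,
        seed=5,
    )
    defaults.update(kw)
    return SynthConfig(**defaults)


class TestConfigValidation:
    def test_tiny_site_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            SynthConfig(site_sizes=(2,)).validate()

    def test_nonfinite_coefficients_rejected(self):
        cfg = small_config()
        cfg.stim_coefs["sum_degree"] = float("nan")
        with pytest.raises(ValueError, match="non-finite"):
            cfg.validate()

    def test_probability_vector_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SynthConfig(strength_probs=(0.5, 0.2, 0.2)).validate()

    def test_response_rate_bounds(self):
        with pytest.raises(ValueError, match="response_rate"):
            small_config(response_rate=1.2).validate()


class TestGenerateSite:
    def test_same_seed_identical_outputs(self):
        cfg = small_config()
        a = generate_site(cfg, 0)
        b = generate_site(cfg, 0)
        assert a[0] == b[0]
        assert a[1] == b[1]
        assert a[2] == b[2]

    def test_nesting_invariants_every_site(self):
        _, truths, _ = generate_study(SynthConfig(seed=2))
        for net in truths:
            assert net.preexisting <= net.grant
            assert net.sustained <= net.grant
            assert net.stimulated == net.grant - net.preexisting

    def test_exactly_one_integrator_per_site(self):
        orgs, _, _ = generate_study(small_config())
        for site in ("A", "B"):
            assert sum(o.is_integrator for o in orgs if o.site_id == site) == 1

    def test_intercept_only_stimulation_rate(self):
        """With all slope coefficients zero, the stimulated fraction among
        eligible dyads matches logistic(intercept) to binomial error."""
        beta0 = -1.2
        coefs = {k: 0.0 for k in SynthConfig().stim_coefs}
        coefs["intercept"] = beta0
        cfg = SynthConfig(site_sizes=(40, 40, 40), n_steering_per_site=5,
                          response_rate=1.0, stim_coefs=coefs, seed=11)
        _, truths, _ = generate_study(cfg)
        eligible = sum(t.possible_dyads - len(t.preexisting) for t in truths)
        stim = sum(len(t.stimulated) for t in truths)
        p = 1 / (1 + math.exp(-beta0))
        se = math.sqrt(p * (1 - p) / eligible)
        assert abs(stim / eligible - p) < 4 * se

    def test_fixed_respondent_count_gives_exact_missing_fraction(self):
        """An 11-node site at response rate 0.455 has exactly 5 respondents,
        so C(6,2)/C(11,2) = 27.3% of dyads are missing."""
        cfg = SynthConfig(site_sizes=(11,), n_steering_per_site=(2,),
                          response_rate=(0.455,), seed=3)
        orgs, _, reports = generate_site(cfg, 0)
        assert sum(o.responded for o in orgs) == 5
        (net,) = build_networks(orgs, reports)
        assert len(net.missing) == math.comb(6, 2)
        assert 100.0 * len(net.missing) / net.possible_dyads == pytest.approx(
            27.3, abs=0.05
        )

    def test_site_index_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            generate_site(small_config(), 9)


class TestPerturbRecall:
    def test_zero_rate_is_identity(self):
        _, _, reports = generate_site(small_config(), 0)
        rng = np.random.default_rng(0)
        assert perturb_recall(reports, 0.0, rng) == reports

    def test_flips_only_preexisting_to_stimulated(self):
        _, _, reports = generate_site(small_config(), 0)
        rng = np.random.default_rng(0)
        out = perturb_recall(reports, 0.3, rng)
        n_pre_before = len({dyad(r.reporter, r.target) for r in reports
                            if r.evolution == "preexisting"})
        n_pre_after = len({dyad(r.reporter, r.target) for r in out
                           if r.evolution == "preexisting"})
        assert n_pre_after == n_pre_before - round(0.3 * n_pre_before)
        for before, after in zip(reports, out):
            if before.evolution != after.evolution:
                assert before.evolution == "preexisting"
                assert after.evolution == "stimulated"
            else:
                assert before == after


class TestTrueCoefficients:
    def test_site_intercepts_expand_shared_intercept(self):
        cfg = small_config()
        truth = true_coefficients(cfg, "stimulated")
        assert truth["site[A]"] == truth["site[B]"] == cfg.stim_coefs["intercept"]
        assert truth["sum_degree"] == cfg.stim_coefs["sum_degree"]

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            true_coefficients(small_config(), "nope")


class TestRecallErrorSensitivity:
    def test_requires_replication(self):
        with pytest.raises(ValueError, match="n_reps"):
            recall_error_sensitivity(small_config(), n_reps=1, seed=0)

    def test_zero_rate_gives_exactly_zero_deviation(self):
        cfg = small_config(recall_error_rate=0.0)
        table = recall_error_sensitivity(cfg, n_reps=2, seed=1)
        assert (table["mean_abs_deviation"] == 0.0).all()
        assert (table["sign_agreement"] == 1.0).all()

    def test_large_perturbation_deviates_more_than_small(self):
        """Coefficient deviations grow with the recall-error rate."""
        cfg_small = small_config(site_sizes=(16, 14), recall_error_rate=0.05)
        cfg_large = replace(cfg_small, recall_error_rate=0.5)
        dev_small = recall_error_sensitivity(cfg_small, n_reps=4, seed=2)
        dev_large = recall_error_sensitivity(cfg_large, n_reps=4, seed=2)
        key = ["model", "coefficient"]
        merged = dev_small.merge(dev_large, on=key, suffixes=("_s", "_l"))
        shared = merged[~merged["coefficient"].str.startswith("site[")]
        assert (
            shared["mean_abs_deviation_l"].mean()
            > shared["mean_abs_deviation_s"].mean()
        )
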