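"""Dyad designs, the IRLS logistic fitter, Rubin pooling, and prediction."""

import math

import numpy as np
import pandas as pd
import pytest

from achnet.lnrm import (
    LnrmFit,
    fit_logistic,
    pool_fits,
    predict_sustain_curve,
    stimulated_design,
    sustained_design,
)
from achnet.netbuild import SiteNetwork, dyad
from conftest import make_attrs, make_org


def star_site():
    """n0 is a preexisting hub (degree 3); n4 isolated in preexisting."""
    orgs = [
        make_org("n0", site_id="S", integrator=True, sector="public_health"),
        make_org("n1", site_id="S", steering=True),
        make_org("n2", site_id="S", steering=True),
        make_org("n3", site_id="S", sector="social_services"),
        make_org("n4", site_id="S"),
    ]
    net = SiteNetwork(site_id="S", organizations={o.org_id: o for o in orgs})
    for u, v in [("n0", "n1"), ("n0", "n2"), ("n0", "n3")]:
        net.preexisting.add(dyad(u, v))
        net.grant.add(dyad(u, v))
        net.edge_attrs[dyad(u, v)] = make_attrs()
    stim = dyad("n1", "n2")
    net.grant.add(stim)
    net.sustained.add(stim)
    net.edge_attrs[stim] = make_attrs(evolution="stimulated", sustain=True, strength=3)
    return net.validate()


class TestStimulatedDesign:
    def test_risk_set_excludes_preexisting_dyads(self):
        design = stimulated_design([star_site()])
        pairs = set(zip(design["u"], design["v"]))
        assert dyad("n0", "n1") not in pairs
        assert len(design) == 10 - 3  # possible dyads minus preexisting

    def test_sum_degree_and_outcome(self):
        design = stimulated_design([star_site()]).set_index(["u", "v"])
        row = design.loc[("n1", "n2")]
        assert row["sum_degree"] == 2  # preexisting degrees 1 + 1
        assert row["outcome"] == 1
        assert row["steering_both"] == 1
        iso = design.loc[("n3", "n4")]
        assert iso["sum_degree"] == 1
        assert iso["outcome"] == 0

    def test_same_sector_indicator(self):
        design = stimulated_design([star_site()]).set_index(["u", "v"])
        assert design.loc[("n1", "n4")]["same_sector"] == 1  # both healthcare
        assert design.loc[("n3", "n4")]["same_sector"] == 0

    def test_covariates_symmetric_under_relabeling(self):
        """Reversing the node id order flips every pair but leaves each
        dyad's covariates unchanged."""
        net = star_site()
        flip = {f"n{i}": f"m{4 - i}" for i in range(5)}
        relabeled = SiteNetwork(
            site_id="S",
            organizations={
                flip[o.org_id]: make_org(
                    flip[o.org_id], site_id="S", sector=o.sector,
                    integrator=o.is_integrator, steering=o.is_steering,
                )
                for o in net.organizations.values()
            },
            preexisting={dyad(flip[u], flip[v]) for u, v in net.preexisting},
            grant={dyad(flip[u], flip[v]) for u, v in net.grant},
            sustained={dyad(flip[u], flip[v]) for u, v in net.sustained},
            edge_attrs={
                dyad(flip[u], flip[v]): a for (u, v), a in net.edge_attrs.items()
            },
        ).validate()
        a = stimulated_design([net])
        b = stimulated_design([relabeled])
        key = lambda df, u, v: df.set_index(["u", "v"]).sort_index()
        a = a.assign(u2=a["u"].map(flip), v2=a["v"].map(flip))
        cols = ["sum_degree", "abs_closeness_diff", "same_sector",
                "integrator_in_dyad", "steering_both", "steering_one", "outcome"]
        for _, row in a.iterrows():
            pair = dyad(row["u2"], row["v2"])
            match = b[(b["u"] == pair[0]) & (b["v"] == pair[1])].iloc[0]
            for c in cols:
                assert row[c] == match[c]


class TestSustainedDesign:
    def test_one_row_per_grant_edge(self, eight_edge_site):
        design = sustained_design([eight_edge_site])
        assert len(design) == 8
        assert design["outcome"].sum() == 6

    def test_attributes_attached(self):
        design = sustained_design([star_site()]).set_index(["u", "v"])
        row = design.loc[("n1", "n2")]
        assert row["avg_strength"] == 3.0
        assert row["stimulated"] == 1
        assert row["outcome"] == 1
        assert design.loc[("n0", "n1")]["stimulated"] == 0

    def test_centralities_use_grant_layer(self):
        design = sustained_design([star_site()]).set_index(["u", "v"])
        # grant degrees: n0=3, n1=2 (preexisting would give n1=1)
        assert design.loc[("n0", "n1")]["sum_degree"] == 5


def intercept_design(k, n, site="S"):
    return pd.DataFrame(
        {
            "site_id": site,
            "u": [f"u{i}" for i in range(n)],
            "v": [f"v{i}" for i in range(n)],
            "outcome": [1] * k + [0] * (n - k),
            "x": np.linspace(-1, 1, n),
        }
    )


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        design = intercept_design(3, 10).drop(columns="x")
        fit = fit_logistic(design)
        assert fit.params["site[S]"] == pytest.approx(math.log(3 / 7), abs=1e-8)

    def test_matches_statsmodels_on_random_designs(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        for _ in range(5):
            n, p = 60, 3
            X = rng.normal(size=(n, p))
            beta = rng.normal(scale=0.8, size=p + 1)
            eta = beta[0] + X @ beta[1:]
            y = rng.random(n) < 1 / (1 + np.exp(-eta))
            design = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
            design["site_id"] = "S"
            design["u"] = [f"u{i}" for i in range(n)]
            design["v"] = [f"v{i}" for i in range(n)]
            design["outcome"] = y.astype(int)
            fit = fit_logistic(design)
            ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
            mine = np.r_[fit.params["site[S]"], [fit.params[f"x{j}"] for j in range(p)]]
            assert np.allclose(mine, ref.params, atol=1e-5)

    def test_complete_separation_flagged_and_capped(self):
        design = intercept_design(5, 10)
        design["x"] = design["outcome"] * 2.0 - 1.0  # perfect separator
        with pytest.warns(UserWarning, match="converge"):
            fit = fit_logistic(design)
        assert not fit.converged
        assert np.abs(fit.params).max() <= 20.0

    def test_rank_deficient_design_names_columns(self):
        design = intercept_design(4, 12)
        design["x_dup"] = design["x"]
        with pytest.raises(ValueError, match="x_dup|x"):
            fit_logistic(design)

    def test_single_class_outcome_rejected(self):
        design = intercept_design(0, 8)
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(design)

    def test_or_and_ci_consistent_with_log_scale(self):
        design = intercept_design(4, 12)
        fit = fit_logistic(design)
        np.testing.assert_allclose(fit.odds_ratios, np.exp(fit.params))
        np.testing.assert_allclose(
            fit.ci_low, np.exp(fit.params - 1.96 * fit.se)
        )
        assert ((fit.ci_low <= fit.odds_ratios) & (fit.odds_ratios <= fit.ci_high)).all()


def make_fit(est, var, names=("b",)):
    return LnrmFit(
        params=pd.Series(est, index=list(names)),
        cov=pd.DataFrame(np.diag(var), index=list(names), columns=list(names)),
        n_rows=10,
        converged=True,
    )


class TestPoolFits:
    def test_single_fit_identity(self):
        fit = make_fit([0.3], [0.5])
        assert pool_fits([fit]) is fit

    def test_rubin_hand_example(self):
        pooled = pool_fits([make_fit([0.0], [1.0]), make_fit([1.0], [1.0])])
        assert pooled.params["b"] == pytest.approx(0.5, abs=1e-12)
        assert pooled.cov.loc["b", "b"] == pytest.approx(1.75, abs=1e-12)

    def test_identical_fits_have_no_between_variance(self):
        fits = [make_fit([0.4], [0.9]) for _ in range(5)]
        pooled = pool_fits(fits)
        assert pooled.cov.loc["b", "b"] == pytest.approx(0.9, abs=1e-12)

    def test_mismatched_columns_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pool_fits([make_fit([0.0], [1.0]), make_fit([0.0], [1.0], names=("c",))])


class TestPredictSustainCurve:
    def test_null_model_flat_at_half(self, eight_edge_site):
        design = sustained_design([eight_edge_site])
        covs = [c for c in design.columns if c not in ("site_id", "u", "v", "outcome")]
        names = ["site[S]"] + covs
        fit = make_fit([0.0] * len(names), [0.1] * len(names), names)
        curve = predict_sustain_curve(fit, design)
        assert np.allclose(curve["probability"], 0.5)

    def test_positive_strength_coefficient_increases(self, eight_edge_site):
        design = sustained_design([eight_edge_site])
        fit = fit_logistic(design, covariates=["avg_strength", "sum_degree"]) \
            if design["avg_strength"].nunique() > 1 else None
        covs = [c for c in design.columns if c not in ("site_id", "u", "v", "outcome")]
        names = ["site[S]"] + covs
        params = pd.Series(0.0, index=names)
        params["avg_strength"] = math.log(1.881)
        fit = LnrmFit(
            params=params,
            cov=pd.DataFrame(np.eye(len(names)) * 0.01, index=names, columns=names),
            n_rows=8,
            converged=True,
        )
        curve = predict_sustain_curve(fit, design, strength_grid=[1, 2, 3])
        probs = curve["probability"].to_numpy()
        assert np.all(np.diff(probs) > 0)
        # odds ratio between adjacent strength levels equals the coefficient
        odds = probs / (1 - probs)
        assert odds[2] / odds[1] == pytest.approx(1.881, rel=1e-9)

    def test_unknown_site_rejected(self, eight_edge_site):
        design = sustained_design([eight_edge_site])
        covs = [c for c in design.columns if c not in ("site_id", "u", "v", "outcome")]
        names = ["site[S]"] + covs
        fit = make_fit([0.0] * len(names), [0.1] * len(names), names)
        with pytest.raises(ValueError, match="unknown site"):
            predict_sustain_curve(fit, design, site_id="nope")
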