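"""ERGM MPLE fitting and missing-dyad imputation."""

import math

import numpy as np
import pytest

from achnet.impute import fit_ergm, impute_missing
from achnet.netbuild import SiteNetwork, dyad
from achnet.netstats import transitivity
from conftest import make_attrs, make_org, random_edges


def site_from_edges(nodes, edges, missing=(), site_id="S"):
    orgs = {
        n: make_org(n, site_id=site_id, integrator=(i == 0))
        for i, n in enumerate(nodes)
    }
    net = SiteNetwork(site_id=site_id, organizations=orgs)
    for pair in edges:
        net.grant.add(pair)
        net.preexisting.add(pair)
        net.edge_attrs[pair] = make_attrs(strength=2)
    net.missing = set(missing)
    return net.validate()


class TestFitErgm:
    def test_edges_only_density_half_gives_zero(self):
        nodes = [f"v{i}" for i in range(5)]
        # 5 of 10 dyads tied
        edges = {dyad(nodes[i], nodes[j]) for i, j in
                 [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)]}
        model = fit_ergm(site_from_edges(nodes, edges), terms=("edges",))
        assert model.coefficients[0] == pytest.approx(0.0, abs=1e-7)

    def test_edges_only_closed_form_logit(self):
        rng = np.random.default_rng(5)
        nodes = [f"v{i}" for i in range(11)]  # 55 dyads
        all_pairs = [dyad(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
        edges = set(rng.choice(len(all_pairs), size=10, replace=False).tolist())
        edges = {all_pairs[k] for k in edges}
        model = fit_ergm(site_from_edges(nodes, edges), terms=("edges",))
        assert model.coefficients[0] == pytest.approx(math.log(10 / 45), abs=1e-7)

    def test_triangle_free_graph_keeps_edge_coef_near_logit(self):
        # perfect matching on 6 nodes: no triangles, density 3/15 = 0.2
        nodes = [f"v{i}" for i in range(6)]
        edges = {dyad(nodes[i], nodes[j]) for i, j in [(0, 1), (2, 3), (4, 5)]}
        model = fit_ergm(site_from_edges(nodes, edges), terms=("edges", "triangles"))
        assert np.all(np.isfinite(model.coefficients))
        assert abs(model.coefficients[0] - math.log(0.2 / 0.8)) < 0.2

    def test_mple_matches_statsmodels_logit(self):
        """MPLE is logistic regression on change statistics; cross-check the
        coefficients against an independent fitter."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        nodes, edges = random_edges(rng, 14, 0.3)
        net = site_from_edges(nodes, edges)
        model = fit_ergm(net, terms=("edges", "triangles"))
        # rebuild the MPLE design independently
        adj = {n: set() for n in nodes}
        for u, v in edges:
            adj[u].add(v)
            adj[v].add(u)
        X, y = [], []
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                X.append([1.0, len(adj[u] & adj[v])])
                y.append(dyad(u, v) in edges)
        ref = sm.Logit(np.array(y, float), np.array(X)).fit(disp=0)
        assert np.allclose(model.coefficients, ref.params, atol=1e-5)

    def test_degenerate_layer_flagged(self):
        nodes = ["a", "b", "c"]
        with pytest.warns(UserWarning, match="degenerate"):
            model = fit_ergm(site_from_edges(nodes, set()), terms=("edges",))
        assert model.degenerate
        assert abs(model.coefficients[0]) <= 20


class TestImputeMissing:
    def test_no_missing_dyads_is_identity(self, eight_edge_site):
        model = fit_ergm(eight_edge_site, terms=("edges",))
        imp = impute_missing(eight_edge_site, model, m=3, seed=1)
        for comp in imp.completions:
            assert comp == eight_edge_site

    def test_observed_dyads_never_altered_and_nesting_holds(self):
        from achnet.netbuild import build_networks
        from achnet.synth import SynthConfig, generate_site

        cfg = SynthConfig(site_sizes=(18,), n_steering_per_site=(4,),
                          response_rate=(0.5,), seed=21)
        orgs, _, reports = generate_site(cfg, 0)
        (net,) = build_networks(orgs, reports)
        assert net.missing
        model = fit_ergm(net)
        imp = impute_missing(net, model, m=10, seed=3)
        observed = set(net.grant)
        for comp in imp.completions:
            comp.validate()  # nesting invariants
            assert observed <= comp.grant
            assert (comp.grant - observed) <= set(imp.imputed_dyads)
            assert comp.preexisting <= comp.grant
            assert comp.sustained <= comp.grant

    def test_edges_only_reproduces_observed_density(self):
        """Mean imputed-dyad density over m=200 completions stays within
        3 Monte-Carlo SE of the observed density (Bernoulli oracle)."""
        rng = np.random.default_rng(13)
        nodes, edges = random_edges(rng, 20, 0.35)
        all_pairs = [dyad(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
        half = rng.choice(len(all_pairs), size=len(all_pairs) // 2, replace=False)
        missing = {all_pairs[k] for k in half}
        edges = edges - missing
        net = site_from_edges(nodes, edges, missing=missing)
        observed_dyads = net.possible_dyads - len(missing)
        p = len(net.grant) / observed_dyads
        m = 200
        model = fit_ergm(net, terms=("edges",))
        imp = impute_missing(net, model, m=m, seed=17)
        fractions = [
            sum(1 for pr in imp.imputed_dyads if pr in comp.grant) / len(imp.imputed_dyads)
            for comp in imp.completions
        ]
        mc_se = math.sqrt(p * (1 - p) / (len(missing) * m))
        assert abs(np.mean(fractions) - p) <= 3 * mc_se

    @pytest.mark.parametrize("triangle_update", ["observed", "sequential"])
    def test_triangle_term_raises_transitivity(self, triangle_update):
        """With a positive triangle coefficient, completions are more
        transitive on average than edges-only completions of the same
        input (paired, frozen seed)."""
        rng = np.random.default_rng(29)
        nodes, edges = random_edges(rng, 16, 0.35)
        # make the observed part transitive enough for a positive coefficient
        for tri in [("v0", "v1"), ("v1", "v2"), ("v0", "v2"),
                    ("v3", "v4"), ("v4", "v5"), ("v3", "v5")]:
            edges.add(dyad(*tri))
        all_pairs = [dyad(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
        half = rng.choice(len(all_pairs), size=40, replace=False)
        missing = {all_pairs[k] for k in half}
        edges = edges - missing
        net = site_from_edges(nodes, edges, missing=missing)
        full = fit_ergm(net, terms=("edges", "triangles"))
        assert full.coefficients[1] > 0
        edges_only = fit_ergm(net, terms=("edges",))
        m = 200
        t_full = np.mean([
            transitivity(c.grant)
            for c in impute_missing(net, full, m=m, seed=5,
                                    triangle_update=triangle_update).completions
        ])
        t_edges = np.mean([
            transitivity(c.grant)
            for c in impute_missing(net, edges_only, m=m, seed=5).completions
        ])
        assert t_full >= t_edges

    def test_bad_arguments_rejected(self, eight_edge_site):
        model = fit_ergm(eight_edge_site, terms=("edges",))
        with pytest.raises(ValueError, match="m must be"):
            impute_missing(eight_edge_site, model, m=0, seed=1)
        other = eight_edge_site.copy()
        other.site_id = "other"
        with pytest.raises(ValueError, match="site"):
            impute_missing(other, model, m=2, seed=1)
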