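"""Shared fixtures: small hand-built rosters, reports, and site networks."""

from __future__ import annotations

import numpy as np
import pytest

from achnet.netbuild import EdgeAttrs, SiteNetwork, dyad
from achnet.survey_io import Organization, TieReport


def make_org(org_id, site_id="X", sector="healthcare", integrator=False,
             steering=False, responded=True):
    return Organization(
        org_id=org_id,
        site_id=site_id,
        sector=sector,
        is_integrator=integrator,
        is_steering=steering,
        responded=responded,
    )


def make_attrs(evolution="preexisting", sustain=False, strength=2.0,
               types=("advisory",)):
    return EdgeAttrs(
        evolution=evolution,
        sustain_expected=sustain,
        avg_strength=float(strength),
        types=frozenset(types),
    )


@pytest.fixture
def three_org_roster():
    return [
        make_org("a", integrator=True, sector="public_health"),
        make_org("b", steering=True),
        make_org("c", sector="social_services"),
    ]


@pytest.fixture
def three_org_reports():
    return [
        TieReport("a", "b", frozenset({"advisory"}), 2, "preexisting", True),
        TieReport("b", "a", frozenset({"care_coordination"}), 3, "preexisting", False),
        TieReport("a", "c", frozenset({"data_sharing"}), 1, "stimulated", True),
    ]


@pytest.fixture
def eight_edge_site():
    """A 6-node site with 5 preexisting + 3 stimulated ties, 6 sustained."""
    orgs = [make_org(f"n{i}", site_id="S", integrator=(i == 0)) for i in range(6)]
    pre = [("n0", "n1"), ("n0", "n2"), ("n1", "n2"), ("n2", "n3"), ("n3", "n4")]
    stim = [("n0", "n4"), ("n1", "n4"), ("n4", "n5")]
    sustained = pre[:4] + stim[:2]
    net = SiteNetwork(site_id="S", organizations={o.org_id: o for o in orgs})
    for u, v in pre + stim:
        pair = dyad(u, v)
        evolution = "preexisting" if (u, v) in pre else "stimulated"
        net.grant.add(pair)
        if evolution == "preexisting":
            net.preexisting.add(pair)
        is_sus = (u, v) in sustained
        if is_sus:
            net.sustained.add(pair)
        net.edge_attrs[pair] = make_attrs(
            evolution=evolution, sustain=is_sus, strength=2.0
        )
    return net.validate()


def random_edges(rng: np.random.Generator, n: int, p: float):
    """Random undirected edge set over string node ids v0..v{n-1}."""
    nodes = [f"v{i}" for i in range(n)]
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add(dyad(nodes[i], nodes[j]))
    return nodes, edges
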