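"""Aggregate directed tie reports into per-site layered networks.

Each site's collaboration structure is represented as an undirected graph
over its member organizations with three *nested* edge layers:

* ``preexisting`` — ties that predated the grant,
* ``grant`` — all ties active during the grant period
  (``preexisting`` plus the grant-stimulated ties),
* ``sustained`` — grant-period ties expected to continue after funding.

Aggregation applies the **union rule**: an unordered pair counts as tied if
either endpoint reports the tie in either direction, because false negatives
(forgotten ties) are far more common in roster surveys than false positives.
A pair in which *neither* organization responded carries no information at
all and is recorded as a **missing dyad**, to be multiply imputed downstream
(:mod:`achnet.impute`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from achnet.survey_io import Organization, TieReport, validate_reports, validate_roster

__all__ = [
    "dyad",
    "EdgeAttrs",
    "DyadObservation",
    "SiteNetwork",
    "aggregate_reports",
    "build_site_network",
    "build_networks",
]

Pair = Tuple[str, str]


def dyad(u: str, v: str) -> Pair:
    """Canonical (sorted) unordered pair for two organization ids."""
    if u == v:
        raise ValueError(f"degenerate dyad ({u!r}, {v!r})")
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class EdgeAttrs:
    """Aggregated attributes of one undirected tie."""

    evolution: str  # "preexisting" | "stimulated"
    sustain_expected: bool
    avg_strength: float  # mean of the one or two reported strengths, in [1, 3]
    types: FrozenSet[str]


@dataclass(frozen=True)
class DyadObservation:
    """Observation status of one unordered pair after aggregation.

    ``status`` is ``"tie"`` (at least one endpoint reported the tie),
    ``"no_tie"`` (at least one endpoint responded, none reported it), or
    ``"missing"`` (neither endpoint responded). Attributes are present iff
    ``status == "tie"``.
    """

    pair: Pair
    status: str
    attrs: Optional[EdgeAttrs] = None

    def __post_init__(self) -> None:
        if self.status not in ("tie", "no_tie", "missing"):
            raise ValueError(f"unknown status {self.status!r}")
        if (self.attrs is not None) != (self.status == "tie"):
            raise ValueError("attrs must be present exactly when status is 'tie'")


@dataclass
class SiteNetwork:
    """One site's undirected network with nested edge layers.

    Invariants (checked by :meth:`validate`): ``preexisting`` and
    ``sustained`` are subsets of ``grant``; the missing mask is disjoint
    from the grant layer; every grant edge has attributes.
    """

    site_id: str
    organizations: Dict[str, Organization]
    preexisting: Set[Pair] = field(default_factory=set)
    grant: Set[Pair] = field(default_factory=set)
    sustained: Set[Pair] = field(default_factory=set)
    missing: Set[Pair] = field(default_factory=set)
    edge_attrs: Dict[Pair, EdgeAttrs] = field(default_factory=dict)

    @property
    def nodes(self) -> List[str]:
        return list(self.organizations)

    @property
    def n(self) -> int:
        return len(self.organizations)

    @property
    def possible_dyads(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def stimulated(self) -> Set[Pair]:
        """Grant-period ties that did not preexist the grant."""
        return self.grant - self.preexisting

    def layer(self, name: str) -> Set[Pair]:
        try:
            return {"preexisting": self.preexisting, "grant": self.grant,
                    "sustained": self.sustained}[name]
        except KeyError:
            raise ValueError(f"unknown layer {name!r}") from None

    def validate(self) -> "SiteNetwork":
        if not self.preexisting <= self.grant:
            raise ValueError(f"site {self.site_id}: preexisting not nested in grant")
        if not self.sustained <= self.grant:
            raise ValueError(f"site {self.site_id}: sustained not nested in grant")
        if self.missing & self.grant:
            raise ValueError(f"site {self.site_id}: missing mask overlaps grant edges")
        node_set = set(self.organizations)
        for pair in self.grant | self.missing:
            if not set(pair) <= node_set:
                raise ValueError(f"site {self.site_id}: edge {pair} off the roster")
        if set(self.edge_attrs) != self.grant:
            raise ValueError(f"site {self.site_id}: edge_attrs keys != grant layer")
        return self

    def copy(self) -> "SiteNetwork":
        return SiteNetwork(
            site_id=self.site_id,
            organizations=dict(self.organizations),
            preexisting=set(self.preexisting),
            grant=set(self.grant),
            sustained=set(self.sustained),
            missing=set(self.missing),
            edge_attrs=dict(self.edge_attrs),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SiteNetwork):
            return NotImplemented
        return (
            self.site_id == other.site_id
            and self.organizations == other.organizations
            and self.preexisting == other.preexisting
            and self.grant == other.grant
            and self.sustained == other.sustained
            and self.missing == other.missing
            and self.edge_attrs == other.edge_attrs
        )


def aggregate_reports(
    organizations: Sequence[Organization],
    tie_reports: Sequence[TieReport],
    sustain_rule: str = "any",
) -> List[DyadObservation]:
    """Collapse directed reports into per-dyad observations for one site.

    Union rule: a pair is a tie if either endpoint reported it in either
    direction. Neither endpoint responding makes the dyad ``missing``.
    Attribute conflicts between the (at most two) reports on a pair resolve
    as: ``avg_strength`` = mean of reported strengths; ``types`` = union;
    ``evolution`` = ``"preexisting"`` if *any* reporter says preexisting
    (a tie one partner knew before the grant cannot have been stimulated by
    it); ``sustain_expected`` follows ``sustain_rule`` — ``"any"`` (default,
    one optimistic partner suffices) or ``"all"`` (every reporter of the tie
    must expect continuation).
    """
    if sustain_rule not in ("any", "all"):
        raise ValueError(f"sustain_rule must be 'any' or 'all', got {sustain_rule!r}")
    validate_roster(organizations)
    validate_reports(organizations, tie_reports)
    sites = {o.site_id for o in organizations}
    if len(sites) != 1:
        raise ValueError(
            f"aggregate_reports expects a single site's roster, got sites {sorted(sites)}"
        )
    responded = {o.org_id for o in organizations if o.responded}
    by_pair: Dict[Pair, List[TieReport]] = {}
    for rep in tie_reports:
        by_pair.setdefault(dyad(rep.reporter, rep.target), []).append(rep)

    observations: List[DyadObservation] = []
    ids = sorted(o.org_id for o in organizations)
    for i, u in enumerate(ids):
        for v in ids[i + 1:]:
            pair = (u, v)
            reps = by_pair.get(pair, [])
            if reps:
                strengths = [r.strength for r in reps]
                types = frozenset().union(*(r.types for r in reps))
                evolution = (
                    "preexisting"
                    if any(r.evolution == "preexisting" for r in reps)
                    else "stimulated"
                )
                agg = any if sustain_rule == "any" else all
                sustain = agg(r.sustain_expected for r in reps)
                observations.append(
                    DyadObservation(
                        pair=pair,
                        status="tie",
                        attrs=EdgeAttrs(
                            evolution=evolution,
                            sustain_expected=sustain,
                            avg_strength=sum(strengths) / len(strengths),
                            types=types,
                        ),
                    )
                )
            elif u not in responded and v not in responded:
                observations.append(DyadObservation(pair=pair, status="missing"))
            else:
                observations.append(DyadObservation(pair=pair, status="no_tie"))
    return observations


def build_site_network(
    observations: Sequence[DyadObservation],
    organizations: Sequence[Organization],
) -> SiteNetwork:
    """Assemble one site's :class:`SiteNetwork` from dyad observations.

    The grant layer holds every tie dyad; the preexisting layer those whose
    aggregated evolution is ``"preexisting"``; the sustained layer those
    with ``sustain_expected``. Nesting holds by construction.
    """
    sites = {o.site_id for o in organizations}
    if len(sites) != 1:
        raise ValueError(f"expected one site, got {sorted(sites)}")
    net = SiteNetwork(
        site_id=sites.pop(),
        organizations={o.org_id: o for o in sorted(organizations, key=lambda o: o.org_id)},
    )
    for obs in observations:
        if obs.status == "tie":
            net.grant.add(obs.pair)
            net.edge_attrs[obs.pair] = obs.attrs
            if obs.attrs.evolution == "preexisting":
                net.preexisting.add(obs.pair)
            if obs.attrs.sustain_expected:
                net.sustained.add(obs.pair)
        elif obs.status == "missing":
            net.missing.add(obs.pair)
    return net.validate()


def build_networks(
    organizations: Sequence[Organization],
    tie_reports: Sequence[TieReport],
    sustain_rule: str = "any",
) -> List[SiteNetwork]:
    """Aggregate and build a :class:`SiteNetwork` for every site present."""
    validate_roster(organizations)
    validate_reports(organizations, tie_reports)
    by_site: Dict[str, List[Organization]] = {}
    for org in organizations:
        by_site.setdefault(org.site_id, []).append(org)
    reports_by_site: Dict[str, List[TieReport]] = {s: [] for s in by_site}
    org_site = {o.org_id: o.site_id for o in organizations}
    for rep in tie_reports:
        reports_by_site[org_site[rep.reporter]].append(rep)
    networks = []
    for site_id in sorted(by_site):
        obs = aggregate_reports(
            by_site[site_id], reports_by_site[site_id], sustain_rule=sustain_rule
        )
        networks.append(build_site_network(obs, by_site[site_id]))
    return networks
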