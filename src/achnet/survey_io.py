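"""Read, write, and validate roster-survey artifacts.

A coalition survey presents each responding organization with a roster of
all member organizations at its site and asks it to characterize every
collaboration it has: which of four collaborative activities it involves,
how strong the relationship is (a trust/maturity ordinal), whether the tie
predated the grant or was stimulated by it, and whether it is expected to
continue after funding ends.

Two tabular artifacts are exchanged:

``organizations.csv``
    one row per organization: ``org_id, site_id, sector, is_integrator,
    is_steering, responded``.
``reports.csv``
    one row per directed tie claim: ``reporter_id, target_id, advisory,
    care_coordination, data_sharing, resource_sharing, strength, evolution,
    sustain_expected``.

Reports are *directed claims*; symmetrization into undirected dyads is the
job of :mod:`achnet.netbuild`, not of this module.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "SECTORS",
    "COLLAB_TYPES",
    "STRENGTH_ALIASES",
    "Organization",
    "TieReport",
    "SurveyValidationError",
    "load_survey",
    "write_survey",
    "write_networks",
    "read_networks",
]

#: Sector affiliations recognized for coalition member organizations.
SECTORS = (
    "healthcare",
    "public_health",
    "social_services",
    "government",
    "insurer",
    "community_action",
    "other",
)

#: The four collaborative activities a tie can involve.
COLLAB_TYPES = ("advisory", "care_coordination", "data_sharing", "resource_sharing")

#: Accepted spellings for the 1-3 relationship-strength ordinal
#: (1 = little trust / new relationship, 3 = high trust / strong relationship).
STRENGTH_ALIASES = {
    "1": 1,
    "2": 2,
    "3": 3,
    "new": 1,
    "developing": 2,
    "strong": 3,
}

EVOLUTIONS = ("preexisting", "stimulated")


class SurveyValidationError(ValueError):
    """Raised when survey tables violate the roster schema."""


@dataclass(frozen=True)
class Organization:
    """A coalition member organization (a network node).

    ``is_integrator`` marks the site's lead facilitating organization
    (exactly one per site); ``is_steering`` marks membership of the site's
    decision-making steering committee. ``responded`` records whether the
    organization completed the survey — non-respondents can still appear as
    targets of other organizations' reports.
    """

    org_id: str
    site_id: str
    sector: str
    is_integrator: bool = False
    is_steering: bool = False
    responded: bool = True

    def __post_init__(self) -> None:
        if self.sector not in SECTORS:
            raise SurveyValidationError(
                f"organization {self.org_id!r}: unknown sector {self.sector!r}"
            )


@dataclass(frozen=True)
class TieReport:
    """One respondent's directed characterization of one collaboration.

    ``types`` is the non-empty subset of :data:`COLLAB_TYPES` the reporter
    selected; ``strength`` is the 1-3 trust ordinal; ``evolution`` says
    whether the reporter considers the tie to predate the grant
    (``"preexisting"``) or to have been stimulated by it (``"stimulated"``);
    ``sustain_expected`` is the reporter's projection that the collaboration
    continues beyond the funding period.
    """

    reporter: str
    target: str
    types: frozenset = field(default_factory=frozenset)
    strength: int = 2
    evolution: str = "preexisting"
    sustain_expected: bool = False

    def __post_init__(self) -> None:
        if self.reporter == self.target:
            raise SurveyValidationError(
                f"self-report: {self.reporter!r} reporting a tie to itself"
            )
        if not self.types:
            raise SurveyValidationError(
                f"report {self.reporter!r}->{self.target!r}: empty collaboration types"
            )
        bad = set(self.types) - set(COLLAB_TYPES)
        if bad:
            raise SurveyValidationError(
                f"report {self.reporter!r}->{self.target!r}: unknown types {sorted(bad)}"
            )
        if self.strength not in (1, 2, 3):
            raise SurveyValidationError(
                f"report {self.reporter!r}->{self.target!r}: strength must be 1-3, "
                f"got {self.strength!r}"
            )
        if self.evolution not in EVOLUTIONS:
            raise SurveyValidationError(
                f"report {self.reporter!r}->{self.target!r}: evolution must be one of "
                f"{EVOLUTIONS}, got {self.evolution!r}"
            )


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n", ""):
        return False
    raise SurveyValidationError(f"cannot parse boolean value {value!r}")


def _parse_strength(value) -> int:
    s = str(value).strip().lower()
    try:
        return STRENGTH_ALIASES[s]
    except KeyError:
        raise SurveyValidationError(
            f"unknown strength {value!r}; expected 1/2/3 or new/developing/strong"
        ) from None


ORG_COLUMNS = ["org_id", "site_id", "sector", "is_integrator", "is_steering", "responded"]
REPORT_COLUMNS = [
    "reporter_id",
    "target_id",
    "advisory",
    "care_coordination",
    "data_sharing",
    "resource_sharing",
    "strength",
    "evolution",
    "sustain_expected",
]


def validate_roster(organizations: Sequence[Organization]) -> None:
    """Check roster-level invariants: unique ids, one integrator per site."""
    seen: set = set()
    for org in organizations:
        key = org.org_id
        if key in seen:
            raise SurveyValidationError(f"duplicate org_id {org.org_id!r}")
        seen.add(key)
    sites: dict = {}
    for org in organizations:
        sites.setdefault(org.site_id, []).append(org)
    for site_id, orgs in sites.items():
        n_int = sum(o.is_integrator for o in orgs)
        if n_int != 1:
            raise SurveyValidationError(
                f"site {site_id!r}: expected exactly one integrator organization, "
                f"found {n_int}"
            )


def validate_reports(
    organizations: Sequence[Organization], reports: Sequence[TieReport]
) -> None:
    """Check reports against the roster: referential integrity, respondent
    provenance, within-site endpoints, no duplicate (reporter, target) rows."""
    index = {o.org_id: o for o in organizations}
    seen_pairs: set = set()
    dupes = []
    for i, rep in enumerate(reports):
        for endpoint in (rep.reporter, rep.target):
            if endpoint not in index:
                raise SurveyValidationError(
                    f"report row {i}: org {endpoint!r} not in roster"
                )
        reporter = index[rep.reporter]
        target = index[rep.target]
        if not reporter.responded:
            raise SurveyValidationError(
                f"report row {i}: reporter {rep.reporter!r} is marked as a "
                "non-respondent"
            )
        if reporter.site_id != target.site_id:
            raise SurveyValidationError(
                f"report row {i}: endpoints {rep.reporter!r} (site "
                f"{reporter.site_id!r}) and {rep.target!r} (site {target.site_id!r}) "
                "span sites"
            )
        key = (rep.reporter, rep.target)
        if key in seen_pairs:
            dupes.append(key)
        seen_pairs.add(key)
    if dupes:
        raise SurveyValidationError(
            f"duplicate (reporter, target) rows: {sorted(set(dupes))}"
        )


def load_survey(org_path, report_path):
    """Load and validate the organization roster and tie reports.

    Returns ``(organizations, tie_reports)`` as lists of
    :class:`Organization` and :class:`TieReport`. Strength accepts the
    string aliases ``new``/``developing``/``strong`` for 1/2/3.
    """
    org_df = pd.read_csv(org_path, dtype=str, keep_default_na=False)
    missing_cols = set(ORG_COLUMNS) - set(org_df.columns)
    if missing_cols:
        raise SurveyValidationError(
            f"{org_path}: missing columns {sorted(missing_cols)}"
        )
    organizations = [
        Organization(
            org_id=row["org_id"],
            site_id=row["site_id"],
            sector=row["sector"],
            is_integrator=_parse_bool(row["is_integrator"]),
            is_steering=_parse_bool(row["is_steering"]),
            responded=_parse_bool(row["responded"]),
        )
        for row in org_df.to_dict("records")
    ]
    validate_roster(organizations)

    rep_df = pd.read_csv(report_path, dtype=str, keep_default_na=False)
    missing_cols = set(REPORT_COLUMNS) - set(rep_df.columns)
    if missing_cols:
        raise SurveyValidationError(
            f"{report_path}: missing columns {sorted(missing_cols)}"
        )
    reports = []
    for row in rep_df.to_dict("records"):
        types = frozenset(t for t in COLLAB_TYPES if _parse_bool(row[t]))
        reports.append(
            TieReport(
                reporter=row["reporter_id"],
                target=row["target_id"],
                types=types,
                strength=_parse_strength(row["strength"]),
                evolution=str(row["evolution"]).strip().lower(),
                sustain_expected=_parse_bool(row["sustain_expected"]),
            )
        )
    validate_reports(organizations, reports)
    return organizations, reports


def write_survey(organizations, reports, org_path, report_path) -> None:
    """Write roster and reports in the schema :func:`load_survey` reads."""
    org_df = pd.DataFrame(
        [
            {
                "org_id": o.org_id,
                "site_id": o.site_id,
                "sector": o.sector,
                "is_integrator": int(o.is_integrator),
                "is_steering": int(o.is_steering),
                "responded": int(o.responded),
            }
            for o in organizations
        ],
        columns=ORG_COLUMNS,
    )
    org_df.to_csv(org_path, index=False)
    rep_df = pd.DataFrame(
        [
            {
                "reporter_id": r.reporter,
                "target_id": r.target,
                **{t: int(t in r.types) for t in COLLAB_TYPES},
                "strength": r.strength,
                "evolution": r.evolution,
                "sustain_expected": int(r.sustain_expected),
            }
            for r in reports
        ],
        columns=REPORT_COLUMNS,
    )
    rep_df.to_csv(report_path, index=False)


# ---------------------------------------------------------------------------
# network serialization

EDGE_COLUMNS = [
    "u",
    "v",
    "preexisting",
    "grant",
    "sustained",
    "evolution",
    "sustain_expected",
    "avg_strength",
] + list(COLLAB_TYPES)


def write_networks(networks, path) -> None:
    """Serialize per-site layered networks to ``path``.

    For each site writes ``site_<id>_edges.csv`` (one row per grant-layer
    edge with layer flags and edge attributes), ``site_<id>_missing.csv``
    (the missing-dyad mask), and ``site_<id>.graphml`` (grant-layer graph
    with node attributes). Round-trips losslessly through
    :func:`read_networks`.
    """
    path = Path(path)
    os.makedirs(path, exist_ok=True)
    for net in networks:
        rows = []
        for pair in sorted(net.grant):
            attrs = net.edge_attrs[pair]
            rows.append(
                {
                    "u": pair[0],
                    "v": pair[1],
                    "preexisting": int(pair in net.preexisting),
                    "grant": 1,
                    "sustained": int(pair in net.sustained),
                    "evolution": attrs.evolution,
                    "sustain_expected": int(attrs.sustain_expected),
                    "avg_strength": attrs.avg_strength,
                    **{t: int(t in attrs.types) for t in COLLAB_TYPES},
                }
            )
        pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(
            path / f"site_{net.site_id}_edges.csv", index=False
        )
        pd.DataFrame(sorted(net.missing), columns=["u", "v"]).to_csv(
            path / f"site_{net.site_id}_missing.csv", index=False
        )
        g = nx.Graph()
        for org in net.organizations.values():
            g.add_node(
                org.org_id,
                site_id=org.site_id,
                sector=org.sector,
                is_integrator=int(org.is_integrator),
                is_steering=int(org.is_steering),
                responded=int(org.responded),
            )
        g.add_edges_from(net.grant)
        nx.write_graphml(g, path / f"site_{net.site_id}.graphml")


def read_networks(path):
    """Read back the file set written by :func:`write_networks`."""
    from achnet.netbuild import EdgeAttrs, SiteNetwork, dyad

    path = Path(path)
    networks = []
    for gml in sorted(path.glob("site_*.graphml")):
        site_id = gml.stem[len("site_"):]
        g = nx.read_graphml(gml)
        organizations = {
            node: Organization(
                org_id=node,
                site_id=data["site_id"],
                sector=data["sector"],
                is_integrator=bool(int(data["is_integrator"])),
                is_steering=bool(int(data["is_steering"])),
                responded=bool(int(data["responded"])),
            )
            for node, data in sorted(g.nodes(data=True))
        }
        edges = pd.read_csv(path / f"site_{site_id}_edges.csv", dtype=str)
        preexisting, grant, sustained, edge_attrs = set(), set(), set(), {}
        for row in edges.to_dict("records"):
            pair = dyad(row["u"], row["v"])
            grant.add(pair)
            if int(row["preexisting"]):
                preexisting.add(pair)
            if int(row["sustained"]):
                sustained.add(pair)
            edge_attrs[pair] = EdgeAttrs(
                evolution=row["evolution"],
                sustain_expected=bool(int(row["sustain_expected"])),
                avg_strength=float(row["avg_strength"]),
                types=frozenset(t for t in COLLAB_TYPES if int(row[t])),
            )
        miss_df = pd.read_csv(path / f"site_{site_id}_missing.csv", dtype=str)
        missing = {dyad(r["u"], r["v"]) for r in miss_df.to_dict("records")}
        networks.append(
            SiteNetwork(
                site_id=site_id,
                organizations=organizations,
                preexisting=preexisting,
                grant=grant,
                sustained=sustained,
                missing=missing,
                edge_attrs=edge_attrs,
            )
        )
    return networks
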