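"""Synthetic multi-site coalition survey generator.

Real coalition roster surveys are rarely released, so every downstream
stage of this package is exercised against synthetic data whose generative
parameters are known exactly. The generator emulates a seven-site Iowa-style
ACH coalition (roster sizes 11-36, response rates ~38-58%, one integrator
organization and a small steering committee per site) and produces, per
site:

1. a **preexisting** collaboration layer from a Bernoulli graph with a
   sector-homophily term and a triangle-closure bonus applied in a single
   Gibbs pass over dyads (cheap, reproducible, and enough to induce the
   nonzero transitivity real coalition networks show);
2. **stimulated** ties drawn per non-preexisting dyad from a logistic model
   in dyad covariates computed on the preexisting layer (degree sum,
   harmonic-closeness difference, sector concordance, governance roles) —
   exactly the covariates of the stimulated LNRM, so the fitted model is
   well-specified and parameter recovery is a meaningful test;
3. a **sustained** label per grant-period tie from a logistic model on
   grant-layer covariates plus relationship strength, the stimulated
   indicator, and the four collaboration types;
4. directed :class:`~achnet.survey_io.TieReport` rows emitted only by the
   responding organizations, one per incident true tie (no false-positive
   reports; an optional false-negative rate defaults to 0).

Respondents are drawn as a fixed count ``round(response_rate x n)`` without
replacement, matching the exact per-site response rates coalition studies
report and making missing-dyad fractions reproducible.

Default true log-odds coefficients are the published coalition-study
effect sizes (e.g. 1.157 odds per unit degree sum for stimulation, 1.881
per strength level for sustainment); intercepts are calibrated so synthetic
site summaries (densities ~0.15-0.5, transitivity ~0.3-0.6, tens of
stimulated ties per site) fall in the reported ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from achnet import reference
from achnet.netbuild import EdgeAttrs, SiteNetwork, dyad
from achnet.netstats import closeness_vector, degree_vector
from achnet.survey_io import COLLAB_TYPES, SECTORS, Organization, TieReport

__all__ = [
    "SynthConfig",
    "DEFAULT_STIM_COEFS",
    "DEFAULT_SUSTAIN_COEFS",
    "generate_site",
    "generate_study",
    "perturb_recall",
    "true_coefficients",
    "recall_error_sensitivity",
]

#: True stimulated-model log-odds: published effect sizes, calibrated intercept.
DEFAULT_STIM_COEFS: Dict[str, float] = {
    "intercept": -5.3,
    "sum_degree": math.log(1.157),
    "abs_closeness_diff": math.log(1.092),
    "same_sector": math.log(1.259),
    "integrator_in_dyad": math.log(2.715),
    "steering_both": math.log(13.860),
    "steering_one": math.log(3.226),
}

#: True sustained-model log-odds.
DEFAULT_SUSTAIN_COEFS: Dict[str, float] = {
    "intercept": -3.2,
    "sum_degree": math.log(1.062),
    "abs_closeness_diff": math.log(1.054),
    "same_sector": math.log(1.440),
    "integrator_in_dyad": math.log(1.217),
    "steering_both": math.log(0.887),
    "steering_one": math.log(1.230),
    "avg_strength": math.log(1.881),
    "stimulated": math.log(0.695),
    "advisory": math.log(1.534),
    "care_coordination": math.log(1.264),
    "data_sharing": math.log(2.129),
    "resource_sharing": math.log(2.164),
}

DEFAULT_SECTOR_PROBS: Dict[str, float] = {
    "healthcare": 0.30,
    "public_health": 0.12,
    "social_services": 0.22,
    "government": 0.12,
    "insurer": 0.05,
    "community_action": 0.09,
    "other": 0.10,
}

#: Preexisting-layer generator: baseline log-odds, sector-homophily log-odds,
#: and triangle-closure bonus per shared neighbor (one Gibbs pass).
DEFAULT_PREEXIST_PARAMS: Dict[str, float] = {
    "baseline": -2.3,
    "homophily": 0.7,
    "closure": 1.0,
}


def _check_prob_vector(name: str, probs: Sequence[float]) -> None:
    total = float(sum(probs))
    if abs(total - 1.0) > 1e-12:
        raise ValueError(f"{name} must sum to 1, got {total!r}")
    if any(p < 0 for p in probs):
        raise ValueError(f"{name} has negative entries")


@dataclass
class SynthConfig:
    """Study conditions for the synthetic coalition generator.

    Defaults mirror the seven published Iowa ACH sites: roster sizes,
    response rates, and steering-committee sizes per site, with exactly one
    integrator organization per site. ``response_rate`` and
    ``n_steering_per_site`` accept either one value for all sites or a
    per-site sequence. ``recall_error_rate`` is the fraction of preexisting
    ties whose evolution is misreported as stimulated in the emitted survey
    (the truth network is unaffected).
    """

    site_sizes: Tuple[int, ...] = reference.SITE_SIZES
    sector_probs: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SECTOR_PROBS)
    )
    n_steering_per_site: Sequence[int] = reference.STEERING_COUNTS
    response_rate: Sequence[float] = reference.RESPONSE_RATES
    preexist_params: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREEXIST_PARAMS)
    )
    stim_coefs: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STIM_COEFS)
    )
    sustain_coefs: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUSTAIN_COEFS)
    )
    strength_probs: Tuple[float, float, float] = (0.25, 0.45, 0.30)
    type_probs: Dict[str, float] = field(
        default_factory=lambda: {
            "advisory": 0.55,
            "care_coordination": 0.50,
            "data_sharing": 0.35,
            "resource_sharing": 0.35,
        }
    )
    recall_error_rate: float = 0.0
    false_negative_rate: float = 0.0
    seed: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.site_sizes)

    def site_id(self, site_index: int) -> str:
        if site_index < 26:
            return chr(ord("A") + site_index)
        return f"S{site_index}"

    def _per_site(self, value, site_index: int):
        if np.isscalar(value):
            return value
        return value[site_index]

    def validate(self) -> "SynthConfig":
        if any(n < 3 for n in self.site_sizes):
            raise ValueError(f"site sizes must be >= 3, got {self.site_sizes}")
        if set(self.sector_probs) - set(SECTORS):
            raise ValueError("sector_probs has unknown sectors")
        _check_prob_vector("sector_probs", list(self.sector_probs.values()))
        _check_prob_vector("strength_probs", self.strength_probs)
        for name, coefs in (("stim_coefs", self.stim_coefs),
                            ("sustain_coefs", self.sustain_coefs),
                            ("preexist_params", self.preexist_params)):
            if not all(np.isfinite(v) for v in coefs.values()):
                raise ValueError(f"non-finite coefficients in {name}")
        for t, p in self.type_probs.items():
            if t not in COLLAB_TYPES or not 0 <= p <= 1:
                raise ValueError(f"bad type_probs entry {t!r}: {p!r}")
        rates = (
            [self.response_rate] if np.isscalar(self.response_rate)
            else list(self.response_rate)
        )
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("response_rate must lie in [0, 1]")
        if not 0 <= self.recall_error_rate <= 0.5:
            raise ValueError("recall_error_rate must lie in [0, 0.5]")
        if not 0 <= self.false_negative_rate < 1:
            raise ValueError("false_negative_rate must lie in [0, 1)")
        return self


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_preexisting(
    rng: np.random.Generator, same_sector: np.ndarray, params: Dict[str, float]
) -> np.ndarray:
    """Bernoulli graph with homophily, then one Gibbs pass adding the
    triangle-closure bonus per shared neighbor."""
    n = same_sector.shape[0]
    base, homo, closure = params["baseline"], params["homophily"], params["closure"]
    iu, ju = np.triu_indices(n, 1)
    eta0 = base + homo * same_sector[iu, ju]
    adj = np.zeros((n, n), dtype=np.int8)
    draws = rng.random(len(iu)) < 1.0 / (1.0 + np.exp(-eta0))
    adj[iu[draws], ju[draws]] = 1
    adj |= adj.T
    order = rng.permutation(len(iu))
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        adj[i, j] = adj[j, i] = 0
        common = float(adj[i] @ adj[j])
        eta = base + homo * same_sector[i, j] + closure * common
        if rng.random() < _sigmoid(eta):
            adj[i, j] = adj[j, i] = 1
    return adj


def _dyad_x(coefs, orgs_i, orgs_j, deg, clo, i, j, extra=None) -> float:
    n_steer = int(orgs_i.is_steering) + int(orgs_j.is_steering)
    eta = (
        coefs["intercept"]
        + coefs["sum_degree"] * (deg[i] + deg[j])
        + coefs["abs_closeness_diff"] * abs(clo[i] - clo[j])
        + coefs["same_sector"] * (orgs_i.sector == orgs_j.sector)
        + coefs["integrator_in_dyad"] * (orgs_i.is_integrator or orgs_j.is_integrator)
        + coefs["steering_both"] * (n_steer == 2)
        + coefs["steering_one"] * (n_steer == 1)
    )
    if extra:
        for name, value in extra.items():
            eta += coefs[name] * value
    return eta


def generate_site(
    config: SynthConfig, site_index: int
) -> Tuple[List[Organization], SiteNetwork, List[TieReport]]:
    """Generate one site: roster, complete true network, and the survey
    reports the responding organizations would file.

    Deterministic in ``(config.seed, site_index)``; sites are mutually
    independent given the seed.
    """
    config.validate()
    if not 0 <= site_index < config.n_sites:
        raise ValueError(f"site_index {site_index} out of range")
    rng = np.random.default_rng([config.seed, site_index])
    site_id = config.site_id(site_index)
    n = config.site_sizes[site_index]
    n_steer = int(config._per_site(config.n_steering_per_site, site_index))
    rate = float(config._per_site(config.response_rate, site_index))

    # roster: org 0 is the integrator (a public-health lead, as in ACH
    # governance); steering members drawn among the rest
    sectors = list(config.sector_probs)
    probs = np.array([config.sector_probs[s] for s in sectors])
    drawn = rng.choice(len(sectors), size=n, p=probs)
    steering = set(1 + rng.choice(n - 1, size=min(n_steer, n - 1), replace=False))
    n_resp = round(rate * n)
    responders = set(rng.choice(n, size=n_resp, replace=False))
    orgs = [
        Organization(
            org_id=f"{site_id}{i:02d}",
            site_id=site_id,
            sector="public_health" if i == 0 else sectors[drawn[i]],
            is_integrator=(i == 0),
            is_steering=(i in steering),
            responded=(i in responders),
        )
        for i in range(n)
    ]
    ids = [o.org_id for o in orgs]

    same_sector = np.equal.outer(
        np.array([o.sector for o in orgs]), np.array([o.sector for o in orgs])
    ).astype(float)
    pre_adj = _draw_preexisting(rng, same_sector, config.preexist_params)
    pre_edges = {
        dyad(ids[i], ids[j]) for i, j in zip(*np.nonzero(np.triu(pre_adj, 1)))
    }

    deg_pre = degree_vector(pre_edges, ids)
    clo_pre = closeness_vector(pre_edges, ids)
    stim_edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            pair = dyad(ids[i], ids[j])
            if pair in pre_edges:
                continue
            eta = _dyad_x(config.stim_coefs, orgs[i], orgs[j], deg_pre, clo_pre, i, j)
            if rng.random() < _sigmoid(eta):
                stim_edges.add(pair)

    grant = pre_edges | stim_edges
    strengths = {
        pair: int(1 + rng.choice(3, p=np.asarray(config.strength_probs)))
        for pair in sorted(grant)
    }
    types: Dict = {}
    argmax_type = max(config.type_probs, key=config.type_probs.get)
    for pair in sorted(grant):
        ts = frozenset(
            t for t in COLLAB_TYPES if rng.random() < config.type_probs[t]
        )
        types[pair] = ts if ts else frozenset([argmax_type])

    deg_g = degree_vector(grant, ids)
    clo_g = closeness_vector(grant, ids)
    idx = {org_id: i for i, org_id in enumerate(ids)}
    sustained = set()
    edge_attrs = {}
    for pair in sorted(grant):
        i, j = idx[pair[0]], idx[pair[1]]
        extra = {
            "avg_strength": float(strengths[pair]),
            "stimulated": float(pair in stim_edges),
            **{t: float(t in types[pair]) for t in COLLAB_TYPES},
        }
        eta = _dyad_x(config.sustain_coefs, orgs[i], orgs[j], deg_g, clo_g, i, j, extra)
        is_sus = rng.random() < _sigmoid(eta)
        if is_sus:
            sustained.add(pair)
        edge_attrs[pair] = EdgeAttrs(
            evolution="stimulated" if pair in stim_edges else "preexisting",
            sustain_expected=is_sus,
            avg_strength=float(strengths[pair]),
            types=types[pair],
        )

    truth = SiteNetwork(
        site_id=site_id,
        organizations={o.org_id: o for o in orgs},
        preexisting=pre_edges,
        grant=grant,
        sustained=sustained,
        missing=set(),
        edge_attrs=edge_attrs,
    ).validate()

    # survey emission: reported evolution may carry recall error at the
    # edge level (both endpoints misremember consistently)
    reported_evolution = {
        pair: attrs.evolution for pair, attrs in edge_attrs.items()
    }
    if config.recall_error_rate > 0:
        pre_sorted = sorted(pre_edges)
        n_flip = round(config.recall_error_rate * len(pre_sorted))
        if n_flip:
            flip_idx = rng.choice(len(pre_sorted), size=n_flip, replace=False)
            for k in flip_idx:
                reported_evolution[pre_sorted[k]] = "stimulated"

    reports: List[TieReport] = []
    for o in orgs:
        if not o.responded:
            continue
        for pair in sorted(grant):
            if o.org_id not in pair:
                continue
            if config.false_negative_rate and rng.random() < config.false_negative_rate:
                continue
            target = pair[0] if pair[1] == o.org_id else pair[1]
            attrs = edge_attrs[pair]
            reports.append(
                TieReport(
                    reporter=o.org_id,
                    target=target,
                    types=attrs.types,
                    strength=strengths[pair],
                    evolution=reported_evolution[pair],
                    sustain_expected=attrs.sustain_expected,
                )
            )
    return orgs, truth, reports


def generate_study(
    config: SynthConfig,
) -> Tuple[List[Organization], List[SiteNetwork], List[TieReport]]:
    """Generate all sites of the study; concatenated rosters and reports
    plus the list of complete true site networks."""
    orgs_all: List[Organization] = []
    truths: List[SiteNetwork] = []
    reports_all: List[TieReport] = []
    for s in range(config.n_sites):
        orgs, truth, reports = generate_site(config, s)
        orgs_all.extend(orgs)
        truths.append(truth)
        reports_all.extend(reports)
    return orgs_all, truths, reports_all


def perturb_recall(
    reports: Sequence[TieReport], rate: float, rng: np.random.Generator
) -> List[TieReport]:
    """Flip the evolution label preexisting -> stimulated for a fraction
    ``rate`` of the distinct preexisting-reported edges (all reports of a
    flipped edge change consistently)."""
    if not 0 <= rate <= 0.5:
        raise ValueError("rate must lie in [0, 0.5]")
    pre_pairs = sorted(
        {dyad(r.reporter, r.target) for r in reports if r.evolution == "preexisting"}
    )
    n_flip = round(rate * len(pre_pairs))
    flipped = set()
    if n_flip:
        flip_idx = rng.choice(len(pre_pairs), size=n_flip, replace=False)
        flipped = {pre_pairs[k] for k in flip_idx}
    out = []
    for r in reports:
        if r.evolution == "preexisting" and dyad(r.reporter, r.target) in flipped:
            out.append(replace(r, evolution="stimulated"))
        else:
            out.append(r)
    return out


def true_coefficients(config: SynthConfig, model: str) -> pd.Series:
    """Generating log-odds coefficients aligned with the index of a fitted
    :class:`~achnet.lnrm.LnrmFit` for ``model`` ("stimulated" or
    "sustained"): every ``site[...]`` entry equals the shared intercept."""
    coefs = config.stim_coefs if model == "stimulated" else config.sustain_coefs
    if model not in ("stimulated", "sustained"):
        raise ValueError(f"unknown model {model!r}")
    entries = {
        f"site[{config.site_id(s)}]": coefs["intercept"]
        for s in range(config.n_sites)
    }
    entries.update({k: v for k, v in coefs.items() if k != "intercept"})
    return pd.Series(entries)


def recall_error_sensitivity(
    config: SynthConfig,
    n_reps: int,
    seed: int,
    m_imputations: int = 5,
    gibbs_sweeps: int = 10,
) -> pd.DataFrame:
    """Sensitivity of both LNRMs to recall error in the evolution labels.

    Per replicate: generate a study, fit both models on the unperturbed
    reports, flip the evolution label of ``config.recall_error_rate`` of the
    preexisting-reported edges, refit, and record per-coefficient
    deviations. Returns one row per (model, coefficient) with the mean
    absolute deviation and the fraction of replicates whose coefficient
    sign matches the unperturbed fit.
    """
    from achnet.report import fit_models

    config.validate()
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 to estimate variability")
    records: Dict[Tuple[str, str], List[float]] = {}
    signs: Dict[Tuple[str, str], List[bool]] = {}
    for rep in range(n_reps):
        rep_seed = int(np.random.default_rng([seed, rep]).integers(2**31 - 1))
        cfg = replace(config, seed=rep_seed, recall_error_rate=0.0)
        orgs, _, reports = generate_study(cfg)
        base = fit_models(
            orgs, reports, m_imputations=m_imputations,
            gibbs_sweeps=gibbs_sweeps, seed=rep_seed,
        )
        rng = np.random.default_rng([seed, rep, 1])
        perturbed_reports = perturb_recall(reports, config.recall_error_rate, rng)
        pert = fit_models(
            orgs, perturbed_reports, m_imputations=m_imputations,
            gibbs_sweeps=gibbs_sweeps, seed=rep_seed,
        )
        for model in ("stimulated", "sustained"):
            b, p = base[model].params, pert[model].params
            for name in b.index.intersection(p.index):
                key = (model, name)
                records.setdefault(key, []).append(float(p[name] - b[name]))
                signs.setdefault(key, []).append(
                    bool(np.sign(p[name]) == np.sign(b[name]))
                )
    rows = [
        {
            "model": model,
            "coefficient": name,
            "mean_abs_deviation": float(np.mean(np.abs(records[(model, name)]))),
            "sign_agreement": float(np.mean(signs[(model, name)])),
        }
        for (model, name) in records
    ]
    return pd.DataFrame(rows)
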