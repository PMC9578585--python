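"""End-to-end pipeline orchestration and report rendering.

``run_pipeline`` executes the full analysis — load or generate the survey,
aggregate reports into layered site networks, multiply impute missing
dyads, summarize the networks, fit the stimulated and sustained logistic
network regression models (one fit per imputed completion, pooled with
Rubin's rules), compare collaboration-type composition — and writes a
bundle of CSV tables plus a JSON manifest that records the seed, the
configuration echo, stage timings, and row counts, so a run can be
reproduced from its own output.
"""

from __future__ import annotations

import json
import logging
import os
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

import achnet
from achnet.compare import collab_type_comparison, comparison_table
from achnet.impute import fit_ergm, impute_missing
from achnet.lnrm import (
    LnrmFit,
    fit_logistic,
    pool_fits,
    predict_sustain_curve,
    stimulated_design,
    sustained_design,
)
from achnet.netbuild import SiteNetwork, build_networks
from achnet.netstats import NetworkSummary, summarize_site, summary_table
from achnet.survey_io import load_survey, write_networks, write_survey
from achnet.synth import SynthConfig, generate_study

__all__ = ["PipelineConfig", "PipelineResult", "fit_models", "run_pipeline"]

logger = logging.getLogger("achnet")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input source must be set: either ``synth`` (generate data)
    or the pair ``org_path``/``report_path`` (load survey CSVs). The master
    ``seed`` drives every random stage; imputation seeds are derived from
    it per site and completion.
    """

    synth: Optional[SynthConfig] = None
    org_path: Optional[str] = None
    report_path: Optional[str] = None
    m_imputations: int = 10
    gibbs_sweeps: int = 20
    ergm_terms: Tuple[str, ...] = ("edges", "triangles")
    risk_set: str = "non_preexisting"
    sustain_rule: str = "any"
    seed: int = 0
    output_dir: str = "achnet_report"

    def validate(self) -> "PipelineConfig":
        has_files = self.org_path is not None and self.report_path is not None
        if (self.synth is None) == (not has_files):
            raise ValueError(
                "exactly one of synth config or (org_path, report_path) must be set"
            )
        if self.m_imputations < 1:
            raise ValueError("m_imputations must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_raw = raw.pop("synth", None)
        cfg = cls(**raw)
        if synth_raw is not None:
            if "site_sizes" in synth_raw:
                synth_raw["site_sizes"] = tuple(synth_raw["site_sizes"])
            cfg.synth = SynthConfig(**synth_raw)
        if cfg.ergm_terms is not None:
            cfg.ergm_terms = tuple(cfg.ergm_terms)
        return cfg.validate()


@dataclass
class PipelineResult:
    """In-memory report bundle produced by :func:`run_pipeline`."""

    networks: List[SiteNetwork]
    completions: List[List[SiteNetwork]]  # indexed [completion][site]
    summaries: List[NetworkSummary]
    stimulated_fit: LnrmFit
    sustained_fit: LnrmFit
    tables: Dict[str, pd.DataFrame]
    manifest: dict


def _site_seed(master_seed: int, site_index: int) -> int:
    return int(np.random.default_rng([master_seed, site_index]).integers(2**31 - 1))


def build_completions(
    networks: Sequence[SiteNetwork],
    m_imputations: int,
    gibbs_sweeps: int,
    ergm_terms: Sequence[str],
    seed: int,
) -> List[List[SiteNetwork]]:
    """Impute every site's missing dyads, returning ``m`` aligned lists of
    completed networks (sites with nothing missing repeat unchanged). If no
    site has missing dyads a single pseudo-completion is returned."""
    any_missing = any(net.missing for net in networks)
    m = m_imputations if any_missing else 1
    per_site: List[List[SiteNetwork]] = []
    for s, net in enumerate(networks):
        if net.missing:
            model = fit_ergm(net, layer="grant", terms=ergm_terms)
            imputed = impute_missing(
                net, model, m=m, seed=_site_seed(seed, s), sweeps=gibbs_sweeps
            )
            per_site.append(imputed.completions)
        else:
            per_site.append([net] * m)
    return [[per_site[s][c] for s in range(len(networks))] for c in range(m)]


def _common_covariates(frames: Sequence[pd.DataFrame]) -> List[str]:
    """Covariate columns that vary in every completion's design; columns
    with no variation anywhere are dropped from all fits so that pooled
    coefficient sets stay aligned."""
    from achnet.lnrm import META_COLUMNS

    covs = [c for c in frames[0].columns if c not in META_COLUMNS]
    keep, dropped = [], []
    for c in covs:
        (keep if all(f[c].nunique() > 1 for f in frames) else dropped).append(c)
    if dropped:
        warnings.warn(
            f"dropping covariates with no variation in the data: {dropped}",
            stacklevel=2,
        )
    return keep


def _fit_or_degenerate(design: pd.DataFrame, covariates=None) -> LnrmFit:
    """Fit an LNRM, degrading gracefully when the outcome has one class.

    A single-class outcome is the limit of complete separation (the
    intercepts' MLE is infinite), so rather than aborting the pipeline the
    fit is returned with intercepts capped at +/-20, zero slopes, an
    uninformative covariance, and ``converged=False``.
    """
    from achnet.lnrm import COEF_CAP, META_COLUMNS, _design_matrix

    if covariates is None:
        covariates = [c for c in design.columns if c not in META_COLUMNS]
    classes = set(design["outcome"].unique())
    if len(classes) >= 2:
        return fit_logistic(design, covariates=covariates)
    warnings.warn(
        "single-class outcome; returning capped degenerate fit", stacklevel=2
    )
    _, _, names = _design_matrix(design, covariates)
    sign = 1.0 if classes == {1} else -1.0
    params = pd.Series(
        [sign * COEF_CAP if n.startswith("site[") else 0.0 for n in names],
        index=names,
    )
    big = 1e4
    return LnrmFit(
        params=params,
        cov=pd.DataFrame(np.eye(len(names)) * big, index=names, columns=names),
        n_rows=len(design),
        converged=False,
    )


def fit_models(
    organizations,
    reports,
    m_imputations: int = 10,
    gibbs_sweeps: int = 20,
    ergm_terms: Sequence[str] = ("edges", "triangles"),
    risk_set: str = "non_preexisting",
    sustain_rule: str = "any",
    seed: int = 0,
) -> Dict[str, object]:
    """Aggregate, build, impute, and fit both LNRMs, pooling across
    completions.

    Returns a dict with pooled ``"stimulated"``/``"sustained"`` fits, the
    designs stacked across completions, the observed ``"networks"``, and
    the ``"completions"``.
    """
    networks = build_networks(organizations, reports, sustain_rule=sustain_rule)
    completions = build_completions(
        networks, m_imputations, gibbs_sweeps, ergm_terms, seed
    )
    stim_frames = [stimulated_design(c, risk_set=risk_set) for c in completions]
    sus_frames = [sustained_design(c) for c in completions]
    stim_covs = _common_covariates(stim_frames)
    sus_covs = _common_covariates(sus_frames)
    stim_fits = [_fit_or_degenerate(df, stim_covs) for df in stim_frames]
    sus_fits = [_fit_or_degenerate(df, sus_covs) for df in sus_frames]
    return {
        "stimulated": pool_fits(stim_fits),
        "sustained": pool_fits(sus_fits),
        "stimulated_design": pd.concat(stim_frames, ignore_index=True),
        "sustained_design": pd.concat(sus_frames, ignore_index=True),
        "networks": networks,
        "completions": completions,
    }


def _model_table(stim: LnrmFit, sus: LnrmFit) -> pd.DataFrame:
    frames = []
    for model, fit in (("stimulated", stim), ("sustained", sus)):
        tab = fit.summary().reset_index(names="variable")
        tab.insert(0, "model", model)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle to
    ``config.output_dir``.

    Stages and outputs: site summary table (``site_summary.csv``), pooled
    model table (``model_table.csv``), collaboration-type comparisons
    (``type_comparisons.csv``), per-site sustainment-probability curves
    (``sustain_curves.csv``), GraphML/edge-list network exports
    (``networks/``), and ``manifest.json``. Deterministic under a fixed
    master seed.
    """
    config.validate()
    out = Path(config.output_dir)
    os.makedirs(out, exist_ok=True)
    timings: Dict[str, float] = {}
    counts: Dict[str, int] = {}

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    try:
        t0 = stage("input")
        if config.synth is not None:
            organizations, _truths, reports = generate_study(config.synth)
            write_survey(
                organizations, reports, out / "organizations.csv", out / "reports.csv"
            )
        else:
            organizations, reports = load_survey(config.org_path, config.report_path)
        counts["organizations"] = len(organizations)
        counts["tie_reports"] = len(reports)
        timings["input"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'input' failed (seed={config.seed})") from exc

    try:
        t0 = stage("fit")
        fitted = fit_models(
            organizations,
            reports,
            m_imputations=config.m_imputations,
            gibbs_sweeps=config.gibbs_sweeps,
            ergm_terms=config.ergm_terms,
            risk_set=config.risk_set,
            sustain_rule=config.sustain_rule,
            seed=config.seed,
        )
        networks: List[SiteNetwork] = fitted["networks"]
        completions: List[List[SiteNetwork]] = fitted["completions"]
        counts["sites"] = len(networks)
        counts["stimulated_rows"] = int(
            len(fitted["stimulated_design"]) / len(completions)
        )
        counts["sustained_rows"] = int(len(fitted["sustained_design"]) / len(completions))
        timings["fit"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit' failed (seed={config.seed})") from exc

    try:
        t0 = stage("summaries")
        per_site_completions = [
            [completions[c][s] for c in range(len(completions))]
            for s in range(len(networks))
        ]
        summaries = [
            summarize_site(per_site_completions[s], networks[s])
            for s in range(len(networks))
        ]
        site_table = summary_table(summaries)
        timings["summaries"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage 'summaries' failed (seed={config.seed})"
        ) from exc

    try:
        t0 = stage("compare")
        comparisons = comparison_table(collab_type_comparison(networks))
        timings["compare"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage 'compare' failed (seed={config.seed})"
        ) from exc

    try:
        t0 = stage("render")
        curves = predict_sustain_curve(
            fitted["sustained"], fitted["sustained_design"]
        )
        model_tab = _model_table(fitted["stimulated"], fitted["sustained"])
        site_table.to_csv(out / "site_summary.csv")
        model_tab.to_csv(out / "model_table.csv", index=False)
        comparisons.to_csv(out / "type_comparisons.csv", index=False)
        curves.to_csv(out / "sustain_curves.csv", index=False)
        write_networks(networks, out / "networks")
        manifest = {
            "package": "achnet",
            "version": achnet.__version__,
            "seed": config.seed,
            "m_imputations": config.m_imputations,
            "gibbs_sweeps": config.gibbs_sweeps,
            "ergm_terms": list(config.ergm_terms),
            "risk_set": config.risk_set,
            "sustain_rule": config.sustain_rule,
            "synth": None if config.synth is None else asdict(config.synth),
            "inputs": {"org_path": config.org_path, "report_path": config.report_path},
            "counts": counts,
            "timings_s": {k: round(v, 4) for k, v in timings.items()},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        timings["render"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage 'render' failed (seed={config.seed})"
        ) from exc

    for name, t in timings.items():
        logger.info("stage %s: %.3fs", name, t)
    return PipelineResult(
        networks=networks,
        completions=completions,
        summaries=summaries,
        stimulated_fit=fitted["stimulated"],
        sustained_fit=fitted["sustained"],
        tables={
            "site_summary": site_table,
            "model_table": model_tab,
            "type_comparisons": comparisons,
            "sustain_curves": curves,
        },
        manifest=manifest,
    )
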