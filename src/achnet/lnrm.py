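"""Logistic network regression models (LNRM) on dyads.

A logistic network regression model treats each dyad (unordered pair of
organizations) as one Bernoulli observation whose success probability is a
logistic function of dyad-level covariates derived from the network itself
and from node attributes. Two models are built here:

**Stimulated model** — among dyads *without* a preexisting tie (the risk
set for new-tie formation), the outcome is whether a grant-stimulated tie
formed. Covariates are computed on the preexisting layer:

* ``sum_degree`` — total number of preexisting ties involving either
  organization of the pair (activity),
* ``abs_closeness_diff`` — absolute difference in harmonic closeness
  centrality (positional (dis)similarity),
* ``same_sector`` — sector-concordance indicator,
* ``integrator_in_dyad`` — the pair includes the site's integrator,
* ``steering_both`` / ``steering_one`` — both / exactly one endpoint on the
  steering committee,
* one fixed-effect intercept per site (no global intercept).

**Sustained model** — one row per grant-period tie; the outcome is whether
it is expected to be sustained beyond funding. Centrality covariates are
recomputed on the grant layer, and the model adds ``avg_strength`` (the
dyad's mean reported relationship strength), a ``stimulated`` indicator,
and the four collaboration-type indicators.

Fitting maximizes the Bernoulli log-likelihood by iteratively reweighted
least squares with Wald inference; fits across multiply imputed completions
are combined with Rubin's rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.stats import norm

from achnet.netbuild import SiteNetwork
from achnet.netstats import closeness_vector, degree_vector
from achnet.survey_io import COLLAB_TYPES

__all__ = [
    "STIMULATED_COVARIATES",
    "SUSTAINED_COVARIATES",
    "LnrmFit",
    "stimulated_design",
    "sustained_design",
    "fit_logistic",
    "pool_fits",
    "predict_sustain_curve",
]

STIMULATED_COVARIATES = [
    "sum_degree",
    "abs_closeness_diff",
    "same_sector",
    "integrator_in_dyad",
    "steering_both",
    "steering_one",
]

SUSTAINED_COVARIATES = STIMULATED_COVARIATES + [
    "avg_strength",
    "stimulated",
] + list(COLLAB_TYPES)

META_COLUMNS = ["site_id", "u", "v", "outcome"]

COEF_CAP = 20.0  # log-odds cap flagged as separation


def _dyad_covariates(net: SiteNetwork, pair, deg, clo, index) -> Dict[str, float]:
    u, v = pair
    ou, ov = net.organizations[u], net.organizations[v]
    iu, iv = index[u], index[v]
    n_steer = int(ou.is_steering) + int(ov.is_steering)
    return {
        "sum_degree": float(deg[iu] + deg[iv]),
        "abs_closeness_diff": float(abs(clo[iu] - clo[iv])),
        "same_sector": float(ou.sector == ov.sector),
        "integrator_in_dyad": float(ou.is_integrator or ov.is_integrator),
        "steering_both": float(n_steer == 2),
        "steering_one": float(n_steer == 1),
    }


def stimulated_design(
    networks: Sequence[SiteNetwork], risk_set: str = "non_preexisting"
) -> pd.DataFrame:
    """Dyad-level design for the stimulated-tie model, pooled across sites.

    One row per dyad in the risk set; ``outcome`` is 1 iff the dyad is a
    grant-layer tie that did not preexist the grant. ``sum_degree`` and
    ``abs_closeness_diff`` are computed on the preexisting layer. Missing
    dyads (never observed) are excluded — run imputed completions through
    this function instead.

    ``risk_set``: ``"non_preexisting"`` (default; stimulation is only
    possible where no tie preexisted) or ``"all"`` dyads.
    """
    if risk_set not in ("non_preexisting", "all"):
        raise ValueError(f"unknown risk_set {risk_set!r}")
    frames = []
    for net in networks:
        nodes = net.nodes
        index = {node: i for i, node in enumerate(nodes)}
        deg = degree_vector(net.preexisting, nodes)
        clo = closeness_vector(net.preexisting, nodes)
        rows = []
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                pair = (u, v) if u < v else (v, u)
                if pair in net.missing:
                    continue
                if risk_set == "non_preexisting" and pair in net.preexisting:
                    continue
                row = {
                    "site_id": net.site_id,
                    "u": pair[0],
                    "v": pair[1],
                    "outcome": int(pair in net.grant and pair not in net.preexisting),
                }
                row.update(_dyad_covariates(net, pair, deg, clo, index))
                rows.append(row)
        if not rows:
            warnings.warn(
                f"site {net.site_id}: empty risk set, contributes no rows",
                stacklevel=2,
            )
            continue
        frames.append(pd.DataFrame(rows))
    if not frames:
        return pd.DataFrame(columns=META_COLUMNS + STIMULATED_COVARIATES)
    return pd.concat(frames, ignore_index=True)[META_COLUMNS + STIMULATED_COVARIATES]


def sustained_design(networks: Sequence[SiteNetwork]) -> pd.DataFrame:
    """Dyad-level design for the sustainment model, pooled across sites.

    One row per grant-layer tie; ``outcome`` is 1 iff the tie is in the
    sustained layer. Centrality covariates come from the grant layer;
    ``avg_strength``, the ``stimulated`` indicator, and type indicators are
    attached from the aggregated edge attributes.
    """
    frames = []
    for net in networks:
        nodes = net.nodes
        index = {node: i for i, node in enumerate(nodes)}
        deg = degree_vector(net.grant, nodes)
        clo = closeness_vector(net.grant, nodes)
        rows = []
        for pair in sorted(net.grant):
            attrs = net.edge_attrs[pair]
            row = {
                "site_id": net.site_id,
                "u": pair[0],
                "v": pair[1],
                "outcome": int(pair in net.sustained),
            }
            row.update(_dyad_covariates(net, pair, deg, clo, index))
            row["avg_strength"] = attrs.avg_strength
            row["stimulated"] = float(attrs.evolution == "stimulated")
            for t in COLLAB_TYPES:
                row[t] = float(t in attrs.types)
            rows.append(row)
        if not rows:
            warnings.warn(
                f"site {net.site_id}: no grant-layer ties, contributes no rows",
                stacklevel=2,
            )
            continue
        frames.append(pd.DataFrame(rows))
    if not frames:
        return pd.DataFrame(columns=META_COLUMNS + SUSTAINED_COVARIATES)
    return pd.concat(frames, ignore_index=True)[META_COLUMNS + SUSTAINED_COVARIATES]


@dataclass
class LnrmFit:
    """Fitted LNRM: log-odds coefficients with Wald inference.

    ``params`` are on the log-odds scale; ``odds_ratios = exp(params)``;
    ``ci_low``/``ci_high`` bound the odds ratios (exp of the symmetric
    log-scale interval). ``m_imputations > 1`` marks a Rubin-pooled fit.
    """

    params: pd.Series
    cov: pd.DataFrame
    n_rows: int
    converged: bool
    m_imputations: int = 1

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def ci_low(self) -> pd.Series:
        return np.exp(self.params - 1.96 * self.se)

    @property
    def ci_high(self) -> pd.Series:
        return np.exp(self.params + 1.96 * self.se)

    @property
    def p_values(self) -> pd.Series:
        z = self.params / self.se
        return pd.Series(2.0 * norm.sf(np.abs(z)), index=self.params.index)

    def summary(self) -> pd.DataFrame:
        """Results table: OR, 95% CI, p-value per coefficient."""
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.se,
                "odds_ratio": self.odds_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": self.p_values,
            }
        )


def _design_matrix(design: pd.DataFrame, covariates: Sequence[str]):
    sites = sorted(design["site_id"].unique())
    site_cols = [f"site[{s}]" for s in sites]
    X = np.zeros((len(design), len(sites) + len(covariates)))
    for j, s in enumerate(sites):
        X[:, j] = (design["site_id"] == s).to_numpy(float)
    for j, c in enumerate(covariates):
        X[:, len(sites) + j] = design[c].to_numpy(float)
    y = design["outcome"].to_numpy(float)
    return X, y, site_cols + list(covariates)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the trailing pivot columns of a rank-revealing QR
        _, _, piv = qr(X, mode="economic", pivoting=True)
        collinear = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


def irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    cap: float = COEF_CAP,
):
    """Bernoulli-logistic maximum likelihood via iteratively reweighted
    least squares.

    Converges when the maximum absolute score (gradient of the
    log-likelihood) drops below ``tol``. Returns ``(beta, cov, converged)``
    with ``cov`` the inverse observed information. Under complete
    separation the coefficients diverge; they are capped at ``|cap|`` and
    the fit flagged non-converged.
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - mu)
        # coordinates pinned at the cap are separated; they cannot satisfy
        # the score equation, so convergence is judged on the free ones
        pinned = np.abs(beta) >= cap
        free_score = score[~pinned] if (~pinned).any() else score
        if np.max(np.abs(free_score)) < tol:
            converged = not pinned.any()
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # dampen overshooting steps far outside the plausible log-odds range
        step_max = np.max(np.abs(step))
        if step_max > 10.0:
            step *= 10.0 / step_max
        beta = np.clip(beta + step, -cap, cap)
    beta = np.clip(beta, -cap, cap)
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return beta, cov, converged


def fit_logistic(
    design: pd.DataFrame, covariates: Optional[Sequence[str]] = None
) -> LnrmFit:
    """Fit an LNRM to a dyad-level design frame.

    The design matrix is one fixed-effect indicator per site (no global
    intercept — the site dummies span it) followed by the covariate
    columns. ``covariates`` defaults to every non-metadata column of
    ``design``. Requires both outcome classes and a full-rank design;
    collinear columns are named in the error.
    """
    if covariates is None:
        covariates = [c for c in design.columns if c not in META_COLUMNS]
    if len(design) == 0:
        raise ValueError("empty design")
    y_vals = design["outcome"].unique()
    if len(set(y_vals) & {0, 1}) < 2:
        raise ValueError(
            "outcome must contain both classes; "
            f"got values {sorted(y_vals)}"
        )
    for c in covariates:
        if not np.all(np.isfinite(design[c].to_numpy(float))):
            raise ValueError(f"non-finite values in covariate {c!r}")
        if design[c].nunique() == 1:
            raise ValueError(f"constant non-intercept column {c!r}")
    X, y, names = _design_matrix(design, covariates)
    _check_rank(X, names)
    beta, cov, converged = irls(X, y)
    if not converged:
        warnings.warn(
            "LNRM fit did not converge (possible complete separation); "
            "coefficients capped",
            stacklevel=2,
        )
    return LnrmFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        n_rows=len(design),
        converged=converged,
    )


def pool_fits(fits: Sequence[LnrmFit]) -> LnrmFit:
    """Combine fits across imputed completions with Rubin's rules.

    Pooled estimate = mean of estimates; total variance = mean
    within-imputation variance + (1 + 1/m) x between-imputation variance.
    The pooled covariance matrix applies the same inflation to the averaged
    within covariance so that CIs derive from the total variance. With
    ``m = 1`` the input fit is returned unchanged.
    """
    if len(fits) == 0:
        raise ValueError("no fits to pool")
    names = list(fits[0].params.index)
    for f in fits[1:]:
        if list(f.params.index) != names:
            raise ValueError("fits have mismatched coefficient sets")
    if len(fits) == 1:
        return fits[0]
    m = len(fits)
    estimates = np.vstack([f.params.to_numpy() for f in fits])
    pooled = estimates.mean(axis=0)
    within = np.mean([f.cov.to_numpy() for f in fits], axis=0)
    centered = estimates - pooled
    between = (centered.T @ centered) / (m - 1)
    total = within + (1.0 + 1.0 / m) * between
    return LnrmFit(
        params=pd.Series(pooled, index=names),
        cov=pd.DataFrame(total, index=names, columns=names),
        n_rows=fits[0].n_rows,
        converged=all(f.converged for f in fits),
        m_imputations=m,
    )


def predict_sustain_curve(
    fit: LnrmFit,
    design: pd.DataFrame,
    strength_grid: Optional[Sequence[float]] = None,
    site_id: Optional[str] = None,
) -> pd.DataFrame:
    """Predicted sustainment probability as a function of relationship
    strength, by site.

    For each site, all covariates other than ``avg_strength`` are held at
    their site-specific means (from ``design``, the sustained-model design
    the fit was estimated on), the site's own intercept is active, and
    ``avg_strength`` sweeps the grid. Returns a frame with columns
    ``site_id, avg_strength, probability``.
    """
    if "avg_strength" not in fit.params.index:
        raise ValueError("fit has no avg_strength term; not a sustainment model")
    if strength_grid is None:
        strength_grid = np.linspace(1.0, 3.0, 21)
    covariates = [
        c for c in design.columns if c not in META_COLUMNS
    ]
    sites = sorted(design["site_id"].unique())
    if site_id is not None:
        if site_id not in sites:
            raise ValueError(f"unknown site {site_id!r}")
        sites = [site_id]
    rows = []
    for s in sites:
        sub = design[design["site_id"] == s]
        means = sub[covariates].mean()
        for strength in strength_grid:
            x = pd.Series(0.0, index=fit.params.index)
            x[f"site[{s}]"] = 1.0
            for c in covariates:
                x[c] = means[c]
            x["avg_strength"] = strength
            eta = float(fit.params @ x)
            rows.append(
                {
                    "site_id": s,
                    "avg_strength": float(strength),
                    "probability": 1.0 / (1.0 + np.exp(-eta)),
                }
            )
    return pd.DataFrame(rows)
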