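"""Mediation by risk-ratio attenuation.

For each candidate mediator, the intervention effect on the IPV outcome is
estimated twice with modified Poisson regression (EA-clustered robust
variance): once from a base model (arm + matched-pair fixed effects + age
group + marital status + EA-level baseline outcome prevalence) and once
with the mediator added.  The percent attenuation is computed on the
excess-risk-ratio scale:

    A = 100 * (RR_mediated - RR_base) / (1 - RR_base)

positive values mean the effect moved toward the null when the mediator
was adjusted for (suggestive of mediation); negative values mean the
effect strengthened.  No CI is attached to attenuation percentages by
default; a cluster-bootstrap CI is available behind a flag as an
extension.

The module also provides the mediator-outcome association models
(modified Poisson adjusted for pair, arm, age, marital status, education
and childhood abuse), with community-level mediators entered per
10-percentage-point change in EA prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression_core import (
    CollinearityError,
    ConvergenceError,
    DesignSpec,
    EffectEstimate,
    fit_glm,
    risk_ratio_from_model,
)

__all__ = [
    "MediationRow",
    "BASE_MODEL_TERMS",
    "ASSOCIATION_TERMS",
    "base_model_rr",
    "mediator_adjusted_rr",
    "percent_attenuation",
    "round_percent",
    "mediation_table",
    "risk_factor_association",
    "attenuation_bootstrap_ci",
]

# base mediation model: pair, age group, marital status, baseline prevalence
BASE_MODEL_TERMS = ("arm", "C(pair_id)", "age_group", "marital_status",
                    "ea_baseline_prev")
# association model: pair, arm, age, marital status, education, abuse
ASSOCIATION_TERMS = ("arm", "C(pair_id)", "age_group", "marital_status",
                     "education", "childhood_abuse")


@dataclass
class MediationRow:
    mediator: str
    level: str
    reporter: str
    base_rr: float
    adjusted_rr: float | None
    attenuation_pct: float | None
    attenuation_display: int | None
    n_base: int
    n_adjusted: int | None
    error: str = ""


def _resolve_terms(terms, data):
    """Drop terms whose columns are absent (e.g. no baseline column in a
    bare simulation frame); the caller's adjustment description reflects
    the terms actually used."""
    out = []
    for t in terms:
        col = t[2:-1] if t.startswith("C(") else t
        if col in data.columns:
            out.append(t)
    return tuple(out)


def base_model_rr(data: pd.DataFrame, outcome: str = "ipv",
                  terms: tuple[str, ...] = BASE_MODEL_TERMS,
                  cluster: str = "ea_id",
                  subset: str | None = None) -> EffectEstimate:
    """Arm risk ratio from the mediator-free modified Poisson model."""
    design = DesignSpec(outcome=outcome, terms=_resolve_terms(terms, data),
                        cluster=cluster, subset=subset)
    model = fit_glm(data, design, link="log")
    return risk_ratio_from_model(model, "arm")


def mediator_adjusted_rr(data: pd.DataFrame, mediator: str,
                         outcome: str = "ipv",
                         terms: tuple[str, ...] = BASE_MODEL_TERMS,
                         cluster: str = "ea_id",
                         subset: str | None = None) -> EffectEstimate:
    """Arm risk ratio after adding a single mediator to the base model."""
    sub = data.query(subset) if subset else data
    vals = sub[mediator].dropna()
    if vals.nunique() <= 1:
        raise CollinearityError(f"mediator {mediator!r} is constant in the "
                                "analysis subset")
    design = DesignSpec(
        outcome=outcome,
        terms=_resolve_terms(terms, data) + (mediator,),
        cluster=cluster, subset=subset,
    )
    model = fit_glm(data, design, link="log")
    return risk_ratio_from_model(model, "arm")


def percent_attenuation(base, adjusted) -> float | None:
    """Percent change in the arm RR on the excess-risk-ratio scale.

    ``100 * (RR_med - RR_base) / (1 - RR_base)``; undefined (None) when the
    base RR equals 1.  Accepts floats or EffectEstimates.
    """
    rr_base = base.estimate if isinstance(base, EffectEstimate) else float(base)
    rr_med = adjusted.estimate if isinstance(adjusted, EffectEstimate) else float(adjusted)
    if rr_base == 1.0:
        return None
    return 100.0 * (rr_med - rr_base) / (1.0 - rr_base)


def round_percent(x: float | None) -> int | None:
    """Nearest integer, rounding halves away from zero (display convention)."""
    if x is None or not np.isfinite(x):
        return None
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def mediation_table(
    data: pd.DataFrame,
    mediators: list[tuple[str, str, str]],
    reporter: str = "",
    outcome: str = "ipv",
    terms: tuple[str, ...] = BASE_MODEL_TERMS,
    cluster: str = "ea_id",
    subset: str | None = None,
) -> pd.DataFrame:
    """One attenuation row per mediator (name, ecological level, column).

    The base model is fitted once; per-mediator failures are recorded
    in-row and the run continues.  Rows are ordered community ->
    relationship -> individual, preserving input order within level.
    """
    names = [m[0] for m in mediators]
    if len(set(names)) != len(names):
        raise ValueError("duplicate mediator names in request")
    base = base_model_rr(data, outcome=outcome, terms=terms,
                         cluster=cluster, subset=subset)
    level_order = {"community": 0, "relationship": 1, "individual": 2}
    ordered = sorted(mediators, key=lambda m: level_order.get(m[1], 9))
    rows = []
    for name, level, column in ordered:
        try:
            adj = mediator_adjusted_rr(data, column, outcome=outcome,
                                       terms=terms, cluster=cluster,
                                       subset=subset)
            att = percent_attenuation(base, adj)
            n_change = adj.n != base.n
            rows.append(MediationRow(
                mediator=name, level=level, reporter=reporter,
                base_rr=base.estimate, adjusted_rr=adj.estimate,
                attenuation_pct=att, attenuation_display=round_percent(att),
                n_base=base.n, n_adjusted=adj.n,
                error="n-changed" if n_change else "",
            ))
        except (CollinearityError, ConvergenceError, ValueError, KeyError) as exc:
            rows.append(MediationRow(
                mediator=name, level=level, reporter=reporter,
                base_rr=base.estimate, adjusted_rr=None,
                attenuation_pct=None, attenuation_display=None,
                n_base=base.n, n_adjusted=None, error=str(exc),
            ))
    out = pd.DataFrame([r.__dict__ for r in rows])
    out.attrs["base_estimate"] = base
    return out


def risk_factor_association(data: pd.DataFrame, mediator: str,
                            outcome: str = "ipv",
                            terms: tuple[str, ...] = ASSOCIATION_TERMS,
                            cluster: str = "ea_id",
                            subset: str | None = None) -> EffectEstimate:
    """Mediator-outcome risk ratio from the adjusted association model.

    Community-level mediators should be passed as the attached ecological
    exposure column (per 10-percentage-point change by default).
    """
    design = DesignSpec(
        outcome=outcome,
        terms=_resolve_terms(terms, data) + (mediator,),
        cluster=cluster, subset=subset,
    )
    model = fit_glm(data, design, link="log")
    return risk_ratio_from_model(model, mediator)


def attenuation_bootstrap_ci(
    data: pd.DataFrame, mediator: str, outcome: str = "ipv",
    terms: tuple[str, ...] = BASE_MODEL_TERMS, cluster: str = "ea_id",
    subset: str | None = None, n_boot: int = 200, seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Cluster-bootstrap percentile CI for the attenuation percentage.

    An extension beyond the attenuation point estimates (which carry no CI
    by default); resamples whole clusters with replacement.
    """
    rng = np.random.default_rng(seed)
    clusters = data[cluster].unique()
    stats = []
    for _ in range(n_boot):
        take = rng.choice(clusters, size=len(clusters), replace=True)
        frames = []
        for b, c in enumerate(take):
            block = data[data[cluster] == c].copy()
            block[cluster] = f"boot{b}"
            frames.append(block)
        boot = pd.concat(frames, ignore_index=True)
        try:
            base = base_model_rr(boot, outcome=outcome, terms=terms,
                                 cluster=cluster, subset=subset)
            adj = mediator_adjusted_rr(boot, mediator, outcome=outcome,
                                       terms=terms, cluster=cluster,
                                       subset=subset)
        except (CollinearityError, ConvergenceError, ValueError):
            continue
        att = percent_attenuation(base, adj)
        if att is not None:
            stats.append(att)
    if not stats:
        return (np.nan, np.nan)
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
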