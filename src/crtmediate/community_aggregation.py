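"""Enumeration-area prevalences and community-level effect estimates.

Community-level mediators are continuous measures: the EA-level prevalence
(in percent, 0-100) of each indicator.  This module computes those
prevalences, arm-level summaries (unweighted mean and SD across EAs),
covariate-adjusted mean differences between arms (EA-level linear model
with matched-pair fixed effects), and the per-respondent ecological
exposure column used by the individual-level mediation models (EA
prevalence divided by a stated scale, default 10 percentage points).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .indicator_engine import IndicatorMatrix

__all__ = [
    "EASummary",
    "MeanDifferenceEstimate",
    "ea_prevalence",
    "arm_summary",
    "adjusted_mean_difference",
    "attach_community_exposure",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EASummary:
    ea_id: str
    community_id: str
    pair_id: str
    arm: int
    sex: str
    indicator: str
    n: int
    prevalence: float  # percent, 0-100


@dataclass
class MeanDifferenceEstimate:
    indicator: str
    mean_by_arm: dict[int, float]
    sd_by_arm: dict[int, float | None]
    difference: float
    ci_low: float
    ci_high: float
    se: float
    adjustment: str
    n_eas: int
    flags: tuple[str, ...] = ()


def ea_prevalence(matrix: IndicatorMatrix,
                  indicators: list[str] | None = None) -> pd.DataFrame:
    """Per-EA prevalence (percent) of each indicator.

    prevalence = 100 * true / (true + false); EAs with zero eligible
    respondents for an indicator are omitted with a logged note.
    """
    names = indicators or list(matrix.values.columns)
    meta = matrix.meta
    ea_meta = meta.drop_duplicates("ea_id").set_index("ea_id")
    rows = []
    for name in names:
        grouped = pd.DataFrame({
            "value": matrix.values[name],
            "ea_id": meta["ea_id"],
        }).groupby("ea_id", sort=True)["value"]
        denom = grouped.count()
        numer = grouped.apply(lambda v: int((v == 1.0).sum()))
        for ea in denom.index:
            n = int(denom[ea])
            if n == 0:
                logger.info("EA %s has zero eligible respondents for %s; omitted",
                            ea, name)
                continue
            sub_meta = ea_meta.loc[ea]
            rows.append({
                "ea_id": ea,
                "community_id": sub_meta["community_id"],
                "pair_id": sub_meta["pair_id"],
                "arm": int(sub_meta["arm"]),
                "sex": sub_meta["sex"],
                "indicator": name,
                "n": n,
                "prevalence": 100.0 * float(numer[ea]) / n,
            })
    return pd.DataFrame(
        rows, columns=["ea_id", "community_id", "pair_id", "arm", "sex",
                       "indicator", "n", "prevalence"],
    )


def arm_summary(summaries: pd.DataFrame, indicator: str,
                sex: str | None = None) -> pd.DataFrame:
    """Unweighted mean and SD of EA prevalences within each arm.

    SD is NA when an arm has a single EA.
    """
    df = summaries[summaries["indicator"] == indicator]
    if sex is not None:
        df = df[df["sex"] == sex]
    if df.empty:
        raise ValueError(f"no EA summaries for indicator {indicator!r}")
    out = (
        df.groupby("arm")["prevalence"]
        .agg(n_eas="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return out


def _ols(X: np.ndarray, y: np.ndarray):
    coef, _res, rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("collinear pair/arm structure in EA-level model")
    resid = y - X @ coef
    df_resid = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df_resid if df_resid > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return coef, cov, df_resid


def adjusted_mean_difference(
    summaries: pd.DataFrame,
    indicator: str,
    sex: str | None = None,
    baseline_summaries: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> MeanDifferenceEstimate:
    """Intervention-control difference in EA prevalence, pair-adjusted.

    EA-level linear model: prevalence ~ arm + pair fixed effects
    (+ community-level baseline prevalence when supplied; baseline EAs are
    re-drawn between waves, so the baseline covariate is carried at the
    community level).  CI from the t distribution on the residual df.
    The adjustment description is always emitted with the estimate.
    """
    df = summaries[summaries["indicator"] == indicator].copy()
    if sex is not None:
        df = df[df["sex"] == sex]
    if df.empty:
        raise ValueError(f"no EA summaries for indicator {indicator!r}")
    pairs = sorted(df["pair_id"].unique())
    by_pair_arm = df.groupby("pair_id")["arm"].nunique()
    if (by_pair_arm < 2).any():
        raise ValueError("both arms must be present in every pair")
    adjustment = "arm + pair fixed effects"
    cols = [np.ones(len(df)), df["arm"].to_numpy(float)]
    names = ["Intercept", "arm"]
    for pair in pairs[1:]:
        cols.append((df["pair_id"] == pair).to_numpy(float))
        names.append(f"pair[{pair}]")
    if baseline_summaries is not None:
        base = baseline_summaries[baseline_summaries["indicator"] == indicator]
        if sex is not None:
            base = base[base["sex"] == sex]
        comm_base = base.groupby("community_id")["prevalence"].mean()
        df["baseline_prev"] = df["community_id"].map(comm_base)
        if df["baseline_prev"].notna().all():
            cols.append(df["baseline_prev"].to_numpy(float))
            names.append("baseline_prev")
            adjustment += " + community baseline prevalence"
    X = np.column_stack(cols)
    y = df["prevalence"].to_numpy(float)
    coef, cov, df_resid = _ols(X, y)
    i_arm = names.index("arm")
    diff = float(coef[i_arm])
    se = float(np.sqrt(max(cov[i_arm, i_arm], 0.0)))
    flags: tuple[str, ...] = ()
    if se < 1e-8 or df_resid == 0:
        flags = ("degenerate-ci",)
        tq = 0.0
    else:
        tq = float(stats.t.ppf(1 - alpha / 2, df_resid))
    arm_stats = arm_summary(df.assign(indicator=indicator), indicator)
    mean_by_arm = dict(zip(arm_stats["arm"], arm_stats["mean"]))
    sd_by_arm = {
        int(a): (None if np.isnan(s) else float(s))
        for a, s in zip(arm_stats["arm"], arm_stats["sd"])
    }
    return MeanDifferenceEstimate(
        indicator=indicator,
        mean_by_arm=mean_by_arm,
        sd_by_arm=sd_by_arm,
        difference=diff,
        ci_low=diff - tq * se,
        ci_high=diff + tq * se,
        se=se,
        adjustment=adjustment,
        n_eas=len(df),
        flags=flags,
    )


def attach_community_exposure(
    data: pd.DataFrame,
    summaries: pd.DataFrame,
    indicator: str,
    scale: float = 10.0,
    column: str | None = None,
    leave_one_out: bool = False,
    matrix: IndicatorMatrix | None = None,
) -> pd.DataFrame:
    """Attach each respondent's EA prevalence of a mediator as an exposure.

    The exposure is the EA prevalence in percent divided by ``scale``
    (default 10, so a unit change is 10 percentage points).  Respondents in
    EAs without a summary receive a missing exposure.  ``leave_one_out``
    excludes the respondent's own contribution (requires ``matrix``);
    including self is the default — the difference is O(1/n) at EA sizes
    around 28.
    """
    column = column or f"exposure_{indicator}"
    df = data.copy()
    sub = summaries[summaries["indicator"] == indicator]
    ea_prev = sub.set_index("ea_id")["prevalence"]
    ea_n = sub.set_index("ea_id")["n"]
    prev = df["ea_id"].map(ea_prev)
    if leave_one_out:
        if matrix is None:
            raise ValueError("leave_one_out requires the indicator matrix")
        own = df["respondent_id"].map(matrix.values[indicator])
        n = df["ea_id"].map(ea_n)
        loo = (prev / 100.0 * n - own.fillna(0)) / (n - own.notna().astype(int))
        prev = 100.0 * loo.where(n > own.notna().astype(int))
    df[column] = prev / scale
    return df
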