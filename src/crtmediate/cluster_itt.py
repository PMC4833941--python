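"""Pair-matched, covariate-adjusted cluster-level intention-to-treat estimator.

The estimator follows the classic cluster-summary construction for
pair-matched community trials with a binary outcome:

1.  Fit an individual-level logistic model of the outcome on covariates
    only (no arm term), pooled over both arms.
2.  For each randomisation cluster ``j`` (community/site), compute the
    expected events ``E_j`` (sum of fitted probabilities) and observed
    events ``O_j``; the ratio residual ``R_j = O_j / E_j`` carries the
    whole intervention contrast.
3.  Within each matched pair ``p`` form the log ratio
    ``l_p = log(R_int,p) - log(R_ctl,p)``; the adjusted risk ratio is the
    exponential of the size-weighted mean of the ``l_p`` with a t-based CI
    on ``P - 1`` degrees of freedom.

Zero-event clusters receive a 0.5 continuity correction to both ``O_j``
and ``E_j`` (flagged in the output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regression_core import DesignSpec, EffectEstimate, FittedModel, fit_glm

__all__ = [
    "expected_events",
    "observed_events",
    "ratio_residuals",
    "paired_cluster_rr",
    "itt_effect",
]


def expected_events(model: FittedModel, cluster_ids: pd.Series) -> pd.Series:
    """Per-cluster expected events: sum of fitted probabilities.

    ``cluster_ids`` must be indexed like the data the model was fitted on;
    rows dropped during fitting (filter/complete-case) are excluded, so a
    cluster with every member filtered is absent from the output.
    """
    clusters = cluster_ids.loc[model.row_index]
    return (
        pd.Series(model.mu, index=model.row_index)
        .groupby(clusters.to_numpy())
        .sum()
        .rename("E")
    )


def observed_events(outcome: pd.Series, cluster_ids: pd.Series,
                    row_index: pd.Index | None = None) -> pd.Series:
    if row_index is not None:
        outcome = outcome.loc[row_index]
        cluster_ids = cluster_ids.loc[row_index]
    return outcome.groupby(cluster_ids.to_numpy()).sum().rename("O")


def ratio_residuals(observed: pd.Series, expected: pd.Series,
                    cluster_info: pd.DataFrame) -> pd.DataFrame:
    """Cluster table with ratio residuals R_j = O_j / E_j.

    ``cluster_info`` maps cluster id -> pair_id, arm (and optionally n).
    E_j == 0 is an error; O_j == 0 yields R_j = 0 with a flag (the log-scale
    combination later applies the continuity policy).
    """
    if set(observed.index) != set(expected.index):
        raise ValueError("observed and expected cluster keys do not match")
    info = cluster_info.copy()
    rows = []
    for cluster in sorted(observed.index, key=str):
        O, E = float(observed[cluster]), float(expected[cluster])
        if E <= 0:
            raise ValueError(f"cluster {cluster!r} has non-positive expected events")
        rows.append({
            "cluster_id": cluster,
            "pair_id": info.loc[cluster, "pair_id"],
            "arm": int(info.loc[cluster, "arm"]),
            "O": O,
            "E": E,
            "R": O / E,
            "n": float(info.loc[cluster, "n"]) if "n" in info.columns else np.nan,
            "zero_events": O == 0,
        })
    return pd.DataFrame(rows)


def paired_cluster_rr(residuals: pd.DataFrame, weights: str = "pair",
                      alpha: float = 0.05, continuity: float = 0.5,
                      adjustment: str = "") -> EffectEstimate:
    """Combine ratio residuals into a pair-adjusted, size-weighted RR.

    weights:
        ``"pair"`` (default) — pair weight proportional to the pair's total
        sample size; ``"equal"`` — unweighted mean of pair log ratios.
    """
    df = residuals.copy()
    flags: list[str] = []
    if df["zero_events"].any():
        zero = df["zero_events"]
        df.loc[zero, "O"] += continuity
        df.loc[zero, "E"] += continuity
        df["R"] = df["O"] / df["E"]
        flags.append("continuity-corrected")
    pairs = []
    for pair_id, grp in df.groupby("pair_id", sort=True):
        arms = grp.groupby("arm")[["O", "E", "n"]].sum()
        if set(arms.index) != {0, 1}:
            raise ValueError(f"pair {pair_id!r} lacks one of the arms")
        r1 = arms.loc[1, "O"] / arms.loc[1, "E"]
        r0 = arms.loc[0, "O"] / arms.loc[0, "E"]
        if r1 <= 0 or r0 <= 0:
            raise ValueError(f"pair {pair_id!r} has a zero ratio residual after "
                             "continuity correction")
        size = float(arms["n"].sum())
        pairs.append((pair_id, np.log(r1) - np.log(r0), size))
    P = len(pairs)
    ell = np.array([p[1] for p in pairs])
    w = (np.array([p[2] for p in pairs]) if weights == "pair"
         else np.ones(P))
    if not np.isfinite(w).all() or w.sum() <= 0:
        w = np.ones(P)
        flags.append("missing-sizes-equal-weights")
    lbar = float(np.average(ell, weights=w))
    n_total = int(df["n"].sum()) if df["n"].notna().all() else 0
    if P < 2:
        return EffectEstimate(
            scale="risk ratio", estimate=float(np.exp(lbar)),
            ci_low=np.nan, ci_high=np.nan, se=np.nan,
            adjustment=adjustment or "pair-matched cluster-level",
            n=n_total, n_clusters=len(df),
            flags=tuple(flags + ["no-ci-single-pair"]),
        )
    # weighted one-sample variance of the pair log ratios
    se = float(np.sqrt(np.sum(w * (ell - lbar) ** 2) / (w.sum() * (P - 1))))
    tq = float(stats.t.ppf(1 - alpha / 2, P - 1))
    if se == 0:
        flags.append("degenerate-ci")
    return EffectEstimate(
        scale="risk ratio",
        estimate=float(np.exp(lbar)),
        ci_low=float(np.exp(lbar - tq * se)),
        ci_high=float(np.exp(lbar + tq * se)),
        se=se,
        adjustment=adjustment or "pair-matched cluster-level, size-weighted",
        n=n_total,
        n_clusters=len(df),
        flags=tuple(flags),
    )


def itt_effect(
    data: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...],
    cluster_col: str = "community_id",
    pair_col: str = "pair_id",
    arm_col: str = "arm",
    subset: str | None = None,
    weights: str = "pair",
) -> EffectEstimate:
    """End-to-end adjusted cluster-level ITT risk ratio.

    ``data`` is an analysis frame (one row per eligible respondent at
    follow-up, outcome 0/1, covariates attached — including any EA-level
    baseline prevalence column).  The expected-events model is logistic on
    the covariates only, pooled across arms, so the cluster residuals carry
    the intervention contrast; pairing and size weighting happen at the
    cluster level.
    """
    design = DesignSpec(outcome=outcome, terms=tuple(covariates),
                        cluster=None, subset=subset)
    model = fit_glm(data, design, link="logit")
    E = expected_events(model, data[cluster_col])
    O = observed_events(data[outcome], data[cluster_col], model.row_index)
    used = data.loc[model.row_index]
    info = (
        used.groupby(cluster_col)
        .agg(pair_id=(pair_col, "first"), arm=(arm_col, "first"),
             n=(outcome, "size"))
    )
    residuals = ratio_residuals(O, E, info)
    covar_desc = ", ".join(covariates) if covariates else "none"
    return paired_cluster_rr(
        residuals, weights=weights,
        adjustment=(f"cluster-level pair-matched, size-weighted; "
                    f"expected events adjusted for: {covar_desc}"),
    )
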