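"""End-to-end orchestration: simulate -> indicators -> aggregate -> effects
-> mediation, with validation, manifests and table-shaped CSV reports.

Every run emits five report files (ITT effects on the IPV outcomes,
intervention effects on mediators for each reporter, mediator-outcome
associations, and the attenuation ledger) plus a JSON manifest recording
the seed, configuration, sample counts and any warnings.  Re-running with
the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster_itt import itt_effect
from .community_aggregation import (
    adjusted_mean_difference,
    attach_community_exposure,
    ea_prevalence,
)
from .indicator_engine import (
    IndicatorMatrix,
    build_indicator_matrix,
    load_default_specs,
    parse_indicator_specs,
)
from .mediation_ledger import (
    ASSOCIATION_TERMS,
    BASE_MODEL_TERMS,
    mediation_table,
    risk_factor_association,
)
from .regression_core import categorize_age
from .synthetic_data import SimConfig, TrialRoster, generate_trial

__all__ = [
    "RunConfig",
    "PipelineError",
    "ValidationReport",
    "ADJUSTMENT_PRESETS",
    "run_pipeline",
    "validate_inputs",
    "prepare_outcome_frame",
    "attach_baseline_prevalence",
]

# Documented covariate presets for the three model families.
ADJUSTMENT_PRESETS = {
    # expected-events logistic model of the cluster-level ITT analysis
    "itt": ("age_group", "marital_status", "ea_baseline_prev"),
    # mediator intervention effects at the cluster level (binary mediators)
    "itt_mediator": ("age_group", "marital_status"),
    # mediator-outcome association models
    "association": ASSOCIATION_TERMS,
    # attenuation base model
    "mediation": BASE_MODEL_TERMS,
}

_OUTCOME_BY_SEX = {"female": "ipv_experience", "male": "ipv_perpetration"}
_REPORTER_BY_SEX = {"female": "women", "male": "men"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage, self.code = stage, code


@dataclass
class RunConfig:
    sim: SimConfig | None = None
    baseline_csv: str | None = None
    followup_csv: str | None = None
    indicator_config: str | None = None
    outdir: str = "results"
    seed: int | None = None
    verbose: bool = False

    def validate(self) -> None:
        from_csv = self.baseline_csv is not None and self.followup_csv is not None
        if (self.sim is None) == (not from_csv):
            raise PipelineError("config", "input-source",
                                "exactly one input source required "
                                "(sim config or baseline+follow-up CSVs)")
        if self.indicator_config is not None and not Path(self.indicator_config).exists():
            raise PipelineError("config", "indicator-config",
                                f"indicator config not found: {self.indicator_config}")


@dataclass
class ValidationReport:
    hard_errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_rows: int = 0
    n_excluded: int = 0
    data: pd.DataFrame | None = None

    @property
    def ok(self) -> bool:
        return not self.hard_errors


def validate_inputs(roster: pd.DataFrame | str | Path) -> ValidationReport:
    """Check roster invariants: id nesting, arm constancy, age range.

    Structural violations are hard errors; value-level problems become
    warnings and the offending rows are excluded from the cleaned frame.
    """
    df = pd.read_csv(roster) if not isinstance(roster, pd.DataFrame) else roster.copy()
    report = ValidationReport(n_rows=len(df))
    required = ["respondent_id", "pair_id", "community_id", "ea_id", "arm", "sex", "age"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        report.hard_errors.append(f"missing required columns: {missing}")
        return report
    if df["respondent_id"].duplicated().any():
        report.hard_errors.append("duplicate respondent ids")
    for child, parent in (("ea_id", "community_id"), ("community_id", "pair_id")):
        nunique = df.groupby(child)[parent].nunique()
        bad = nunique[nunique > 1]
        if len(bad):
            report.hard_errors.append(
                f"{child} values nested in multiple {parent}s: {list(bad.index[:5])}"
            )
    arm_check = df.groupby("community_id")["arm"].nunique()
    varying = arm_check[arm_check > 1]
    if len(varying):
        report.hard_errors.append(
            "arm varies within community(ies): " + ", ".join(map(str, varying.index))
        )
    keep = df["age"].between(18, 49)
    n_bad_age = int((~keep).sum())
    if n_bad_age:
        report.warnings.append(f"{n_bad_age} row(s) with age outside 18-49 excluded")
    report.n_excluded = n_bad_age
    report.data = df[keep].reset_index(drop=True) if report.ok else None
    return report


# ---------------------------------------------------------------------------
# analysis-frame builders (shared by reports, tests, acceptance runs)
# ---------------------------------------------------------------------------

def attach_baseline_prevalence(
    frame: pd.DataFrame,
    baseline: pd.DataFrame,
    outcome_col: str = "ipv",
    column: str = "ea_baseline_prev",
) -> pd.DataFrame:
    """Attach the baseline outcome prevalence as a covariate.

    Baseline EAs are re-drawn between waves, so the summary is carried at
    (community, sex) level: mean baseline prevalence (proportion) among
    respondents with a defined outcome.
    """
    base = baseline.dropna(subset=[outcome_col])
    prev = base.groupby(["community_id", "sex"])[outcome_col].mean()
    out = frame.copy()
    key = pd.MultiIndex.from_frame(out[["community_id", "sex"]])
    out[column] = prev.reindex(key).to_numpy()
    return out


def prepare_outcome_frame(
    followup: pd.DataFrame,
    baseline: pd.DataFrame | None = None,
    outcome_col: str = "ipv",
    sex: str | None = None,
) -> pd.DataFrame:
    """Analysis frame for the individual-level models: respondents with a
    defined outcome (partnered in the past year), decade age groups, and —
    when a baseline roster is supplied — the baseline prevalence covariate."""
    df = followup
    if sex is not None:
        df = df[df["sex"] == sex]
    df = df.dropna(subset=[outcome_col]).copy()
    df[outcome_col] = df[outcome_col].astype(float)
    df["age_group"] = categorize_age(df["age"])
    if baseline is not None:
        df = attach_baseline_prevalence(df, baseline, outcome_col=outcome_col)
    return df


def _matrix_outcome_frame(
    roster: pd.DataFrame, matrix: IndicatorMatrix,
    baseline_roster: pd.DataFrame, baseline_matrix: IndicatorMatrix,
    sex: str,
) -> pd.DataFrame:
    """Outcome frame built from indicator-matrix values (item-derived)."""
    indicator = _OUTCOME_BY_SEX[sex]
    values = matrix.values[indicator]
    df = roster[roster["sex"] == sex].copy()
    df["ipv"] = df["respondent_id"].map(values)
    base = baseline_roster[baseline_roster["sex"] == sex].copy()
    base_vals = baseline_matrix.values[_OUTCOME_BY_SEX[sex]]
    base["ipv"] = base["respondent_id"].map(base_vals)
    return prepare_outcome_frame(df, base, outcome_col="ipv", sex=sex)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _fmt_counts(values: pd.Series) -> str:
    n = int((values == 1.0).sum())
    N = int(values.notna().sum())
    pct = f"{100 * n / N:.0f}%" if N else "-"
    return f"{n}/{N} ({pct})"


def _itt_report(rosters, matrices, specs) -> pd.DataFrame:
    rows = []
    for sex in ("female", "male"):
        indicator = _OUTCOME_BY_SEX[sex]
        counts = {}
        for wave in ("baseline", "follow-up"):
            matrix = matrices[wave]
            mask = matrix.meta["sex"] == sex
            for arm in (1, 0):
                vals = matrix.values.loc[mask & (matrix.meta["arm"] == arm), indicator]
                counts[f"{wave}_arm{arm}"] = _fmt_counts(vals)
        frame = _matrix_outcome_frame(
            rosters["follow-up"].data, matrices["follow-up"],
            rosters["baseline"].data, matrices["baseline"], sex,
        )
        est = itt_effect(frame, "ipv", ADJUSTMENT_PRESETS["itt"])
        rows.append({
            "outcome": indicator,
            "reporter": _REPORTER_BY_SEX[sex],
            "baseline_intervention": counts["baseline_arm1"],
            "baseline_control": counts["baseline_arm0"],
            "followup_intervention": counts["follow-up_arm1"],
            "followup_control": counts["follow-up_arm0"],
            "aRR": round(est.estimate, 2),
            "ci_low": round(est.ci_low, 2),
            "ci_high": round(est.ci_high, 2),
            "adjustment": est.adjustment,
        })
    return pd.DataFrame(rows)


def _mediator_effects_report(rosters, matrices, specs, sex: str) -> pd.DataFrame:
    """Intervention effect on each mediator: EA-level mean differences for
    community indicators, cluster-level aRRs for binary indicators."""
    fu_matrix = matrices["follow-up"]
    fu_prev = ea_prevalence(fu_matrix)
    base_prev = ea_prevalence(matrices["baseline"])
    roster = rosters["follow-up"].data
    rows = []
    for spec in specs:
        if spec.hidden or spec.level == "outcome":
            continue
        if spec.reporter not in ("both", _REPORTER_BY_SEX[sex]):
            continue
        try:
            if spec.level == "community":
                est = adjusted_mean_difference(fu_prev, spec.name, sex=sex,
                                               baseline_summaries=base_prev)
                summary = est.mean_by_arm
                sds = est.sd_by_arm
                rows.append({
                    "indicator": spec.name, "level": spec.level,
                    "intervention_mean": round(summary.get(1, np.nan), 1),
                    "intervention_sd": round(sds.get(1) or np.nan, 1),
                    "control_mean": round(summary.get(0, np.nan), 1),
                    "control_sd": round(sds.get(0) or np.nan, 1),
                    "effect": round(est.difference, 1),
                    "ci_low": round(est.ci_low, 1),
                    "ci_high": round(est.ci_high, 1),
                    "measure": "adjusted mean difference",
                    "note": ";".join(est.flags),
                })
            else:
                df = roster[roster["sex"] == sex].copy()
                df["mediator"] = df["respondent_id"].map(fu_matrix.values[spec.name])
                df = df.dropna(subset=["mediator"])
                df["age_group"] = categorize_age(df["age"])
                est = itt_effect(df, "mediator", ADJUSTMENT_PRESETS["itt_mediator"])
                mask = (fu_matrix.meta["sex"] == sex)
                arm1 = fu_matrix.values.loc[mask & (fu_matrix.meta["arm"] == 1), spec.name]
                arm0 = fu_matrix.values.loc[mask & (fu_matrix.meta["arm"] == 0), spec.name]
                rows.append({
                    "indicator": spec.name, "level": spec.level,
                    "intervention_mean": _fmt_counts(arm1),
                    "intervention_sd": "",
                    "control_mean": _fmt_counts(arm0),
                    "control_sd": "",
                    "effect": round(est.estimate, 2),
                    "ci_low": round(est.ci_low, 2),
                    "ci_high": round(est.ci_high, 2),
                    "measure": "aRR",
                    "note": ";".join(est.flags),
                })
        except Exception as exc:  # per-indicator failures recorded in-row
            rows.append({
                "indicator": spec.name, "level": spec.level,
                "intervention_mean": "", "intervention_sd": "",
                "control_mean": "", "control_sd": "",
                "effect": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "measure": "error", "note": str(exc),
            })
    return pd.DataFrame(rows)


def _mediator_columns(frame, roster, matrix, specs, sex):
    """Attach every mediator of this reporter to the outcome frame; returns
    (frame, [(name, level, column)])."""
    fu_prev = ea_prevalence(matrix)
    out = frame
    mediators = []
    for spec in specs:
        if spec.hidden or spec.level == "outcome":
            continue
        if spec.reporter not in ("both", _REPORTER_BY_SEX[sex]):
            continue
        if spec.level == "community":
            sub = fu_prev[(fu_prev["indicator"] == spec.name) & (fu_prev["sex"] == sex)]
            col = f"x_{spec.name}"
            out = attach_community_exposure(out, sub, spec.name, scale=10.0,
                                            column=col)
        else:
            col = f"x_{spec.name}"
            out[col] = out["respondent_id"].map(matrix.values[spec.name])
        mediators.append((spec.name, spec.level, col))
    return out, mediators


def _association_report(rosters, matrices, specs) -> pd.DataFrame:
    rows = []
    for sex in ("female", "male"):
        frame = _matrix_outcome_frame(
            rosters["follow-up"].data, matrices["follow-up"],
            rosters["baseline"].data, matrices["baseline"], sex,
        )
        frame, mediators = _mediator_columns(frame, rosters["follow-up"].data,
                                             matrices["follow-up"], specs, sex)
        for name, level, col in mediators:
            try:
                est = risk_factor_association(frame, col)
                rows.append({
                    "indicator": name, "level": level,
                    "reporter": _REPORTER_BY_SEX[sex],
                    "aRR": round(est.estimate, 2),
                    "ci_low": round(est.ci_low, 2),
                    "ci_high": round(est.ci_high, 2),
                    "unit": ("per 10-point EA prevalence change"
                             if level == "community" else "with vs without"),
                    "n": est.n, "note": ";".join(est.flags),
                })
            except Exception as exc:
                rows.append({
                    "indicator": name, "level": level,
                    "reporter": _REPORTER_BY_SEX[sex],
                    "aRR": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "unit": "", "n": 0, "note": str(exc),
                })
    return pd.DataFrame(rows)


def _mediation_report(rosters, matrices, specs) -> pd.DataFrame:
    frames = []
    for sex in ("female", "male"):
        frame = _matrix_outcome_frame(
            rosters["follow-up"].data, matrices["follow-up"],
            rosters["baseline"].data, matrices["baseline"], sex,
        )
        frame, mediators = _mediator_columns(frame, rosters["follow-up"].data,
                                             matrices["follow-up"], specs, sex)
        table = mediation_table(
            frame, [(n, l, c) for n, l, c in mediators],
            reporter=_REPORTER_BY_SEX[sex],
        )
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write reports + manifest to outdir.

    Returns a dict of the in-memory report DataFrames.  Any stage failure
    raises :class:`PipelineError` naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    captured: list[str] = []

    # stage: indicator config
    try:
        if config.indicator_config:
            specs = parse_indicator_specs(Path(config.indicator_config).read_text())
        else:
            specs = load_default_specs()
    except Exception as exc:
        raise PipelineError("indicators", "config-parse", str(exc)) from exc

    # stage: inputs
    try:
        if config.sim is not None:
            sim = config.sim
            if config.seed is not None:
                sim = dataclasses.replace(sim, seed=config.seed)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                baseline, followup = generate_trial(sim, items=True)
            captured += [str(w.message) for w in caught]
            rosters = {"baseline": baseline, "follow-up": followup}
        else:
            frames = {}
            for wave, path in (("baseline", config.baseline_csv),
                               ("follow-up", config.followup_csv)):
                report = validate_inputs(path)
                if not report.ok:
                    raise PipelineError("validate", "structural",
                                        "; ".join(report.hard_errors))
                captured += report.warnings
                frames[wave] = report.data
            rosters = {
                wave: TrialRoster(
                    wave=wave, data=df,
                    community_pairs=df.set_index("community_id")["pair_id"].to_dict(),
                    community_arms=df.set_index("community_id")["arm"].to_dict(),
                )
                for wave, df in frames.items()
            }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("inputs", "load", str(exc)) from exc

    # stage: indicator matrices
    try:
        matrices = {wave: build_indicator_matrix(specs, roster.data)
                    for wave, roster in rosters.items()}
    except Exception as exc:
        raise PipelineError("indicators", "evaluate", str(exc)) from exc

    reports = {}
    for name, fn in (
        ("itt", lambda: _itt_report(rosters, matrices, specs)),
        ("mediator_effects_women",
         lambda: _mediator_effects_report(rosters, matrices, specs, "female")),
        ("mediator_effects_men",
         lambda: _mediator_effects_report(rosters, matrices, specs, "male")),
        ("associations", lambda: _association_report(rosters, matrices, specs)),
        ("mediation", lambda: _mediation_report(rosters, matrices, specs)),
    ):
        try:
            reports[name] = fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, "compute", str(exc)) from exc

    for name, df in reports.items():
        df.to_csv(outdir / f"{name}.csv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": (config.sim.seed if config.sim is not None else config.seed),
        "input_source": "simulation" if config.sim is not None else "csv",
        "sim_config": dataclasses.asdict(config.sim) if config.sim else None,
        "n_respondents": {w: len(r.data) for w, r in rosters.items()},
        "n_indicators": len([s for s in specs if not s.hidden]),
        "clamp_rates": {w: r.clamp_rate for w, r in rosters.items()},
        "warnings": captured,
        "reports": sorted(reports),
        "adjustment_presets": {k: list(v) for k, v in ADJUSTMENT_PRESETS.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    reports["manifest"] = manifest
    return reports


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig (and nested SimConfig) from YAML."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    sim = doc.pop("sim", None)
    cfg = RunConfig(**doc)
    if sim is not None:
        cfg.sim = SimConfig(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()
        })
    return cfg
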