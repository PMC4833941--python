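"""Composite survey indicators with eligibility denominators.

Item-level responses are turned into binary outcome/mediator indicators via
a declarative rule language (YAML).  Every indicator evaluates to one of
three states per respondent:

* ``True``  — eligible and the composite rule holds;
* ``False`` — eligible and the rule does not hold;
* ineligible (``NA``) — the eligibility predicate (or the reporter
  restriction, or an applicability predicate) fails.

Missing item responses follow the conservative act-list convention:
``any_of`` treats a missing item as non-qualifying unless *all* items are
missing (then the indicator is missing, excluded from both numerator and
denominator); ``all_of``/composites are missing when any needed item is
missing, except that a determinate ``False`` short-circuits missingness.

Denominator = count(True) + count(False), mirroring the "(among those
partnered in the past year)"-style restrictions of the source instrument.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Rule",
    "IndicatorSpec",
    "IndicatorMatrix",
    "IndicatorConfigError",
    "parse_indicator_specs",
    "load_default_specs",
    "evaluate_indicator",
    "build_indicator_matrix",
]

TRUE, FALSE, INELIGIBLE = 1.0, 0.0, np.nan
_LEVELS = ("outcome", "community", "relationship", "individual")
_REPORTERS = ("women", "men", "both")
_REPORTER_SEX = {"women": "female", "men": "male"}


class IndicatorConfigError(ValueError):
    """Malformed indicator configuration."""


@dataclass(frozen=True)
class Rule:
    """One composite rule node.

    kind:
        ``any_of`` / ``all_of`` over (item, qualifying values) pairs,
        ``value_in`` for a single item, ``negation`` of a subrule, or
        ``composite`` (conjunction of subrules).
    """

    kind: str
    items: tuple[tuple[str, tuple[str, ...]], ...] = ()
    subrules: tuple["Rule", ...] = ()

    def referenced_items(self) -> set[str]:
        out = {item for item, _ in self.items}
        for sub in self.subrules:
            out |= sub.referenced_items()
        return out


@dataclass(frozen=True)
class IndicatorSpec:
    name: str
    level: str
    reporter: str = "both"
    eligibility: str | None = None
    applicable_if: Rule | None = None
    rule: Rule | None = None
    reporter_rules: tuple[tuple[str, Rule], ...] = ()
    hidden: bool = False

    def rule_for(self, sex_label: str) -> Rule | None:
        if self.rule is not None:
            return self.rule
        for reporter, rule in self.reporter_rules:
            if _REPORTER_SEX.get(reporter) == sex_label:
                return rule
        return None

    def referenced_items(self) -> set[str]:
        out = set()
        for rule in (self.rule, self.applicable_if):
            if rule is not None:
                out |= rule.referenced_items()
        for _, rule in self.reporter_rules:
            out |= rule.referenced_items()
        return out

    def eligibility_indicator_refs(self) -> set[str]:
        if not self.eligibility:
            return set()
        return {
            atom.removeprefix("not ").removeprefix("indicator:")
            for atom in self.eligibility.split(" and ")
            if atom.removeprefix("not ").startswith("indicator:")
        }


@dataclass
class IndicatorMatrix:
    """Tri-state respondent x indicator matrix plus denominator report.

    ``values`` is coded 1 (true) / 0 (false) / NA (ineligible or missing);
    ``meta`` carries the design columns needed for aggregation.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    denominators: pd.DataFrame

    def to_csv(self, path) -> None:
        pd.concat([self.meta, self.values], axis=1).to_csv(path, index=True)

    @classmethod
    def from_csv(cls, path, indicator_names) -> "IndicatorMatrix":
        df = pd.read_csv(path, index_col=0)
        values = df[[c for c in df.columns if c in set(indicator_names)]]
        meta = df[[c for c in df.columns if c not in set(indicator_names)]]
        return cls(values=values, meta=meta,
                   denominators=_denominator_report(values, meta))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_rule(node, item_dict: dict[str, list[str]], context: str) -> Rule:
    if not isinstance(node, dict) or len(node) != 1:
        raise IndicatorConfigError(f"{context}: rule must be a single-key mapping")
    kind, body = next(iter(node.items()))
    if kind in ("any_of", "all_of"):
        if not isinstance(body, list) or len(body) == 0:
            raise IndicatorConfigError(f"{context}: {kind} requires >=1 item")
        items = tuple(_parse_item(entry, item_dict, context) for entry in body)
        return Rule(kind=kind, items=items)
    if kind == "value_in":
        return Rule(kind="value_in", items=(_parse_item(body, item_dict, context),))
    if kind == "not":
        return Rule(kind="negation", subrules=(_parse_rule(body, item_dict, context),))
    if kind == "all":
        if not isinstance(body, list) or len(body) == 0:
            raise IndicatorConfigError(f"{context}: composite requires >=1 subrule")
        return Rule(kind="composite",
                    subrules=tuple(_parse_rule(b, item_dict, context) for b in body))
    raise IndicatorConfigError(f"{context}: unknown rule kind {kind!r}")


def _parse_item(entry, item_dict, context) -> tuple[str, tuple[str, ...]]:
    if not isinstance(entry, dict) or "item" not in entry:
        raise IndicatorConfigError(f"{context}: item entry needs 'item' and 'values'")
    code = entry["item"]
    if code not in item_dict:
        raise IndicatorConfigError(f"{context}: unknown item code {code!r}")
    values = entry.get("values", ["yes"])
    if not isinstance(values, list) or not values:
        raise IndicatorConfigError(f"{context}: item {code!r} needs qualifying values")
    allowed = set(item_dict[code])
    bad = [v for v in values if v not in allowed]
    if bad:
        raise IndicatorConfigError(
            f"{context}: values {bad} not allowed for item {code!r} "
            f"(allowed: {sorted(allowed)})"
        )
    return (code, tuple(values))


def parse_indicator_specs(config_text: str) -> list[IndicatorSpec]:
    """Parse a YAML indicator configuration into validated specs."""
    doc = yaml.safe_load(config_text)
    if not isinstance(doc, dict) or "items" not in doc or "indicators" not in doc:
        raise IndicatorConfigError("config must define 'items' and 'indicators'")
    item_dict = {
        code: list(meta.get("values", ["yes", "no"]))
        for code, meta in doc["items"].items()
    }
    specs: list[IndicatorSpec] = []
    seen: set[str] = set()
    for entry in doc["indicators"]:
        name = entry.get("name")
        if not name:
            raise IndicatorConfigError("indicator without a name")
        if name in seen:
            raise IndicatorConfigError(f"duplicate indicator name {name!r}")
        seen.add(name)
        level = entry.get("level")
        if level not in _LEVELS:
            raise IndicatorConfigError(f"{name}: level must be one of {_LEVELS}")
        reporter = entry.get("reporter", "both")
        if reporter not in _REPORTERS:
            raise IndicatorConfigError(f"{name}: reporter must be one of {_REPORTERS}")
        rule = reporter_rules = None
        if "rule" in entry:
            rule = _parse_rule(entry["rule"], item_dict, name)
        elif "reporter_rules" in entry:
            reporter_rules = tuple(
                (rep, _parse_rule(r, item_dict, f"{name}[{rep}]"))
                for rep, r in entry["reporter_rules"].items()
            )
        else:
            raise IndicatorConfigError(f"{name}: needs 'rule' or 'reporter_rules'")
        applicable = (
            _parse_rule(entry["applicable_if"], item_dict, f"{name}.applicable_if")
            if "applicable_if" in entry else None
        )
        specs.append(
            IndicatorSpec(
                name=name,
                level=level,
                reporter=reporter,
                eligibility=entry.get("eligibility"),
                applicable_if=applicable,
                rule=rule,
                reporter_rules=reporter_rules or (),
                hidden=bool(entry.get("hidden", False)),
            )
        )
    by_name = {s.name for s in specs}
    for spec in specs:
        missing = spec.eligibility_indicator_refs() - by_name
        if missing:
            raise IndicatorConfigError(
                f"{spec.name}: eligibility references unknown indicator(s) {missing}"
            )
    return specs


def load_default_specs() -> list[IndicatorSpec]:
    """The shipped configuration: both IPV outcomes and the full mediator set."""
    text = (
        importlib.resources.files("crtmediate")
        .joinpath("data/indicators_default.yaml")
        .read_text()
    )
    return parse_indicator_specs(text)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _eval_rule(rule: Rule, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised rule evaluation -> (value bool array, missing bool array)."""
    n = len(data)
    if rule.kind in ("any_of", "all_of", "value_in"):
        qual = np.zeros((n, len(rule.items)), dtype=bool)
        miss = np.zeros((n, len(rule.items)), dtype=bool)
        for j, (item, values) in enumerate(rule.items):
            col = data[item] if item in data.columns else pd.Series(np.nan, index=data.index)
            miss[:, j] = col.isna().to_numpy()
            qual[:, j] = col.isin(values).to_numpy()
        if rule.kind in ("any_of",):
            value = qual.any(axis=1)
            missing = miss.all(axis=1) & ~value
            return value, missing
        if rule.kind == "value_in":
            return qual[:, 0], miss[:, 0]
        # all_of: determinate False (a non-missing, non-qualifying item) wins
        false = (~qual & ~miss).any(axis=1)
        missing = miss.any(axis=1) & ~false
        value = qual.all(axis=1)
        return value & ~missing, missing
    if rule.kind == "negation":
        value, missing = _eval_rule(rule.subrules[0], data)
        return ~value & ~missing, missing
    if rule.kind == "composite":
        results = [_eval_rule(sub, data) for sub in rule.subrules]
        false = np.zeros(n, dtype=bool)
        missing = np.zeros(n, dtype=bool)
        for value, miss in results:
            false |= ~value & ~miss
            missing |= miss
        missing &= ~false
        value = ~false & ~missing
        return value, missing
    raise IndicatorConfigError(f"unknown rule kind {rule.kind!r}")  # pragma: no cover


def _eval_predicate(expr: str, data: pd.DataFrame,
                    computed: dict[str, pd.Series]) -> np.ndarray:
    """Eligibility grammar: `atom [and atom]...`, atom = [not] column or
    [not] indicator:<name>."""
    mask = np.ones(len(data), dtype=bool)
    for atom in expr.split(" and "):
        atom = atom.strip()
        negate = atom.startswith("not ")
        if negate:
            atom = atom[4:].strip()
        if atom.startswith("indicator:"):
            name = atom.removeprefix("indicator:")
            if name not in computed:
                raise IndicatorConfigError(
                    f"eligibility references indicator {name!r} before it is computed"
                )
            vals = computed[name].to_numpy()
            truth = vals == 1.0
        else:
            if atom not in data.columns:
                raise IndicatorConfigError(f"eligibility column {atom!r} not in roster")
            truth = data[atom].fillna(0).to_numpy().astype(bool)
        mask &= ~truth if negate else truth
    return mask


def evaluate_indicator(spec: IndicatorSpec, data: pd.DataFrame,
                       computed: dict[str, pd.Series] | None = None) -> pd.Series:
    """Tri-state evaluation of one indicator over a roster frame.

    Returns a float Series: 1.0 / 0.0 / NaN (ineligible or missing).
    """
    computed = computed or {}
    n = len(data)
    out = np.full(n, INELIGIBLE)
    eligible = np.ones(n, dtype=bool)
    if spec.reporter in _REPORTER_SEX:
        eligible &= (data["sex"] == _REPORTER_SEX[spec.reporter]).to_numpy()
    if spec.eligibility:
        eligible &= _eval_predicate(spec.eligibility, data, computed)
    if spec.applicable_if is not None:
        app_value, app_missing = _eval_rule(spec.applicable_if, data)
        eligible &= app_value & ~app_missing
    if spec.rule is not None:
        value, missing = _eval_rule(spec.rule, data)
        ok = eligible & ~missing
        out[ok] = value[ok].astype(float)
    else:
        for reporter, rule in spec.reporter_rules:
            sex_mask = (data["sex"] == _REPORTER_SEX[reporter]).to_numpy()
            value, missing = _eval_rule(rule, data)
            ok = eligible & sex_mask & ~missing
            out[ok] = value[ok].astype(float)
    return pd.Series(out, index=data.index, name=spec.name)


_META_COLUMNS = ["pair_id", "community_id", "ea_id", "arm", "sex"]


def _denominator_report(values: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for name in values.columns:
        col = values[name]
        for sex, group in col.groupby(meta["sex"]):
            rows.append({
                "indicator": name,
                "sex": sex,
                "n_true": int((group == 1.0).sum()),
                "n_false": int((group == 0.0).sum()),
                "denominator": int(group.notna().sum()),
                "n_na": int(group.isna().sum()),
            })
    return pd.DataFrame(
        rows,
        columns=["indicator", "sex", "n_true", "n_false", "denominator", "n_na"],
    )


def build_indicator_matrix(specs: list[IndicatorSpec],
                           roster_data: pd.DataFrame) -> IndicatorMatrix:
    """Evaluate every spec over a roster, respecting eligibility chains.

    Indicators whose eligibility references another indicator (e.g. the
    disclosure indicator restricted to IPV reporters) are evaluated after
    their dependencies.
    """
    if roster_data["respondent_id"].duplicated().any():
        dupes = roster_data.loc[
            roster_data["respondent_id"].duplicated(), "respondent_id"
        ].tolist()
        raise ValueError(f"duplicate respondent id(s): {dupes[:5]}")
    data = roster_data.set_index("respondent_id")
    computed: dict[str, pd.Series] = {}
    pending = list(specs)
    ordered: list[IndicatorSpec] = []
    while pending:
        progressed = False
        for spec in list(pending):
            deps = spec.eligibility_indicator_refs()
            if deps <= {s.name for s in ordered}:
                ordered.append(spec)
                pending.remove(spec)
                progressed = True
        if not progressed:
            raise IndicatorConfigError(
                "circular indicator eligibility among "
                f"{[s.name for s in pending]}"
            )
    for spec in ordered:
        computed[spec.name] = evaluate_indicator(spec, data, computed)
    values = pd.DataFrame(
        {s.name: computed[s.name] for s in specs if not s.hidden}
    )
    meta_cols = [c for c in _META_COLUMNS if c in data.columns]
    meta = data[meta_cols].copy()
    return IndicatorMatrix(
        values=values, meta=meta,
        denominators=_denominator_report(values, meta),
    )
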