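"""Indicator rules: parsing, tri-state evaluation, denominators, round-trip."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crtmediate.indicator_engine import (
    IndicatorConfigError,
    Rule,
    build_indicator_matrix,
    evaluate_indicator,
    parse_indicator_specs,
    IndicatorMatrix,
)

from conftest import tiny_roster

MINI_CONFIG = """
items:
  a: {values: ["yes", "no"]}
  b: {values: ["yes", "no"]}
  freq: {values: [never, sometimes, often]}
indicators:
  - name: any_ab
    level: individual
    rule:
      any_of:
        - {item: a, values: ["yes"]}
        - {item: b, values: ["yes"]}
  - name: often_freq
    level: individual
    eligibility: partnered_past_year
    rule: {value_in: {item: freq, values: [often]}}
"""


# ---------------------------------------------------------------- parsing --

def test_default_config_covers_outcomes_and_mediators(specs):
    outcomes = [s for s in specs if s.level == "outcome"]
    mediators = [s for s in specs if not s.hidden and s.level != "outcome"]
    assert len(outcomes) == 2
    assert len(mediators) >= 24
    levels = {s.level for s in mediators}
    assert levels == {"community", "relationship", "individual"}
    # the 12-scenario acceptability battery is fully encoded
    battery = next(s for s in specs if s.name == "c_violence_acceptable")
    assert len(battery.rule.items) == 12
    # the men's anonymous-card measure is a single-item rule
    card = next(s for s in specs if s.name == "ipv_perpetration")
    assert card.rule.items[0][0] == "card_violence"


def test_unknown_item_names_offending_spec():
    bad = MINI_CONFIG.replace("item: b", "item: zz")
    with pytest.raises(IndicatorConfigError, match="any_ab"):
        parse_indicator_specs(bad)


def test_empty_any_of_rejected():
    bad = """
items:
  a: {values: ["yes", "no"]}
indicators:
  - name: broken
    level: individual
    rule: {any_of: []}
"""
    with pytest.raises(IndicatorConfigError, match="broken"):
        parse_indicator_specs(bad)


def test_duplicate_indicator_names_rejected():
    dup = MINI_CONFIG + MINI_CONFIG.split("indicators:")[1]
    with pytest.raises(IndicatorConfigError):
        parse_indicator_specs("indicators:".join([MINI_CONFIG, ""])
                              if False else dup)


def test_bad_level_and_value_rejected():
    with pytest.raises(IndicatorConfigError, match="level"):
        parse_indicator_specs(MINI_CONFIG.replace("level: individual",
                                                  "level: galaxy", 1))
    with pytest.raises(IndicatorConfigError, match="not allowed"):
        parse_indicator_specs(MINI_CONFIG.replace("values: [often]",
                                                  "values: [daily]"))


# ------------------------------------------------------------- evaluation --

def ipv_spec(specs):
    return next(s for s in specs if s.name == "ipv_experience")


def acts_row(**kw):
    base = {f: "no" for f in ("act_slap", "act_push", "act_fist", "act_kick",
                              "act_choke", "act_weapon", "act_panga")}
    base.update(kw)
    return base


def test_any_single_act_triggers_outcome(specs):
    roster = tiny_roster([acts_row(act_kick="yes")])
    out = evaluate_indicator(ipv_spec(specs), roster.set_index("respondent_id"))
    assert out.iloc[0] == 1.0


def test_all_acts_no_gives_false(specs):
    roster = tiny_roster([acts_row()])
    out = evaluate_indicator(ipv_spec(specs), roster.set_index("respondent_id"))
    assert out.iloc[0] == 0.0


def test_not_partnered_is_ineligible(specs):
    roster = tiny_roster([acts_row(act_slap="yes", partnered_past_year=0)])
    out = evaluate_indicator(ipv_spec(specs), roster.set_index("respondent_id"))
    assert np.isnan(out.iloc[0])


def test_missing_policy_any_of(specs):
    rows = [
        acts_row(act_slap=np.nan),                      # partial missing -> false
        {f: np.nan for f in acts_row()},                # all missing -> NA
        acts_row(act_slap=np.nan, act_push="yes"),      # missing + yes -> true
    ]
    roster = tiny_roster(rows)
    out = evaluate_indicator(ipv_spec(specs), roster.set_index("respondent_id"))
    assert out.iloc[0] == 0.0
    assert np.isnan(out.iloc[1])
    assert out.iloc[2] == 1.0


def test_missing_policy_all_of(specs):
    spec = next(s for s in specs if s.name == "r_discuss_day")
    rows = [
        dict(discuss_day_self="yes", discuss_day_partner=np.nan),  # -> NA
        dict(discuss_day_self="no", discuss_day_partner=np.nan),   # -> false
        dict(discuss_day_self="yes", discuss_day_partner="yes"),   # -> true
    ]
    roster = tiny_roster(rows)
    out = evaluate_indicator(spec, roster.set_index("respondent_id"))
    assert np.isnan(out.iloc[0])
    assert out.iloc[1] == 0.0
    assert out.iloc[2] == 1.0


def test_applicability_yields_ineligible(specs):
    spec = next(s for s in specs if s.name == "r_appreciate_house")
    rows = [
        dict(appreciate_house_applicable="no", appreciate_house="many_times"),
        dict(appreciate_house_applicable="yes", appreciate_house="many_times"),
        dict(appreciate_house_applicable="yes", appreciate_house="a_few"),
    ]
    roster = tiny_roster(rows)
    out = evaluate_indicator(spec, roster.set_index("respondent_id"))
    assert np.isnan(out.iloc[0])
    assert out.iloc[1] == 1.0 and out.iloc[2] == 0.0


def test_reporter_specific_finance_rules(specs):
    spec = next(s for s in specs if s.name == "r_finance_participation")
    rows = [
        dict(sex="female", finance_participated="yes"),
        dict(sex="male", finance_decided_alone="no"),
        dict(sex="male", finance_decided_alone="yes"),
    ]
    roster = tiny_roster(rows)
    out = evaluate_indicator(spec, roster.set_index("respondent_id"))
    assert out.tolist()[:2] == [1.0, 1.0]
    assert out.iloc[2] == 0.0


def test_mens_measure_ineligible_for_women(specs):
    spec = next(s for s in specs if s.name == "ipv_perpetration")
    roster = tiny_roster([dict(sex="female", card_violence="yes"),
                          dict(sex="male", card_violence="yes")])
    out = evaluate_indicator(spec, roster.set_index("respondent_id"))
    assert np.isnan(out.iloc[0]) and out.iloc[1] == 1.0


# --------------------------------------------------------- property tests --

@st.composite
def response_patterns(draw):
    return draw(st.lists(st.sampled_from(["yes", "no", None]),
                         min_size=1, max_size=6))


@settings(max_examples=200, derandomize=True)
@given(response_patterns())
def test_any_of_matches_bruteforce_oracle(pattern):
    items = {f"i{k}": {"values": ["yes", "no"]} for k in range(len(pattern))}
    rule = Rule("any_of", items=tuple((f"i{k}", ("yes",))
                                      for k in range(len(pattern))))
    df = pd.DataFrame({f"i{k}": [v] for k, v in enumerate(pattern)})
    from crtmediate.indicator_engine import _eval_rule
    value, missing = _eval_rule(rule, df)
    # oracle: missing counts as non-qualifying unless everything is missing
    if all(v is None for v in pattern):
        assert missing[0] and not value[0]
    else:
        assert value[0] == any(v == "yes" for v in pattern)
        assert not missing[0] or value[0] is False


@settings(max_examples=200, derandomize=True)
@given(response_patterns())
def test_all_of_matches_bruteforce_oracle(pattern):
    rule = Rule("all_of", items=tuple((f"i{k}", ("yes",))
                                      for k in range(len(pattern))))
    df = pd.DataFrame({f"i{k}": [v] for k, v in enumerate(pattern)})
    from crtmediate.indicator_engine import _eval_rule
    value, missing = _eval_rule(rule, df)
    if any(v == "no" for v in pattern):
        assert not value[0] and not missing[0]
    elif any(v is None for v in pattern):
        assert missing[0] and not value[0]
    else:
        assert value[0]


def test_tri_state_partition_and_denominators(followup_matrix):
    vals = followup_matrix.values
    assert vals.isin([0.0, 1.0]).to_numpy().sum() + vals.isna().to_numpy().sum() \
        == vals.size
    den = followup_matrix.denominators
    assert (den["denominator"] == den["n_true"] + den["n_false"]).all()


def test_monotonicity_adding_qualifying_response(specs, trial):
    """Flipping an act item to 'yes' never flips the outcome true->false."""
    data = trial[1].data.head(400).copy()
    spec = ipv_spec(specs)
    before = evaluate_indicator(spec, data.set_index("respondent_id"))
    data2 = data.copy()
    data2["act_slap"] = np.where(data2["act_slap"].notna(), "yes",
                                 data2["act_slap"])
    after = evaluate_indicator(spec, data2.set_index("respondent_id"))
    flipped_down = ((before == 1.0) & (after == 0.0)).sum()
    assert flipped_down == 0


# ------------------------------------------------------------ matrix level --

def test_duplicate_respondent_ids_hard_error(specs):
    roster = tiny_roster([acts_row(), acts_row()])
    roster["respondent_id"] = "R001"
    with pytest.raises(ValueError, match="duplicate"):
        build_indicator_matrix(specs, roster)


def test_empty_roster_gives_empty_matrix(specs):
    roster = tiny_roster([]).reindex(columns=tiny_roster([acts_row()]).columns)
    matrix = build_indicator_matrix(specs, roster)
    assert matrix.values.shape[0] == 0
    assert (matrix.denominators["denominator"] == 0).all() \
        or matrix.denominators.empty


def test_denominator_counts_partnered_subset(specs):
    rows = [acts_row(partnered_past_year=1) for _ in range(4)]
    rows += [acts_row(partnered_past_year=0) for _ in range(6)]
    matrix = build_indicator_matrix(specs, tiny_roster(rows))
    den = matrix.denominators
    row = den[(den.indicator == "ipv_experience") & (den.sex == "female")]
    assert int(row["denominator"].iloc[0]) == 4


def test_serialisation_round_trip_idempotent(followup_matrix, tmp_path):
    path = tmp_path / "matrix.csv"
    followup_matrix.to_csv(path)
    back = IndicatorMatrix.from_csv(path, followup_matrix.values.columns)
    pd.testing.assert_frame_equal(
        back.values, followup_matrix.values, check_dtype=False)
    path2 = tmp_path / "matrix2.csv"
    back.to_csv(path2)
    assert path.read_text() == path2.read_text()


def test_item_derived_indicators_match_generator_truth(trial, followup_matrix):
    """End-to-end: indicators recomputed from survey items equal the
    generator's latent truth columns."""
    data = trial[1].data.set_index("respondent_id")
    vals = followup_matrix.values
    women = data[data.sex == "female"]
    assert vals.loc[women.index, "ipv_experience"].equals(
        women["ipv"].astype(float))
    men = data[data.sex == "male"]
    assert vals.loc[men.index, "ipv_perpetration"].equals(
        men["ipv"].astype(float))
    assert vals["c_violence_acceptable"].equals(
        data["true_attitude"].astype(float))
    # a sample of latent mediators, respecting eligibility masks
    partnered = data["partnered_past_year"] == 1
    got = vals.loc[partnered, "r_discuss_worries"]
    want = data.loc[partnered, "m_discuss_worries"].astype(float)
    assert got.equals(want)
    witnessed = data["witnessed_ipv"] == 1
    got = vals.loc[witnessed, "c_responded_appropriately"]
    want = data.loc[witnessed, "m_responded_appropriately"].astype(float)
    assert got.equals(want)
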