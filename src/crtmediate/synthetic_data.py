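"""Synthetic pair-matched community-randomised-trial survey generator.

The generator emulates a trial in which eight communities (four matched
pairs, one community per arm within each pair) receive or do not receive a
community-mobilisation intervention aimed at shifting norms around intimate
partner violence (IPV).  Each community contributes single-sex census
enumeration areas (EAs) of roughly 28 respondents; two cross-sectional
waves (baseline, follow-up) are drawn from the same communities.

The data-generating process routes a configurable fraction ``lambda`` of
the total intervention effect through a community-norm pathway:

* community norm propensity  ``pi_c = expit(b0 + delta*arm + u_pair + v_comm)``
* EA-level propensity        ``pi_ea = expit(logit(pi_c) + jitter)``
* individual attitude        ``a_i ~ Bernoulli(pi_ea)``
* realized EA norm level     ``P_ea = mean(a_i)`` over the EA roster
* outcome risk (log link)::

      log p_i = log(p0) + covariate terms + attitude effect
                + (1 - lambda) * beta * arm          # direct path
                + theta * (P_ea - m0)                # norm path

where ``beta`` is the total target arm log risk-ratio, ``m0`` the expected
control-arm norm level, and ``theta`` is calibrated internally (bisection
against a Monte-Carlo estimate of the marginal arm RR) so that the TOTAL
marginal risk ratio equals ``exp(beta)`` for any ``lambda`` in [0, 1].
Risks are clamped to (0, 1); the clamp rate is surfaced as a diagnostic.

Using the *realized* EA attitude prevalence (rather than the latent
propensity) as the outcome exposure means the survey-measured mediator is
exactly the quantity that drives risk, so the mediated fraction maps
cleanly onto the attenuation recovered downstream.

Randomness is organised as one stream per (seed, wave, community, EA,
variable), so enlarging an EA extends, but never shifts, earlier draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

__all__ = [
    "SimConfig",
    "TrialRoster",
    "generate_trial",
    "true_marginal_rr",
    "COLUMN_DICTIONARY",
]

_CAP = 1.0 - 1e-6
_FLOOR = 1e-12
_CAL_SEED = 987_654_321  # internal: calibration is a pure function of the DGP
_MRR_SEED = 192_837_465

MARITAL_LEVELS = ("married", "partnered_unmarried", "formerly_partnered")
EDUCATION_LEVELS = ("none_or_primary", "secondary", "higher")
_MARITAL_P = np.array([0.60, 0.25, 0.15])
_EDU_P = np.array([0.45, 0.40, 0.15])
_PARTNERED_P = np.array([0.97, 0.92, 0.30])   # by marital level
_COHAB_P = np.array([0.92, 0.45, 0.05])       # by marital level, given partnered
_WITNESSED_P = 0.45
_POLYGAMOUS_P = 0.10
_EVER_PARTNERED_EXTRA = 0.15


@dataclass(frozen=True)
class _Latent:
    """One generated mediator: base prevalence plus a logit shift when the
    respondent holds the violence-accepting attitude."""

    name: str
    base_p: float
    att_coef: float
    eligibility: str | None = None  # column gating whether the item is asked


# Mediators other than the calibrated norm pathway depend on the intervention
# only through the individual's attitude (conditional draws).
_LATENTS: tuple[_Latent, ...] = (
    _Latent("intervene_ok", 0.50, -0.4),
    _Latent("responded_appropriately", 0.35, -0.5, "witnessed_ipv"),
    _Latent("refuse_sex_ok", 0.60, -0.5),
    _Latent("condom_ok", 0.55, -0.5),
    _Latent("respect_joint", 0.50, -0.5),
    _Latent("man_decides_work", 0.55, 0.6),
    _Latent("tell_others_ok", 0.60, -0.5),
    _Latent("drunk_monthly", 0.20, 0.4),
    _Latent("discuss_day", 0.75, -0.5, "partnered_past_year"),
    _Latent("discuss_worries", 0.75, -0.5, "partnered_past_year"),
    _Latent("discuss_sex", 0.55, -0.5, "partnered_past_year"),
    _Latent("appreciate_house", 0.60, -0.5, "partnered_past_year"),
    _Latent("appreciate_outside", 0.65, -0.5, "partnered_past_year"),
    _Latent("joint_decisions", 0.60, -0.6, "partnered_past_year"),
    _Latent("man_helps_house", 0.60, -0.5, "cohabiting"),
    _Latent("refused_job", 0.20, 0.5, "partnered_past_year"),
    _Latent("finance_participation", 0.70, -0.4, "cohabiting"),
    _Latent("concurrent_partners", 0.06, 0.4, "partnered_past_year"),
    _Latent("partner_suspicious", 0.20, 0.6, "partnered_past_year"),
    _Latent("separated_divorced", 0.03, 0.3, "ever_partnered_year"),
    _Latent("told_someone", 0.50, 0.0, None),  # asked only of IPV reporters
)

# variable-id registry for per-(seed, wave, community, ea, variable) streams
_VAR_NAMES = [
    "ea_size", "norm_jitter", "age", "marital", "education", "childhood_abuse",
    "partnered", "cohabiting", "witnessed", "polygamous", "ever_partnered",
    "attitude", "outcome", "applicable_house", "applicable_outside",
] + [f"latent_{l.name}" for l in _LATENTS] + [f"items_{l.name}" for l in _LATENTS] + [
    "items_attitude", "items_outcome", "items_missing",
]
_VAR = {name: i for i, name in enumerate(_VAR_NAMES)}

ACT_ITEMS = (
    "act_slap", "act_push", "act_fist", "act_kick",
    "act_choke", "act_weapon", "act_panga",
)
ATT_ITEMS = (
    "att_disobey", "att_answers_back", "att_disrespect",
    "att_suspect_unfaithful", "att_unfaithful", "att_gossip",
    "att_neglect_children", "att_housework", "att_refuse_sex",
    "att_accuse_infidelity", "att_secrets", "att_angry",
)
RESPONSE_ITEMS = (
    "resp_gathered", "resp_knocked", "resp_separated",
    "resp_informed_authority", "resp_advised_woman_authority",
    "resp_asked_woman", "resp_told_man_unacceptable",
    "resp_advised_man_authority", "resp_helped_man_stop",
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic trial.

    Structural defaults mirror the emulated trial: 4 matched pairs of
    communities, ~12 single-sex EAs per community at follow-up (8 at
    baseline), mean EA size 28 within [18, 35], and a total intervention
    effect of RR 0.45 on the binary IPV outcome.  Variance components and
    the norm shift are documented artifact choices (see docs/methods.md).
    """

    n_pairs: int = 4
    eas_per_community: int = 12
    baseline_eas_per_community: int = 8
    ea_size_mean: float = 28.0
    ea_size_range: tuple[int, int] = (18, 35)
    ea_size_sd: float = 4.0
    arm_log_rr: float = math.log(0.45)
    mediated_fraction: float = 0.7
    norm_shift: float = -1.0          # logit-scale arm effect on norm prevalence
    norm_intercept: float = 0.0       # control-arm norm level ~ 50%
    sigma_pair: float = 0.25
    sigma_community: float = 0.35
    ea_norm_jitter_sd: float = 0.30
    baseline_prevalence: float = 0.30
    age_log_rr: float = -0.010        # per year, centred at 30
    marital_log_rr: tuple[float, float, float] = (0.0, 0.15, 0.30)
    education_log_rr: tuple[float, float, float] = (0.0, -0.10, -0.20)
    childhood_abuse_log_rr: float = 0.35
    childhood_abuse_rate: float = 0.30
    attitude_log_rr: float = 0.0      # individual attitude -> outcome, log scale
    clamp_warn_threshold: float = 0.01
    item_missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.mediated_fraction <= 1.0:
            raise ValueError("mediated_fraction must be in [0, 1]")
        lo, hi = self.ea_size_range
        if not lo <= self.ea_size_mean <= hi:
            raise ValueError("ea_size_range must bracket ea_size_mean")
        for name in ("sigma_pair", "sigma_community", "ea_norm_jitter_sd", "ea_size_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be in [0, 2**31)")
        if not 0.0 <= self.item_missing_rate < 1.0:
            raise ValueError("item_missing_rate must be in [0, 1)")


@dataclass
class TrialRoster:
    """One survey wave: respondent table plus the design maps."""

    wave: str
    data: pd.DataFrame
    community_pairs: dict[str, str]
    community_arms: dict[str, int]
    clamp_rate: float = 0.0

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


COLUMN_DICTIONARY = {
    "respondent_id": "unique respondent identifier",
    "pair_id": "matched community pair",
    "community_id": "community (randomisation unit / site)",
    "ea_id": "census enumeration area (single sex)",
    "arm": "0 control / 1 intervention",
    "sex": "female | male (EA-level segregation)",
    "age": "years, 18-49",
    "marital_status": " | ".join(MARITAL_LEVELS),
    "education": " | ".join(EDUCATION_LEVELS),
    "childhood_abuse": "1 = experienced/witnessed abuse in childhood",
    "partnered_past_year": "1 = had a regular/casual partner in past year",
    "cohabiting": "1 = lives with partner",
    "witnessed_ipv": "1 = has seen/heard IPV in the community",
    "polygamous": "1 = polygamous union",
    "ever_partnered_year": "1 = married/partnered at some point in past year",
    "true_attitude": "latent violence-accepting attitude (0/1)",
    "true_norm_propensity": "EA-level latent norm propensity pi_ea",
    "true_ea_norm_prev": "realized EA attitude prevalence P_ea (0-1)",
    "true_outcome_risk": "clamped individual outcome risk",
    "ipv": "IPV outcome (0/1; NA when not partnered in past year)",
    "m_<name>": "latent mediator truth columns (0/1)",
    "item columns": "survey item responses (only when items=True)",
}


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(tuple(int(k) for k in key)))


def _ea_rng(seed: int, wave_i: int, comm_i: int, ea_i: int, var: int) -> np.random.Generator:
    """Counter-based stream keyed by (seed, wave, community, EA, variable):
    adding respondents to an EA extends, but never shifts, earlier draws."""
    if not (comm_i < 4096 and ea_i < 4096 and var < 128):
        raise ValueError("structure too large for packed stream keys")
    key = (int(seed) | (wave_i << 31) | (comm_i << 33) | (ea_i << 45) | (var << 57))
    return np.random.Generator(np.random.Philox(key=key))


@lru_cache(maxsize=32)
def _truncnorm_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter so the truncated normal has the requested mean."""
    if sd == 0:
        return mean

    def f(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    return float(brentq(f, lo - 5 * sd, hi + 5 * sd, xtol=1e-10))


def _dgp_key(config: SimConfig) -> tuple:
    """Calibration cache key: every parameter of the DGP except the seed and
    structural counts that do not move the marginal risk ratio."""
    return (
        config.ea_size_mean, config.arm_log_rr, config.mediated_fraction,
        config.norm_shift, config.norm_intercept, config.sigma_pair,
        config.sigma_community, config.ea_norm_jitter_sd,
        config.baseline_prevalence, config.age_log_rr, config.marital_log_rr,
        config.education_log_rr, config.childhood_abuse_log_rr,
        config.childhood_abuse_rate, config.attitude_log_rr,
    )


def _mc_components(config: SimConfig, n: int, rng: np.random.Generator):
    """Monte-Carlo draws of everything entering the marginal risk ratio."""
    u = rng.normal(0.0, config.sigma_pair, n)
    v = rng.normal(0.0, config.sigma_community, n)
    jit = rng.normal(0.0, config.ea_norm_jitter_sd, n)
    n_ea = max(int(round(config.ea_size_mean)), 1)
    pi_ea = {}
    p_ea = {}
    att = {}
    for arm in (0, 1):
        pi_c = expit(config.norm_intercept + config.norm_shift * arm + u + v)
        pi = expit(logit(pi_c) + jit)
        pi_ea[arm] = pi
        p_ea[arm] = rng.binomial(n_ea, pi) / n_ea
        att[arm] = (rng.random(n) < pi).astype(float)
    age = rng.integers(18, 50, n)
    marital = rng.choice(3, size=n, p=_MARITAL_P)
    edu = rng.choice(3, size=n, p=_EDU_P)
    abuse = (rng.random(n) < config.childhood_abuse_rate).astype(float)
    lp_cov = (
        config.age_log_rr * (age - 30)
        + np.asarray(config.marital_log_rr)[marital]
        + np.asarray(config.education_log_rr)[edu]
        + config.childhood_abuse_log_rr * abuse
    )
    base = math.log(config.baseline_prevalence) + lp_cov
    return base, p_ea, att


def _marginal_log_rr(config: SimConfig, theta: float, base, p_ea, att, m0) -> float:
    lam, beta = config.mediated_fraction, config.arm_log_rr
    r1 = np.clip(
        np.exp(base + (1 - lam) * beta + theta * (p_ea[1] - m0)
               + config.attitude_log_rr * att[1]),
        _FLOOR, _CAP,
    )
    r0 = np.clip(
        np.exp(base + theta * (p_ea[0] - m0) + config.attitude_log_rr * att[0]),
        _FLOOR, _CAP,
    )
    return float(np.log(r1.mean()) - np.log(r0.mean()))


@lru_cache(maxsize=64)
def _calibrate_cached(key: tuple) -> tuple[float, float]:
    config = _CAL_CONFIGS.pop(key)
    rng = _rng(_CAL_SEED)
    base, p_ea, att = _mc_components(config, 200_000, rng)
    m0 = float(p_ea[0].mean())
    lam, beta = config.mediated_fraction, config.arm_log_rr
    if lam == 0.0 and (config.attitude_log_rr == 0.0 or config.norm_shift == 0.0):
        return 0.0, m0
    if beta == 0.0 and config.attitude_log_rr == 0.0:
        return 0.0, m0

    def f(theta):
        return _marginal_log_rr(config, theta, base, p_ea, att, m0) - beta

    lo, hi = -20.0, 20.0
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise RuntimeError("theta calibration failed to bracket the target")
    xtol = max(abs(0.005 * beta), 1e-5)
    theta = float(brentq(f, lo, hi, xtol=xtol))
    return theta, m0


_CAL_CONFIGS: dict[tuple, SimConfig] = {}


def calibrate_norm_effect(config: SimConfig) -> tuple[float, float]:
    """Return (theta, m0): norm-path coefficient calibrated so the marginal
    arm risk ratio equals exp(arm_log_rr), and the control-arm mean norm
    level.  Cached across configs that share a DGP (seed excluded)."""
    config.validate()
    key = _dgp_key(config)
    _CAL_CONFIGS[key] = config
    out = _calibrate_cached(key)
    _CAL_CONFIGS.pop(key, None)
    return out


def true_marginal_rr(config: SimConfig, n_draws: int = 1_000_000) -> float:
    """Population marginal risk ratio implied by the DGP (large MC draw).

    A pure function of the configuration (internal fixed MC seed), used as
    the recovery target in simulation studies.
    """
    config.validate()
    theta, m0 = calibrate_norm_effect(config)
    rng = _rng(_MRR_SEED)
    base, p_ea, att = _mc_components(config, int(n_draws), rng)
    return float(np.exp(_marginal_log_rr(config, theta, base, p_ea, att, m0)))


# ---------------------------------------------------------------------------
# roster generation
# ---------------------------------------------------------------------------

def _structure(config: SimConfig):
    pairs, communities = [], []
    for p in range(config.n_pairs):
        pair_id = f"P{p + 1}"
        pairs.append(pair_id)
        first_arm = int(_rng(config.seed, 90_000, p).integers(0, 2))
        for k in range(2):
            cid = f"C{2 * p + k + 1:02d}"
            communities.append(
                {"community_id": cid, "pair_id": pair_id,
                 "arm": first_arm if k == 0 else 1 - first_arm,
                 "pair_index": p, "community_index": 2 * p + k}
            )
    return pairs, communities


def _random_effects(config: SimConfig, communities):
    u = {c["pair_id"]: float(_rng(config.seed, 91_000, c["pair_index"]).normal(0, config.sigma_pair))
         for c in communities}
    v = {c["community_id"]: float(_rng(config.seed, 92_000, c["community_index"]).normal(0, config.sigma_community))
         for c in communities}
    return u, v


def _ea_sizes(config: SimConfig, wave_i: int, comm_i: int, n_eas: int) -> np.ndarray:
    lo, hi = config.ea_size_range
    if config.ea_size_sd == 0:
        return np.full(n_eas, int(round(config.ea_size_mean)))
    loc = _truncnorm_loc(config.ea_size_mean, config.ea_size_sd, lo - 0.499, hi + 0.499)
    a, b = (lo - 0.499 - loc) / config.ea_size_sd, (hi + 0.499 - loc) / config.ea_size_sd
    uns = np.array([
        _ea_rng(config.seed, wave_i, comm_i, e, _VAR["ea_size"]).random()
        for e in range(n_eas)
    ])
    raw = truncnorm.ppf(uns, a, b, loc=loc, scale=config.ea_size_sd)
    return np.clip(np.round(raw), lo, hi).astype(int)


def _choice_from_uniform(u: np.ndarray, probs: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.cumsum(probs), u, side="right").clip(0, len(probs) - 1)


def _generate_wave(config, wave: str, wave_i: int, communities, u_pair, v_comm,
                   theta: float, m0: float, items: bool):
    lam, beta = config.mediated_fraction, config.arm_log_rr
    arm_on = 1 if wave == "follow-up" else 0  # baseline: arm coefficient forced to 0
    n_eas = (config.eas_per_community if wave == "follow-up"
             else config.baseline_eas_per_community)
    chunks: dict[str, list[np.ndarray]] = {}
    clamped = 0
    total = 0

    def emit(cols: dict) -> None:
        for name, arr in cols.items():
            chunks.setdefault(name, []).append(np.asarray(arr))

    for comm in communities:
        ci = comm["community_index"]
        arm = comm["arm"]
        pi_c = expit(config.norm_intercept + config.norm_shift * arm * arm_on
                     + u_pair[comm["pair_id"]] + v_comm[comm["community_id"]])
        sizes = _ea_sizes(config, wave_i, ci, n_eas)
        for e in range(n_eas):
            n = int(sizes[e])
            sex = "female" if e < (n_eas + 1) // 2 else "male"
            ea_id = f"{comm['community_id']}-{wave_i}-EA{e + 1:02d}"

            def rng(var: str) -> np.random.Generator:
                return _ea_rng(config.seed, wave_i, ci, e, _VAR[var])

            jit = float(rng("norm_jitter").normal(0, config.ea_norm_jitter_sd))
            pi_ea = float(expit(logit(pi_c) + jit))

            age = rng("age").integers(18, 50, n)
            marital = _choice_from_uniform(rng("marital").random(n), _MARITAL_P)
            edu = _choice_from_uniform(rng("education").random(n), _EDU_P)
            abuse = rng("childhood_abuse").random(n) < config.childhood_abuse_rate
            partnered = rng("partnered").random(n) < _PARTNERED_P[marital]
            cohab = (rng("cohabiting").random(n) < _COHAB_P[marital]) & partnered
            witnessed = rng("witnessed").random(n) < _WITNESSED_P
            polygamous = (rng("polygamous").random(n) < _POLYGAMOUS_P) & partnered
            ever = partnered | (rng("ever_partnered").random(n) < _EVER_PARTNERED_EXTRA)

            attitude = (rng("attitude").random(n) < pi_ea).astype(int)
            p_ea = float(attitude.mean())

            lp = (
                math.log(config.baseline_prevalence)
                + config.age_log_rr * (age - 30)
                + np.asarray(config.marital_log_rr)[marital]
                + np.asarray(config.education_log_rr)[edu]
                + config.childhood_abuse_log_rr * abuse
                + config.attitude_log_rr * attitude
                + (1 - lam) * beta * arm * arm_on
                + theta * (p_ea - m0)
            )
            raw = np.exp(lp)
            clamped += int(((raw > _CAP) | (raw < _FLOOR)).sum())
            total += n
            risk = np.clip(raw, _FLOOR, _CAP)
            y = (rng("outcome").random(n) < risk).astype(float)
            ipv = np.where(partnered, y, np.nan)

            cols = {
                "respondent_id": np.array(
                    [f"{ea_id}-R{i + 1:03d}" for i in range(n)], dtype=object),
                "pair_id": np.full(n, comm["pair_id"], dtype=object),
                "community_id": np.full(n, comm["community_id"], dtype=object),
                "ea_id": np.full(n, ea_id, dtype=object),
                "arm": np.full(n, arm),
                "sex": np.full(n, sex, dtype=object),
                "age": age,
                "marital_status": np.asarray(MARITAL_LEVELS, object)[marital],
                "education": np.asarray(EDUCATION_LEVELS, object)[edu],
                "childhood_abuse": abuse.astype(int),
                "partnered_past_year": partnered.astype(int),
                "cohabiting": cohab.astype(int),
                "witnessed_ipv": witnessed.astype(int),
                "polygamous": polygamous.astype(int),
                "ever_partnered_year": ever.astype(int),
                "true_attitude": attitude,
                "true_norm_propensity": np.full(n, pi_ea),
                "true_ea_norm_prev": np.full(n, p_ea),
                "true_outcome_risk": risk,
                "ipv": ipv,
            }

            latents = {}
            for lat in _LATENTS:
                p_m = expit(logit(lat.base_p) + lat.att_coef * attitude)
                latents[lat.name] = (rng(f"latent_{lat.name}").random(n) < p_m).astype(int)
            for name, val in latents.items():
                cols[f"m_{name}"] = val

            if items:
                cols.update(
                    _materialize_items(config, rng, n, sex, attitude, ipv,
                                       partnered, cohab, witnessed, polygamous,
                                       ever, latents)
                )
            emit(cols)

    data = pd.DataFrame(
        {name: np.concatenate(parts) for name, parts in chunks.items()}
    )
    if items and config.item_missing_rate > 0:
        miss_rng = _rng(config.seed, wave_i, 99_999, _VAR["items_missing"])
        for col in data.columns:
            if _is_item_column(col):
                mask = miss_rng.random(len(data)) < config.item_missing_rate
                data.loc[mask, col] = np.nan
    roster = TrialRoster(
        wave=wave,
        data=data,
        community_pairs={c["community_id"]: c["pair_id"] for c in communities},
        community_arms={c["community_id"]: c["arm"] for c in communities},
        clamp_rate=clamped / max(total, 1),
    )
    return roster


_ITEM_PREFIXES = ("act_", "att_", "resp_")
_ITEM_NAMES = {
    "card_violence", "intervene_ok", "helped_when_witnessed", "refuse_sex_ok",
    "condom_ok", "respect_joint_decisions", "man_decides_work",
    "discuss_day_self", "discuss_day_partner", "discuss_worries",
    "sex_asked_partner", "sex_told_partner", "appreciate_house",
    "appreciate_house_applicable", "appreciate_outside",
    "appreciate_outside_applicable", "joint_decisions_freq", "man_helps_house",
    "refused_job", "finance_participated", "finance_decided_alone",
    "concurrent_partner", "partner_suspicious", "current_status",
    "tell_others_ok", "drunk_freq", "told_someone",
}


def _is_item_column(col: str) -> bool:
    return col in _ITEM_NAMES or col.startswith(_ITEM_PREFIXES)


def _obj(n):
    return np.full(n, np.nan, dtype=object)


def _yes_no(mask, truth, n):
    out = _obj(n)
    out[mask & (truth == 1)] = "yes"
    out[mask & (truth == 0)] = "no"
    return out


def _any_of_items(out, items, truth, mask, rng, p_item=0.45):
    n = truth.shape[0]
    k = len(items)
    draws = rng.random((n, k)) < p_item
    none = draws.sum(axis=1) == 0
    idx = np.where(none)[0]
    draws[idx, rng.integers(0, k, idx.size)] = True
    for j, item in enumerate(items):
        col = _obj(n)
        hit = draws[:, j] & (truth == 1)
        col[mask & (truth == 1)] = "no"
        col[mask & hit] = "yes"
        col[mask & (truth == 0)] = "no"
        out[item] = col


def _value_pick(mask, truth, rng, true_vals, false_vals, n):
    out = _obj(n)
    t_idx = np.where(mask & (truth == 1))[0]
    f_idx = np.where(mask & (truth == 0))[0]
    out[t_idx] = np.asarray(true_vals, object)[rng.integers(0, len(true_vals), t_idx.size)]
    out[f_idx] = np.asarray(false_vals, object)[rng.integers(0, len(false_vals), f_idx.size)]
    return out


def _all_of_items(out, items, truth, mask, rng):
    n = truth.shape[0]
    k = len(items)
    draws = rng.random((n, k)) < 0.5
    all_yes = draws.all(axis=1)
    idx = np.where(all_yes)[0]
    draws[idx, rng.integers(0, k, idx.size)] = False
    for j, item in enumerate(items):
        col = _obj(n)
        col[mask & (truth == 1)] = "yes"
        fmask = mask & (truth == 0)
        col[fmask] = np.where(draws[fmask.nonzero()[0], j], "yes", "no")
        out[item] = col


def _materialize_items(config, rng, n, sex, attitude, ipv, partnered, cohab,
                       witnessed, polygamous, ever, latents):
    """Emit item-level responses consistent with the latent indicator truths."""
    out: dict[str, np.ndarray] = {}
    partnered = partnered.astype(bool)
    cohab = cohab.astype(bool)
    witnessed = witnessed.astype(bool)
    ever = ever.astype(bool)
    has_ipv = np.nan_to_num(ipv, nan=0.0).astype(int)

    # outcome items: act list for women, anonymous card for men
    if sex == "female":
        _any_of_items(out, ACT_ITEMS, has_ipv, partnered, rng("items_outcome"))
        for item in ACT_ITEMS:
            out[item][~partnered] = np.nan
        out["card_violence"] = _obj(n)
    else:
        for item in ACT_ITEMS:
            out[item] = _obj(n)
        out["card_violence"] = _yes_no(partnered, has_ipv, n)

    # 12-scenario attitude battery (all respondents)
    _any_of_items(out, ATT_ITEMS, attitude, np.ones(n, bool), rng("items_attitude"),
                  p_item=0.35)

    all_mask = np.ones(n, bool)
    out["intervene_ok"] = _yes_no(all_mask, latents["intervene_ok"], n)

    # witnessed-response composite: helped AND >=1 appropriate response
    r_resp = rng("items_responded_appropriately")
    resp_truth = latents["responded_appropriately"]
    helped = _obj(n)
    helped[witnessed & (resp_truth == 1)] = "yes"
    false_w = witnessed & (resp_truth == 0)
    helped_anyway = r_resp.random(n) < 0.5
    helped[false_w & helped_anyway] = "yes"
    helped[false_w & ~helped_anyway] = "no"
    out["helped_when_witnessed"] = helped
    resp_mask = witnessed & (helped == "yes")
    resp_value = np.where(resp_mask, resp_truth, 0)
    _any_of_items(out, RESPONSE_ITEMS, resp_value, resp_mask, r_resp, p_item=0.3)

    out["refuse_sex_ok"] = _yes_no(all_mask, latents["refuse_sex_ok"], n)
    out["condom_ok"] = _yes_no(all_mask, latents["condom_ok"], n)
    out["respect_joint_decisions"] = _yes_no(all_mask, latents["respect_joint"], n)
    out["man_decides_work"] = _yes_no(all_mask, latents["man_decides_work"], n)
    out["tell_others_ok"] = _yes_no(all_mask, latents["tell_others_ok"], n)
    out["drunk_freq"] = _value_pick(
        all_mask, latents["drunk_monthly"], rng("items_drunk_monthly"),
        ("once_a_month", "weekly", "most_days"),
        ("never", "less_than_monthly"), n,
    )

    _all_of_items(out, ("discuss_day_self", "discuss_day_partner"),
                  latents["discuss_day"], partnered, rng("items_discuss_day"))
    out["discuss_worries"] = _yes_no(partnered, latents["discuss_worries"], n)
    _all_of_items(out, ("sex_asked_partner", "sex_told_partner"),
                  latents["discuss_sex"], partnered, rng("items_discuss_sex"))

    for stem, var in (("appreciate_house", "applicable_house"),
                      ("appreciate_outside", "applicable_outside")):
        r_app = rng(var)
        applicable = (r_app.random(n) < 0.9) & partnered
        out[f"{stem}_applicable"] = _yes_no(partnered, applicable.astype(int), n)
        out[stem] = _value_pick(
            applicable, latents[stem], rng(f"items_{stem}"),
            ("many_times",), ("none", "a_few"), n,
        )

    out["joint_decisions_freq"] = _value_pick(
        partnered, latents["joint_decisions"], rng("items_joint_decisions"),
        ("most_of_time", "all_of_time"), ("never", "sometimes"), n,
    )
    out["man_helps_house"] = _yes_no(partnered & cohab, latents["man_helps_house"], n)
    out["refused_job"] = _yes_no(partnered, latents["refused_job"], n)

    fin = latents["finance_participation"]
    fin_mask = partnered & cohab
    if sex == "female":
        out["finance_participated"] = _yes_no(fin_mask, fin, n)
        out["finance_decided_alone"] = _obj(n)
    else:
        out["finance_participated"] = _obj(n)
        out["finance_decided_alone"] = _yes_no(fin_mask, 1 - fin, n)

    out["concurrent_partner"] = _yes_no(
        partnered & ~polygamous.astype(bool), latents["concurrent_partners"], n)
    out["partner_suspicious"] = _yes_no(partnered, latents["partner_suspicious"], n)
    out["current_status"] = _value_pick(
        ever, latents["separated_divorced"], rng("items_separated_divorced"),
        ("separated", "divorced", "single"),
        ("married", "cohabiting", "regular_partner"), n,
    )
    told_mask = partnered & (has_ipv == 1)
    out["told_someone"] = _yes_no(told_mask, latents["told_someone"], n)
    return out


def generate_trial(config: SimConfig, items: bool = True) -> tuple[TrialRoster, TrialRoster]:
    """Generate (baseline, follow-up) rosters.

    Deterministic for a fixed seed.  ``items=False`` skips survey-item
    materialization (replicate simulation studies only need the latent
    truth columns, which the item-derived indicators reproduce exactly).
    """
    config.validate()
    theta, m0 = calibrate_norm_effect(config)
    _pairs, communities = _structure(config)
    u_pair, v_comm = _random_effects(config, communities)
    baseline = _generate_wave(config, "baseline", 0, communities, u_pair, v_comm,
                              theta, m0, items)
    followup = _generate_wave(config, "follow-up", 1, communities, u_pair, v_comm,
                              theta, m0, items)
    for roster in (baseline, followup):
        if roster.clamp_rate > config.clamp_warn_threshold:
            warnings.warn(
                f"{roster.wave} wave: outcome risk clamp rate "
                f"{roster.clamp_rate:.2%} exceeds threshold "
                f"{config.clamp_warn_threshold:.2%}",
                RuntimeWarning,
                stacklevel=2,
            )
    return baseline, followup
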