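import warnings

import numpy as np
import pandas as pd
import pytest

from crtmediate import (
    SimConfig,
    build_indicator_matrix,
    generate_trial,
    load_default_specs,
)


def small_config(**kw) -> SimConfig:
    """Reduced structure for replicate-heavy property checks."""
    base = dict(eas_per_community=4, baseline_eas_per_community=2)
    base.update(kw)
    return SimConfig(**base)


def quiet_generate(config, items=False):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return generate_trial(config, items=items)


@pytest.fixture(scope="session")
def specs():
    return load_default_specs()


@pytest.fixture(scope="session")
def trial():
    """One full-size trial with survey items (seed 11)."""
    return quiet_generate(SimConfig(seed=11), items=True)


@pytest.fixture(scope="session")
def followup_matrix(trial, specs):
    return build_indicator_matrix(specs, trial[1].data)


@pytest.fixture(scope="session")
def baseline_matrix(trial, specs):
    return build_indicator_matrix(specs, trial[0].data)


def tiny_roster(rows: list[dict]) -> pd.DataFrame:
    """Hand-built roster frame with design columns defaulted."""
    defaults = dict(
        pair_id="P1", community_id="C01", ea_id="C01-1-EA01", arm=0,
        sex="female", age=30, marital_status="married",
        education="secondary", childhood_abuse=0, partnered_past_year=1,
        cohabiting=1, witnessed_ipv=0, polygamous=0, ever_partnered_year=1,
    )
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["respondent_id"] = f"R{i + 1:03d}"
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)
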