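"""IRLS GLMs and the cluster sandwich: closed forms, algebra, library oracle."""

import numpy as np
import pandas as pd
import pytest

from crtmediate.regression_core import (
    CollinearityError,
    ConvergenceError,
    DesignSpec,
    cluster_robust_covariance,
    fit_glm,
    interaction_screen,
    risk_ratio_from_model,
)


def bernoulli_frame(rng, n=400, n_clusters=8):
    return pd.DataFrame({
        "y": rng.integers(0, 2, n).astype(float),
        "x1": rng.normal(size=n),
        "x2": rng.integers(0, 2, n).astype(float),
        "g": rng.integers(0, n_clusters, n),
    })


def test_intercept_only_log_link_recovers_prevalence():
    y = np.r_[np.ones(25), np.zeros(75)]
    df = pd.DataFrame({"y": y, "g": np.arange(100) % 5})
    m = fit_glm(df, DesignSpec("y", (), cluster="g"), link="log")
    assert np.exp(m.params["Intercept"]) == pytest.approx(0.25, abs=1e-10)


def test_intercept_only_logit_at_half_is_zero():
    df = pd.DataFrame({"y": np.r_[np.ones(50), np.zeros(50)],
                       "g": np.arange(100) % 4})
    m = fit_glm(df, DesignSpec("y", (), cluster="g"), link="logit")
    assert m.params["Intercept"] == pytest.approx(0.0, abs=1e-10)


def test_saturated_modified_poisson_equals_2x2_prevalence_ratio():
    # exposed: 30/80 events; unexposed: 10/120
    df = pd.DataFrame({
        "y": np.r_[np.ones(30), np.zeros(50), np.ones(10), np.zeros(110)],
        "x": np.r_[np.ones(80), np.zeros(120)],
        "g": np.arange(200) % 6,
    })
    m = fit_glm(df, DesignSpec("y", ("x",), cluster="g"), link="log")
    rr_table = (30 / 80) / (10 / 120)
    assert np.exp(m.params["x"]) == pytest.approx(rr_table, rel=1e-8)


def test_singleton_clusters_reduce_to_heteroskedastic_robust():
    rng = np.random.default_rng(5)
    df = bernoulli_frame(rng)
    df["g"] = np.arange(len(df))  # every observation its own cluster
    m = fit_glm(df, DesignSpec("y", ("x1", "x2"), cluster="g"), link="log")
    X, resid = m.X, m.y - m.mu
    w = np.clip(m.mu, 1e-10, None)
    bread = np.linalg.inv(X.T @ (X * w[:, None]))
    hc0 = bread @ (X * (resid**2)[:, None]).T.dot(X) @ bread
    np.testing.assert_allclose(m.cov_robust_uncorrected.to_numpy(), hc0,
                               atol=1e-12)


def test_within_cluster_duplication_leaves_robust_covariance_unchanged():
    rng = np.random.default_rng(6)
    df = bernoulli_frame(rng, n=300, n_clusters=6)
    doubled = pd.concat([df, df], ignore_index=True)
    m1 = fit_glm(df, DesignSpec("y", ("x1", "x2"), cluster="g"), link="log")
    m2 = fit_glm(doubled, DesignSpec("y", ("x1", "x2"), cluster="g"), link="log")
    np.testing.assert_allclose(m1.params, m2.params, atol=1e-8)
    np.testing.assert_allclose(m1.cov_robust, m2.cov_robust, atol=1e-8)


def test_bruteforce_score_accumulation_matches_matrix_form():
    rng = np.random.default_rng(7)
    df = bernoulli_frame(rng)
    m = fit_glm(df, DesignSpec("y", ("x1", "x2"), cluster="g"), link="log")
    X, resid, clusters = m.X, m.y - m.mu, m.clusters
    p = X.shape[1]
    meat = np.zeros((p, p))
    for g in np.unique(clusters):
        s = (X[clusters == g] * resid[clusters == g, None]).sum(axis=0)
        meat += np.outer(s, s)
    w = np.clip(m.mu, 1e-10, None)
    bread = np.linalg.inv(X.T @ (X * w[:, None]))
    brute = bread @ meat @ bread
    np.testing.assert_allclose(m.cov_robust_uncorrected.to_numpy(), brute,
                               atol=1e-10)


@pytest.mark.parametrize("link", ["log", "logit"])
def test_matches_statsmodels_oracle(link):
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(42)
    for _ in range(5):
        df = bernoulli_frame(rng, n=int(rng.integers(200, 500)),
                             n_clusters=int(rng.integers(4, 10)))
        m = fit_glm(df, DesignSpec("y", ("x1", "x2"), cluster="g"), link=link)
        X = np.column_stack([np.ones(len(df)), df.x1, df.x2])
        fam = sm.families.Poisson() if link == "log" else sm.families.Binomial()
        res = sm.GLM(df.y, X, family=fam).fit(
            cov_type="cluster",
            cov_kwds={"groups": df.g, "use_correction": False})
        np.testing.assert_allclose(m.params.to_numpy(), res.params, atol=1e-6)
        np.testing.assert_allclose(
            np.sqrt(np.diag(m.cov_robust_uncorrected)), res.bse,
            rtol=1e-4)


def test_robust_covariance_is_positive_semidefinite():
    rng = np.random.default_rng(8)
    for _ in range(10):
        df = bernoulli_frame(rng, n=250, n_clusters=5)
        m = fit_glm(df, DesignSpec("y", ("x1", "x2"), cluster="g"), link="log")
        eigvals = np.linalg.eigvalsh(m.cov_robust.to_numpy())
        assert eigvals.min() > -1e-12


def test_small_sample_factor_applied():
    rng = np.random.default_rng(9)
    df = bernoulli_frame(rng, n_clusters=8)
    m = fit_glm(df, DesignSpec("y", ("x1",), cluster="g"), link="log")
    G = m.n_clusters
    np.testing.assert_allclose(
        m.cov_robust.to_numpy(),
        m.cov_robust_uncorrected.to_numpy() * G / (G - 1))


def test_separation_raises_with_trace():
    df = pd.DataFrame({"y": np.r_[np.ones(50), np.zeros(50)],
                       "x": np.r_[np.ones(50), np.zeros(50)],
                       "g": np.arange(100) % 4})
    with pytest.raises(ConvergenceError) as err:
        fit_glm(df, DesignSpec("y", ("x",), cluster="g"), link="logit")
    assert len(err.value.trace) > 0


def test_constant_covariate_rejected():
    df = pd.DataFrame({"y": np.r_[np.ones(10), np.zeros(10)],
                       "x": np.ones(20), "g": np.arange(20) % 3})
    with pytest.raises(CollinearityError):
        fit_glm(df, DesignSpec("y", ("x",), cluster="g"), link="log")


def test_fewer_than_two_clusters_rejected():
    df = pd.DataFrame({"y": np.r_[np.ones(10), np.zeros(10)],
                       "x": np.random.default_rng(0).normal(size=20),
                       "g": np.zeros(20)})
    with pytest.raises(ValueError, match="2 clusters"):
        fit_glm(df, DesignSpec("y", ("x",), cluster="g"), link="log")


def test_no_events_rejected():
    df = pd.DataFrame({"y": np.zeros(30), "g": np.arange(30) % 3})
    with pytest.raises(ValueError, match="event"):
        fit_glm(df, DesignSpec("y", (), cluster="g"), link="log")


def test_risk_ratio_wald_interval():
    rng = np.random.default_rng(10)
    df = bernoulli_frame(rng)
    m = fit_glm(df, DesignSpec("y", ("x2",), cluster="g"), link="log")
    est = risk_ratio_from_model(m, "x2")
    beta = m.params["x2"]
    se = np.sqrt(m.cov_robust.loc["x2", "x2"])
    assert est.estimate == pytest.approx(np.exp(beta))
    assert est.ci_low == pytest.approx(np.exp(beta - 1.959963984540054 * se))
    assert est.ci_low < est.estimate < est.ci_high
    assert "x2" not in est.adjustment


def test_missing_term_is_an_error():
    df = pd.DataFrame({"y": np.r_[np.ones(10), np.zeros(10)],
                       "g": np.arange(20) % 3})
    m = fit_glm(df, DesignSpec("y", (), cluster="g"), link="log")
    with pytest.raises(KeyError):
        risk_ratio_from_model(m, "arm")


def test_interaction_untestable_when_factor_duplicates_arm():
    rng = np.random.default_rng(11)
    df = bernoulli_frame(rng)
    df["arm"] = df["x2"]
    res = interaction_screen(df, DesignSpec("y", ("arm", "x2"), cluster="g"),
                             "arm", "x2")
    assert not res.testable


def test_interaction_screen_detects_built_in_interaction():
    """Power check: a strong arm-specific risk-factor effect is found."""
    rng = np.random.default_rng(12)
    hits = 0
    reps = 40
    for _ in range(reps):
        n = 1500
        arm = rng.integers(0, 2, n).astype(float)
        x = rng.integers(0, 2, n).astype(float)
        g = rng.integers(0, 40, n)
        logp = np.log(0.12) + 0.1 * arm + 0.15 * x + 1.0 * arm * x
        y = (rng.random(n) < np.exp(logp)).astype(float)
        df = pd.DataFrame({"y": y, "arm": arm, "x": x, "g": g})
        try:
            res = interaction_screen(df, DesignSpec("y", ("arm", "x"),
                                                    cluster="g"), "arm", "x")
        except ConvergenceError:
            continue
        hits += bool(res.testable and res.significant)
    assert hits / reps > 0.8
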