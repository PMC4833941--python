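"""Individual-level generalized linear models for binary survey outcomes.

Two model families are used throughout the pipeline:

* **Logistic regression** (``link="logit"``) — used to compute expected event
  counts for the cluster-level intention-to-treat estimator.
* **Modified Poisson regression** (``link="log"``) — a log-link Poisson model
  applied to a 0/1 outcome.  The point estimates are consistent risk ratios;
  the model-based variance is wrong for binary data, which is why every
  reported interval uses the cluster-robust sandwich covariance.

Both fits are plain iteratively reweighted least squares (IRLS) on a dense
design matrix.  The sandwich covariance is ``A^{-1} B A^{-1}`` where ``A`` is
the Fisher information at convergence and ``B`` is the outer-product sum of
per-cluster score vectors (clusters are census enumeration areas in the main
analyses), with a ``G/(G-1)`` small-sample factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm as _normal

__all__ = [
    "DesignSpec",
    "FittedModel",
    "EffectEstimate",
    "InteractionResult",
    "ConvergenceError",
    "CollinearityError",
    "fit_glm",
    "cluster_robust_covariance",
    "risk_ratio_from_model",
    "interaction_screen",
    "categorize_age",
    "build_design_matrix",
]

_Z975 = float(_normal.ppf(0.975))


class ConvergenceError(RuntimeError):
    """IRLS failed to converge (often complete/quasi-separation)."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(f"{message} (step norms: {trace[-5:]})")
        self.trace = trace


class CollinearityError(ValueError):
    """Design matrix is rank deficient after filtering."""


@dataclass(frozen=True)
class DesignSpec:
    """Declarative description of one individual-level model.

    Parameters
    ----------
    outcome:
        Name of the 0/1 outcome column.
    terms:
        Covariate columns.  Object/categorical/string columns are expanded
        into indicator terms with the lowest-sorted level as reference; a
        term may be written ``"C(col)"`` to force categorical treatment of a
        numeric column.  Numeric/bool columns enter linearly.
    cluster:
        Column holding the cluster id for the robust covariance
        (enumeration area in the main analyses).  ``None`` -> each
        observation is its own cluster.
    subset:
        Optional pandas query string restricting the estimation sample
        (e.g. an eligibility predicate).
    """

    outcome: str
    terms: tuple[str, ...]
    cluster: str | None = None
    subset: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))


@dataclass
class FittedModel:
    link: str
    params: pd.Series
    cov_model: pd.DataFrame
    cov_robust: pd.DataFrame | None
    cov_robust_uncorrected: pd.DataFrame | None
    n: int
    n_clusters: int | None
    iterations: int
    converged: bool
    n_dropped: int
    n_fitted_gt1: int
    design: DesignSpec
    # internals kept for score-based diagnostics and expected-event sums
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    mu: np.ndarray = field(repr=False, default=None)
    clusters: np.ndarray = field(repr=False, default=None)
    row_index: pd.Index = field(repr=False, default=None)

    @property
    def term_names(self) -> list[str]:
        return list(self.params.index)


@dataclass
class EffectEstimate:
    """A risk ratio or mean difference with its 95% CI and provenance."""

    scale: str
    estimate: float
    ci_low: float
    ci_high: float
    se: float
    adjustment: str
    n: int
    n_clusters: int | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            lo, hi = sorted((self.ci_low, self.ci_high))
            self.ci_low, self.ci_high = lo, hi


@dataclass
class InteractionResult:
    testable: bool
    estimate: float | None
    p_value: float | None
    significant: bool | None
    reason: str = ""


def categorize_age(age: pd.Series, edges=(18, 30, 40, 50)) -> pd.Series:
    """Bin age in years into right-open decade-style categories.

    Default edges give 18-29 / 30-39 / 40-49, the survey's eligible range.
    """
    labels = [f"{lo}-{hi - 1}" for lo, hi in zip(edges[:-1], edges[1:])]
    return pd.cut(age, bins=list(edges), right=False, labels=labels).astype(object)


def _is_categorical(col: pd.Series) -> bool:
    return (
        isinstance(col.dtype, pd.CategoricalDtype)
        or col.dtype == object
        or pd.api.types.is_string_dtype(col)
    )


def build_design_matrix(
    data: pd.DataFrame, terms: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Expand model terms into a dense design matrix with intercept.

    Categorical columns are dummy-coded against the lowest-sorted level
    (the reference-level convention used throughout the package).
    """
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    for term in terms:
        force_cat = term.startswith("C(") and term.endswith(")")
        col_name = term[2:-1] if force_cat else term
        if col_name not in data.columns:
            raise KeyError(f"model term {col_name!r} not in data")
        col = data[col_name]
        if force_cat or _is_categorical(col):
            levels = sorted(pd.unique(col.dropna()), key=str)
            if len(levels) < 2:
                raise CollinearityError(
                    f"term {col_name!r} is constant after filtering"
                )
            for lev in levels[1:]:  # lowest level is the reference
                cols.append((col == lev).to_numpy(dtype=float))
                names.append(f"{col_name}[{lev}]")
        else:
            arr = col.to_numpy(dtype=float)
            if np.nanstd(arr) == 0:
                raise CollinearityError(
                    f"term {col_name!r} is constant after filtering"
                )
            cols.append(arr)
            names.append(col_name)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(
            "design matrix is rank deficient; check for aliased terms"
        )
    return X, names


def _complete_cases(data: pd.DataFrame, design: DesignSpec) -> tuple[pd.DataFrame, int]:
    df = data.query(design.subset) if design.subset else data
    used = [design.outcome]
    for term in design.terms:
        used.append(term[2:-1] if term.startswith("C(") else term)
    if design.cluster:
        used.append(design.cluster)
    before = len(df)
    df = df.dropna(subset=[c for c in dict.fromkeys(used)])
    return df, before - len(df)


def _irls(X: np.ndarray, y: np.ndarray, link: str, max_iter=100, tol=1e-8):
    n, p = X.shape
    beta = np.zeros(p)
    ybar = float(np.clip(y.mean(), 1e-10, 1 - 1e-10))
    beta[0] = np.log(ybar / (1 - ybar)) if link == "logit" else np.log(ybar)
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        if link == "logit":
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
        elif link == "log":
            mu = np.exp(eta)
            w = np.clip(mu, 1e-10, None)
        else:  # pragma: no cover - guarded by fit_glm
            raise ValueError(f"unknown link {link!r}")
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError(f"singular weighted design at iteration {it}") from exc
        step = float(np.linalg.norm(beta_new - beta) / max(1.0, np.linalg.norm(beta_new)))
        trace.append(step)
        beta = beta_new
        if step < tol:
            break
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations "
            "(possible separation)", trace
        )
    if np.abs(beta).max() > 30:
        raise ConvergenceError("diverging coefficients (possible separation)", trace)
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = expit(eta) if link == "logit" else np.exp(eta)
    w = mu * (1.0 - mu) if link == "logit" else mu
    info = X.T @ (X * np.clip(w, 1e-10, None)[:, None])
    return beta, mu, info, it, trace


def fit_glm(data: pd.DataFrame, design: DesignSpec, link: str) -> FittedModel:
    """Fit a logistic or modified-Poisson model by IRLS.

    Raises
    ------
    ValueError
        If the outcome has no events or no non-events after filtering.
    ConvergenceError
        On non-convergence (the iteration trace is attached).
    """
    if link not in ("logit", "log"):
        raise ValueError("link must be 'logit' or 'log'")
    df, n_dropped = _complete_cases(data, design)
    y = df[design.outcome].to_numpy(dtype=float)
    if len(y) == 0 or y.min() == y.max():
        raise ValueError(
            f"outcome {design.outcome!r} needs at least one event and one "
            "non-event after filtering"
        )
    X, names = build_design_matrix(df, design.terms)
    beta, mu, info, iterations, _trace = _irls(X, y, link)
    cov_model = np.linalg.inv(info)
    params = pd.Series(beta, index=names)
    model = FittedModel(
        link=link,
        params=params,
        cov_model=pd.DataFrame(cov_model, index=names, columns=names),
        cov_robust=None,
        cov_robust_uncorrected=None,
        n=len(df),
        n_clusters=None,
        iterations=iterations,
        converged=True,
        n_dropped=n_dropped,
        n_fitted_gt1=int((mu > 1).sum()) if link == "log" else 0,
        design=design,
        X=X,
        y=y,
        mu=mu,
        clusters=None,
        row_index=df.index,
    )
    clusters = (
        df[design.cluster].to_numpy()
        if design.cluster is not None
        else np.arange(len(df))
    )
    model.clusters = clusters
    corrected, uncorrected, n_clusters = cluster_robust_covariance(model, clusters)
    model.cov_robust = pd.DataFrame(corrected, index=names, columns=names)
    model.cov_robust_uncorrected = pd.DataFrame(
        uncorrected, index=names, columns=names
    )
    model.n_clusters = n_clusters
    return model


def cluster_robust_covariance(
    model: FittedModel, clusters: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Sandwich covariance with per-cluster score accumulation.

    Returns ``(corrected, uncorrected, n_clusters)`` where *corrected*
    carries the ``G/(G-1)`` small-sample factor.  For canonical links
    (logit-binomial, log-Poisson) the per-observation score is
    ``x_i (y_i - mu_i)``.
    """
    codes, uniques = pd.factorize(clusters)
    G = len(uniques)
    if G < 2:
        raise ValueError("cluster-robust covariance requires at least 2 clusters")
    X, resid = model.X, model.y - model.mu
    p = X.shape[1]
    scores = np.zeros((G, p))
    np.add.at(scores, codes, X * resid[:, None])
    bread = np.linalg.inv(X.T @ (X * _irls_weights(model)[:, None]))
    meat = scores.T @ scores
    uncorrected = bread @ meat @ bread
    corrected = uncorrected * (G / (G - 1))
    return corrected, uncorrected, G


def _irls_weights(model: FittedModel) -> np.ndarray:
    mu = model.mu
    w = mu * (1.0 - mu) if model.link == "logit" else mu
    return np.clip(w, 1e-10, None)


def risk_ratio_from_model(
    model: FittedModel, term: str, robust: bool = True
) -> EffectEstimate:
    """Exponentiate a coefficient into a risk ratio with a Wald 95% CI."""
    if term not in model.params.index:
        raise KeyError(f"term {term!r} not in model ({list(model.params.index)})")
    beta = float(model.params[term])
    cov = model.cov_robust if robust else model.cov_model
    se = float(np.sqrt(cov.loc[term, term]))
    flags = ("degenerate-ci",) if se == 0 else ()
    covars = [t for t in model.term_names if t != "Intercept" and t != term]
    return EffectEstimate(
        scale="risk ratio",
        estimate=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z975 * se)),
        ci_high=float(np.exp(beta + _Z975 * se)),
        se=se,
        adjustment="adjusted for " + ", ".join(covars) if covars else "unadjusted",
        n=model.n,
        n_clusters=model.n_clusters,
        flags=flags,
    )


def interaction_screen(
    data: pd.DataFrame,
    design: DesignSpec,
    arm_term: str,
    factor_term: str,
    link: str = "log",
    alpha: float = 0.05,
) -> InteractionResult:
    """Wald test (robust covariance) of an arm-by-risk-factor product term.

    Both terms must be numeric/binary columns already present in the design.
    Reports *untestable* when the product is collinear with the main-effect
    design (e.g. the risk factor duplicates the arm indicator).
    """
    df, _ = _complete_cases(data, design)
    try:
        X, _names = build_design_matrix(df, design.terms)
    except CollinearityError as exc:
        return InteractionResult(
            testable=False, estimate=None, p_value=None, significant=None,
            reason=f"main-effect design not identifiable ({exc})",
        )
    product = (df[arm_term].to_numpy(float) * df[factor_term].to_numpy(float))
    # collinearity check: residual of the product after projection on X
    coef, *_ = np.linalg.lstsq(X, product, rcond=None)
    resid = product - X @ coef
    denom = max(float(np.linalg.norm(product)), 1.0)
    if float(np.linalg.norm(resid)) / denom < 1e-8:
        return InteractionResult(
            testable=False, estimate=None, p_value=None, significant=None,
            reason="product term collinear with main effects",
        )
    pname = f"{arm_term}:{factor_term}"
    aug = df.copy()
    aug[pname] = product
    aug_design = DesignSpec(
        outcome=design.outcome,
        terms=tuple(design.terms) + (pname,),
        cluster=design.cluster,
        subset=None,  # subset already applied
    )
    model = fit_glm(aug, aug_design, link)
    beta = float(model.params[pname])
    se = float(np.sqrt(model.cov_robust.loc[pname, pname]))
    if se == 0:
        return InteractionResult(False, beta, None, None, "zero robust variance")
    z = beta / se
    p = float(2 * _normal.sf(abs(z)))
    return InteractionResult(True, beta, p, p < alpha)
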