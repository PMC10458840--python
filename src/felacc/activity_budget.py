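"""Daily activity budgets and Dirichlet regression on compositions.

An *activity budget* is the composition of a cat's day over behaviour
classes: the proportion of predicted 1 s epochs spent in each class,
summing to one. Budgets from different models (mount x technique) and
days are compared with a Dirichlet regression in the common
parametrisation with log link: for observation with covariate row x,
the composition y ~ Dirichlet(alpha(x)) with

    alpha_k(x) = exp(x' beta_k),   k = 1 .. K,

so each class has its own coefficient vector on the log-concentration
scale. The log-likelihood

    sum_obs [ logGamma(sum_k alpha_k) - sum_k logGamma(alpha_k)
              + sum_k (alpha_k - 1) log y_k ]

is maximised by quasi-Newton (BFGS with the analytic gradient) from a
method-of-moments start; standard errors come from the inverse observed
information at the optimum and Wald z = beta / se gives two-sided
p-values per coefficient.

The Dirichlet density is undefined on the boundary, while classifiers
routinely predict a behaviour zero times in a day, so observed
compositions are first pulled strictly inside the simplex with the
standard adjustment y* = (y (n - 1) + 1/K) / n for n observed epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1


from .synthetic_data import StudyBundle


@dataclass(frozen=True)
class ActivityBudget:
    """One cat-day composition over a model's class set."""

    cat_id: str
    day: int
    technique: str
    mount: str
    round_index: int
    classes: tuple[str, ...]
    proportions: np.ndarray
    n_epochs: int

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (len(self.classes),):
            raise ValueError("one proportion per class required")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be nonnegative and sum to 1")
        object.__setattr__(self, "proportions", p)


def predict_budgets(
    model,
    study: StudyBundle,
    days: Iterable[int],
    round_index: int = 0,
) -> list[ActivityBudget]:
    """Apply a trained model to whole days of trace and tally budgets.

    For every cat and requested day the day's trace (for the model's
    mount) is synthesized, features are extracted, every epoch is
    classified, and class frequencies are normalised into a composition
    over ``model.classes``.
    """
    from .features import extract_features

    days = sorted(set(days))
    if not days:
        raise ValueError("at least one day must be requested")
    classes = tuple(model.classes)
    index = {c: i for i, c in enumerate(classes)}
    out = []
    for cat in study:
        for day in days:
            trace = cat.day_trace(model.mount, day)
            feats = extract_features(trace.samples, trace.sampling_rate)
            if feats.empty:
                raise ValueError(f"day {day} has no complete epochs")
            labels = model.predict(feats)
            counts = np.zeros(len(classes))
            for lab in labels:
                counts[index[lab]] += 1
            out.append(ActivityBudget(
                cat.cat_id, day, model.technique, model.mount, round_index,
                classes, counts / counts.sum(), int(len(labels))))
    return out


def budgets_frame(budgets: Sequence[ActivityBudget]) -> pd.DataFrame:
    """Long-format budget table (cat, day, model, class, proportion)."""
    rows = []
    for b in budgets:
        for cls, p in zip(b.classes, b.proportions):
            rows.append({
                "cat_id": b.cat_id, "day": b.day, "technique": b.technique,
                "mount": b.mount, "round": b.round_index,
                "behaviour": cls, "proportion": p, "n_epochs": b.n_epochs,
            })
    return pd.DataFrame(rows)


def zero_adjust(proportions: np.ndarray, n_obs: int) -> np.ndarray:
    """Pull a composition strictly inside the simplex.

    ``y* = (y (n_obs - 1) + 1/K) / n_obs`` — the usual compositional
    adjustment for boundary zeros; y* stays in (0, 1) and sums to 1.
    """
    y = np.asarray(proportions, dtype=float)
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    if abs(y.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    k = y.size
    return (y * (n_obs - 1) + 1.0 / k) / n_obs


def dirichlet_loglik(Y: np.ndarray, alpha: np.ndarray) -> float:
    """Dirichlet log-likelihood of interior compositions ``Y`` (rows)
    under per-observation concentration rows ``alpha``."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    if Y.shape != alpha.shape:
        raise ValueError("Y and alpha must have matching shapes")
    if (Y <= 0).any() or (Y >= 1).any():
        raise ValueError("compositions must be strictly interior; "
                         "zero-adjust first")
    if (alpha <= 0).any():
        raise ValueError("concentrations must be positive")
    return float(
        (special.gammaln(alpha.sum(axis=1))
         - special.gammaln(alpha).sum(axis=1)
         + ((alpha - 1.0) * np.log(Y)).sum(axis=1)).sum())


@dataclass
class DirichletFit:
    """Fitted common-parametrisation Dirichlet regression."""

    classes: tuple[str, ...]
    covariates: tuple[str, ...]
    beta: np.ndarray  # (K, P) log-scale coefficients
    se: np.ndarray  # (K, P)
    loglik: float
    converged: bool
    cov: np.ndarray = field(repr=False, default=None)  # (K*P, K*P)
    n_obs: int = 0

    def coef_frame(self) -> pd.DataFrame:
        rows = []
        for k, cls in enumerate(self.classes):
            for p_, cov in enumerate(self.covariates):
                b, s = self.beta[k, p_], self.se[k, p_]
                z = b / s if s > 0 else np.nan
                rows.append({
                    "behaviour": cls, "covariate": cov, "beta": b, "se": s,
                    "z": z, "p": 2 * stats.norm.sf(abs(z)) if s > 0 else np.nan,
                })
        return pd.DataFrame(rows)

    def alpha(self, X: np.ndarray) -> np.ndarray:
        return np.exp(np.asarray(X, dtype=float) @ self.beta.T)


def design_matrix(
    budgets: pd.DataFrame,
    covariates: Sequence[str] = ("mount", "technique", "day"),
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Treatment-coded design matrix with intercept from budget metadata.

    ``mount`` and ``technique`` enter as single dummies; ``day`` is
    categorical with the first day as reference.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(budgets))}
    for cov in covariates:
        values = budgets[cov].to_numpy()
        levels = sorted(pd.unique(values).tolist())
        for level in levels[1:]:
            cols[f"{cov}[{level}]"] = (values == level).astype(float)
    names = tuple(cols)
    return np.column_stack([cols[n] for n in names]), names


def _loglik_and_grad(theta: np.ndarray, X: np.ndarray, logY: np.ndarray,
                     K: int, P: int) -> tuple[float, np.ndarray]:
    beta = theta.reshape(K, P)
    eta = X @ beta.T  # (n, K)
    eta = np.clip(eta, -30.0, 30.0)
    alpha = np.exp(eta)
    a0 = alpha.sum(axis=1)
    ll = (special.gammaln(a0) - special.gammaln(alpha).sum(axis=1)
          + ((alpha - 1.0) * logY).sum(axis=1)).sum()
    # d ll / d alpha_k = psi(a0) - psi(alpha_k) + log y_k; chain through
    # alpha = exp(eta)
    dalpha = (special.digamma(a0)[:, None] - special.digamma(alpha) + logY)
    deta = dalpha * alpha  # (n, K)
    grad = deta.T @ X  # (K, P)
    return float(ll), grad.ravel()


def _moment_start(Y: np.ndarray, K: int, P: int) -> np.ndarray:
    """Method-of-moments intercepts for a common-alpha Dirichlet."""
    m = Y.mean(axis=0)
    v = Y.var(axis=0, ddof=1) if Y.shape[0] > 1 else np.full(K, 1e-2)
    v = np.clip(v, 1e-6, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.median(m * (1.0 - m) / v - 1.0)
    s = float(np.clip(s, 1.0, 1e4))
    beta = np.zeros((K, P))
    beta[:, 0] = np.log(np.clip(m * s, 1e-6, None))
    return beta.ravel()


def fit_dirichlet_regression(
    budgets: pd.DataFrame,
    covariates: Sequence[str] = ("mount", "technique", "day"),
    class_order: Optional[Sequence[str]] = None,
) -> DirichletFit:
    """Maximum-likelihood Dirichlet regression on long-format budgets.

    ``budgets`` is the output of :func:`budgets_frame` (or any frame
    with ``cat_id, day, technique, mount, behaviour, proportion,
    n_epochs``). Observations are cat-day-model compositions; the
    requested covariates enter the design with treatment coding.
    Compositions are zero-adjusted before fitting. Non-convergence is
    flagged on the result, not raised.
    """
    wide = budgets.pivot_table(
        index=["cat_id", "day", "technique", "mount"],
        columns="behaviour", values="proportion", fill_value=0.0,
    )
    if class_order is None:
        class_order = tuple(wide.columns)
    wide = wide[list(class_order)]
    meta = wide.index.to_frame(index=False)
    n_epochs = (budgets.groupby(["cat_id", "day", "technique", "mount"])
                ["n_epochs"].first().reindex(wide.index).to_numpy())
    Y = wide.to_numpy(dtype=float)
    Y = np.vstack([
        zero_adjust(Y[i] / Y[i].sum(), int(n_epochs[i]))
        for i in range(Y.shape[0])
    ])
    if Y.shape[0] < 2:
        raise ValueError("need at least two observations")
    X, names = design_matrix(meta, [c for c in covariates
                                    if meta[c].nunique() > 1])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    K, P = Y.shape[1], X.shape[1]
    logY = np.log(Y)

    theta0 = _moment_start(Y, K, P)

    def neg(theta):
        ll, grad = _loglik_and_grad(theta, X, logY, K, P)
        return -ll, -grad

    res = optimize.minimize(neg, theta0, jac=True, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-7})
    beta = res.x.reshape(K, P)
    hess = approx_hess1(res.x, lambda th: -_loglik_and_grad(th, X, logY, K, P)[0])
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None)).reshape(K, P)
    except np.linalg.LinAlgError:
        cov = np.full((K * P, K * P), np.nan)
        se = np.full((K, P), np.nan)
    ll_opt, _ = _loglik_and_grad(res.x, X, logY, K, P)
    return DirichletFit(tuple(class_order), names, beta, se, ll_opt,
                        bool(res.success), cov, Y.shape[0])


def compare_budgets(fit: DirichletFit, contrast: str) -> pd.DataFrame:
    """Wald test of one covariate's effect per behaviour class.

    ``contrast`` names a fitted covariate column (e.g. ``"mount[harness]"``
    or ``"technique[SOM]"``). Returns one row per class with the log-scale
    effect, its standard error, z and two-sided p. A contrast of a level
    with itself (effect identically absent from the design) is reported
    as a zero effect with p = 1.
    """
    if contrast in ("none", "self"):
        return pd.DataFrame([
            {"behaviour": c, "effect": 0.0, "se": 0.0, "z": 0.0, "p": 1.0}
            for c in fit.classes
        ])
    if contrast not in fit.covariates:
        raise KeyError(
            f"unknown contrast {contrast!r}; fitted covariates: "
            f"{list(fit.covariates)}")
    j = fit.covariates.index(contrast)
    rows = []
    for k, cls in enumerate(fit.classes):
        b, s = fit.beta[k, j], fit.se[k, j]
        z = b / s if s > 0 else np.nan
        rows.append({
            "behaviour": cls, "effect": b, "se": s, "z": z,
            "p": 2 * stats.norm.sf(abs(z)) if s > 0 else np.nan,
        })
    return pd.DataFrame(rows)
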