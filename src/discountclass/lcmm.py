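"""Latent-class linear mixed models for indifference-point trajectories.

The model is a finite mixture of linear mixed-effects regressions.  With
y_ij the normalized indifference point (v/A) of subject i at normalized
time t_j (delay in months / 120), each latent class g has its own line:

    y_ij | class g  =  beta0_g + beta1_g * t_j + b_i + e_ij,

with a shared random intercept b_i ~ N(0, sigma_b^2) (optional) and shared
residual e_ij ~ N(0, sigma^2).  Marginally within a class the subject
vector y_i is multivariate normal with mean X beta_g and covariance
Sigma = sigma_b^2 J + sigma^2 I, and the mixture likelihood is

    log L = sum_i log sum_g pi_g * MVN(y_i; X beta_g, Sigma).

Estimation is by EM treating both the class label and the random intercept
as missing data; every M-step is closed-form and the observed-data
log-likelihood is non-decreasing across iterations.  Class counts are
compared with AIC, BIC, and the sample-size-adjusted BIC (SABIC), which
replaces BIC's ln(N) penalty with ln((N+2)/24); the class count with the
lowest SABIC is selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .core import Cohort

__all__ = [
    "LcmmModel",
    "LcmmParams",
    "LcmmFit",
    "n_params",
    "marginal_loglik",
    "em_fit",
    "fit_classes",
    "information_criteria",
    "posterior_classify",
    "fixed_effects_in_currency_units",
]

_VAR_FLOOR = 1e-8      # residual-variance floor
_WEIGHT_EPS = 1e-10    # class-weight floor inside logs
_DEGENERATE_FRAC = 1e-6  # class with total responsibility below this*N is degenerate


@dataclass(frozen=True)
class LcmmModel:
    """Specification of a G-class latent-class linear mixed model.

    Outcomes are normalized to y = v/A and delays to t = d/time_scale
    before fitting, so coefficients are comparable across task magnitudes.
    """

    n_classes: int
    random_intercept: bool = True
    time_scale: float = 120.0
    max_iter: int = 500
    tol_loglik: float = 1e-8
    tol_params: float = 1e-6
    n_starts: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.tol_loglik <= 0 or self.tol_params <= 0:
            raise ValueError("tolerances must be > 0")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class LcmmParams:
    """A point in parameter space: weights, per-class lines, variances."""

    weights: np.ndarray        # (G,) mixing proportions, sum 1
    beta: np.ndarray           # (G, 2) intercept and slope on t per class
    var_b: float               # random-intercept variance (0 if absent)
    var_e: float               # residual variance

    @property
    def logits(self) -> np.ndarray:
        """Multinomial logits zeta_g = log(pi_g / pi_G), zeta_G = 0."""
        w = np.maximum(self.weights, _WEIGHT_EPS)
        return np.log(w) - np.log(w[-1])

    def copy(self) -> "LcmmParams":
        return LcmmParams(self.weights.copy(), self.beta.copy(),
                          float(self.var_b), float(self.var_e))


@dataclass
class LcmmFit:
    """Fitted state: parameters, likelihood, posteriors, class assignments."""

    model: LcmmModel
    params: LcmmParams
    loglik: float
    n_params: int
    posteriors: np.ndarray         # (N, G), rows sum to 1
    assigned_class: np.ndarray     # (N,) 1-based argmax labels
    participant_ids: list[str]
    converged: bool
    n_iter: int
    loglik_history: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def class_weights(self) -> np.ndarray:
        return self.params.weights

    @property
    def fixed_effects(self) -> np.ndarray:
        return self.params.beta

    @property
    def class_percentages(self) -> np.ndarray:
        """Share of participants assigned to each class, in percent."""
        G = self.model.n_classes
        counts = np.bincount(self.assigned_class - 1, minlength=G)
        return 100.0 * counts / len(self.assigned_class)


def n_params(G: int, random_intercept: bool = True) -> int:
    """Free parameters: (G-1) logits + 2G fixed effects + sigma^2 [+ sigma_b^2]."""
    return (G - 1) + 2 * G + 1 + int(bool(random_intercept))


def _design(cohort: Cohort, model: LcmmModel) -> tuple[np.ndarray, np.ndarray]:
    """Return (Y, X): normalized outcomes (N, m) and design (m, 2)."""
    Y = cohort.values_matrix() / cohort.task.magnitude
    if np.isnan(Y).any():
        raise ValueError("cohort has missing values; fit requires complete series")
    t = np.asarray(cohort.task.delays) / model.time_scale
    X = np.column_stack([np.ones_like(t), t])
    return Y, X


def _class_logdens(Y: np.ndarray, X: np.ndarray, params: LcmmParams) -> np.ndarray:
    """(N, G) log MVN densities with structured covariance sb^2 J + s2 I.

    Uses the closed-form inverse of the compound-symmetric covariance:
    Sigma^{-1} = (I - c J)/s2 with c = sb^2/(s2 + m sb^2), and
    log|Sigma| = (m-1) log s2 + log(s2 + m sb^2).
    """
    N, m = Y.shape
    s2, sb2 = params.var_e, params.var_b
    denom = s2 + m * sb2
    c = sb2 / denom
    logdet = (m - 1) * math.log(s2) + math.log(denom)
    out = np.empty((N, params.beta.shape[0]))
    for g, bg in enumerate(params.beta):
        R = Y - X @ bg                      # (N, m) residuals
        rs = R.sum(axis=1)
        quad = ((R * R).sum(axis=1) - c * rs * rs) / s2
        out[:, g] = -0.5 * (m * math.log(2 * math.pi) + logdet + quad)
    return out


def marginal_loglik(params: LcmmParams, cohort: Cohort, model: LcmmModel) -> float:
    """Observed-data log-likelihood sum_i log sum_g pi_g phi_g(y_i)."""
    Y, X = _design(cohort, model)
    logphi = _class_logdens(Y, X, params)
    logpi = np.log(np.maximum(params.weights, _WEIGHT_EPS))
    return float(logsumexp(logphi + logpi, axis=1).sum())


def _subject_ols(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-subject OLS (intercept, slope): basis for initialization."""
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return coef.T  # (N, 2)


def _kmeans_start(Y: np.ndarray, X: np.ndarray, G: int, random_intercept: bool,
                  seed: int) -> LcmmParams:
    coefs = _subject_ols(Y, X)
    N, m = Y.shape
    if G == 1:
        labels = np.zeros(N, dtype=int)
    else:
        km = KMeans(n_clusters=G, n_init=10, random_state=seed % 2**31)
        labels = km.fit_predict(coefs)
    beta = np.empty((G, 2))
    weights = np.empty(G)
    for g in range(G):
        mask = labels == g
        weights[g] = max(mask.mean(), 1.0 / N)
        beta[g] = coefs[mask].mean(axis=0) if mask.any() else coefs.mean(axis=0)
    weights /= weights.sum()
    R = np.stack([Y - X @ beta[g] for g in range(G)])  # (G, N, m)
    resid = R[labels, np.arange(N), :]
    if random_intercept:
        row_means = resid.mean(axis=1)
        var_b = max(float(row_means.var()), _VAR_FLOOR)
        var_e = max(float((resid - row_means[:, None]).var()), _VAR_FLOOR)
    else:
        var_b, var_e = 0.0, max(float(resid.var()), _VAR_FLOOR)
    return LcmmParams(weights, beta, var_b, var_e)


def _perturbed_start(base: LcmmParams, rng: np.random.Generator) -> LcmmParams:
    G = base.beta.shape[0]
    spread = max(base.beta.std(), 0.1)
    beta = base.beta + rng.normal(0.0, 0.3 * spread, size=base.beta.shape)
    weights = rng.dirichlet(np.full(G, 5.0))
    return LcmmParams(weights, beta,
                      base.var_b * float(rng.uniform(0.5, 2.0)),
                      base.var_e * float(rng.uniform(0.5, 2.0)))


def _canonicalize(params: LcmmParams, tau: np.ndarray) -> tuple[LcmmParams, np.ndarray]:
    """Order classes by slope (ascending), ties by intercept: fixes label switching."""
    order = np.lexsort((params.beta[:, 0], params.beta[:, 1]))
    return (
        LcmmParams(params.weights[order], params.beta[order],
                   params.var_b, params.var_e),
        tau[:, order],
    )


def em_fit(cohort: Cohort, model: LcmmModel,
           start: LcmmParams | None = None) -> LcmmFit:
    """Fit by EM from a single start (k-means-based if ``start`` is None).

    The E-step computes class responsibilities tau_ig and, when a random
    intercept is present, the conditional mean/variance of b_i given class
    g.  M-steps: pi_g = mean tau_ig; beta_g by tau-weighted least squares
    on intercept-adjusted outcomes; variances from tau-weighted second
    moments.  Stops when the relative log-likelihood change and the
    largest parameter change both fall below tolerance.
    """
    Y, X = _design(cohort, model)
    N, m = Y.shape
    G = model.n_classes
    if start is None:
        start = _kmeans_start(Y, X, G, model.random_intercept, model.seed)
    params = start.copy()
    if not model.random_intercept:
        params.var_b = 0.0

    XtX_inv = np.linalg.inv(X.T @ X)
    history: list[float] = []
    converged = False
    degenerate = False
    tau = np.full((N, G), 1.0 / G)

    for it in range(1, model.max_iter + 1):
        # ---- E-step ----
        logphi = _class_logdens(Y, X, params)
        logw = logphi + np.log(np.maximum(params.weights, _WEIGHT_EPS))
        li = logsumexp(logw, axis=1)
        loglik = float(li.sum())
        tau = np.exp(logw - li[:, None])
        history.append(loglik)

        class_mass = tau.sum(axis=0)
        if (class_mass < _DEGENERATE_FRAC * N).any():
            degenerate = True

        s2, sb2 = params.var_e, params.var_b
        shrink = sb2 / (s2 + m * sb2)          # b | y, g mean factor
        v_b = sb2 * s2 / (s2 + m * sb2) if model.random_intercept else 0.0

        # ---- M-step ----
        new = params.copy()
        new.weights = np.maximum(class_mass / N, _WEIGHT_EPS)
        new.weights /= new.weights.sum()

        mu = np.zeros((N, G))
        ss_e = 0.0
        ss_b = 0.0
        for g in range(G):
            R = Y - X @ params.beta[g]
            mu_g = shrink * R.sum(axis=1)      # E[b_i | y_i, class g]
            mu[:, g] = mu_g
            w = tau[:, g]
            adj = Y - mu_g[:, None]            # remove expected intercept
            wy = (w[:, None] * adj).sum(axis=0) / max(w.sum(), _WEIGHT_EPS)
            new.beta[g] = XtX_inv @ (X.T @ wy)
            R_new = adj - X @ new.beta[g]
            ss_e += float((w[:, None] * R_new * R_new).sum()) + w.sum() * m * v_b
            ss_b += float((w * (mu_g * mu_g + v_b)).sum())
        new.var_e = max(ss_e / (N * m), _VAR_FLOOR)
        if model.random_intercept:
            new.var_b = max(ss_b / N, 0.0)

        dparam = max(
            np.abs(new.beta - params.beta).max(),
            np.abs(new.weights - params.weights).max(),
            abs(new.var_e - params.var_e),
            abs(new.var_b - params.var_b),
        )
        rel_dll = (
            abs(history[-1] - history[-2]) / (abs(history[-2]) + 1.0)
            if len(history) > 1 else np.inf
        )
        params = new
        if rel_dll < model.tol_loglik and dparam < model.tol_params:
            converged = True
            break

    # final E-step at the converged parameters
    logphi = _class_logdens(Y, X, params)
    logw = logphi + np.log(np.maximum(params.weights, _WEIGHT_EPS))
    li = logsumexp(logw, axis=1)
    loglik = float(li.sum())
    history.append(loglik)
    tau = np.exp(logw - li[:, None])

    params, tau = _canonicalize(params, tau)
    assigned = tau.argmax(axis=1) + 1  # ties break toward the lower label
    diagnostics = {}
    if degenerate:
        converged = False
        diagnostics["degenerate_class"] = True
    return LcmmFit(
        model=model, params=params, loglik=loglik,
        n_params=n_params(G, model.random_intercept),
        posteriors=tau, assigned_class=assigned,
        participant_ids=cohort.participant_ids,
        converged=converged, n_iter=len(history) - 1,
        loglik_history=np.asarray(history), diagnostics=diagnostics,
    )


def information_criteria(loglik: float, p: int, n_subjects: int) -> tuple[float, float, float]:
    """(AIC, BIC, SABIC); N counts subjects, the independent sampling units.

    AIC = -2logL + 2p; BIC = -2logL + p ln N;
    SABIC = -2logL + p ln((N+2)/24)  (Sclove's sample-size adjustment).
    """
    if p < 1 or n_subjects < 1:
        raise ValueError("p and n_subjects must be >= 1")
    neg2 = -2.0 * loglik
    return (
        neg2 + 2.0 * p,
        neg2 + p * math.log(n_subjects),
        neg2 + p * math.log((n_subjects + 2) / 24.0),
    )


def fit_with_restarts(cohort: Cohort, model: LcmmModel) -> LcmmFit:
    """Best-of-``n_starts`` EM fit: one k-means start plus random perturbations."""
    Y, X = _design(cohort, model)
    base = _kmeans_start(Y, X, model.n_classes, model.random_intercept, model.seed)
    best: LcmmFit | None = None
    ss = np.random.SeedSequence([model.seed % 2**31, model.n_classes])
    rngs = [np.random.default_rng(s) for s in ss.spawn(model.n_starts)]
    for s_idx in range(model.n_starts):
        start = base if s_idx == 0 else _perturbed_start(base, rngs[s_idx])
        fit = em_fit(cohort, model, start=start)
        better = best is None or fit.loglik > best.loglik
        prefer_converged = (
            best is not None and fit.converged and not best.converged
            and fit.loglik >= best.loglik - 1e-6
        )
        if better or prefer_converged:
            best = fit
    assert best is not None
    best.diagnostics["n_starts"] = model.n_starts
    return best


def fit_classes(
    cohort: Cohort,
    model_template: LcmmModel,
    g_range: Sequence[int] = range(1, 9),
) -> tuple[list[LcmmFit], pd.DataFrame]:
    """Sweep class counts; return fits and a criteria table.

    For each G the best of ``n_starts`` EM runs is kept.  The table has one
    row per G with loglik, parameter count, AIC/BIC/SABIC, convergence,
    and class percentages under the canonical (slope-ascending) labels.
    """
    g_range = list(g_range)
    if not g_range:
        raise ValueError("g_range must be non-empty")
    N = len(cohort)
    fits, rows = [], []
    g_max = max(g_range)
    for G in g_range:
        fit = fit_with_restarts(cohort, replace(model_template, n_classes=G))
        fits.append(fit)
        aic, bic, sabic = information_criteria(fit.loglik, fit.n_params, N)
        row = {
            "n_classes": G, "loglik": fit.loglik, "n_params": fit.n_params,
            "AIC": aic, "BIC": bic, "SABIC": sabic, "converged": fit.converged,
        }
        pct = fit.class_percentages
        for g in range(g_max):
            row[f"class_{g + 1}_pct"] = pct[g] if g < G else np.nan
        rows.append(row)
    return fits, pd.DataFrame(rows)


def select_by_sabic(table: pd.DataFrame) -> int:
    """Class count with the lowest SABIC, preferring converged fits."""
    t = table[table["converged"]] if table["converged"].any() else table
    return int(t.loc[t["SABIC"].idxmin(), "n_classes"])


def posterior_classify(fit: LcmmFit) -> pd.DataFrame:
    """Per-participant assigned class and maximum posterior probability.

    The mean maximum posterior (a class-separation diagnostic) is stored
    in ``result.attrs["mean_max_posterior"]``.
    """
    max_post = fit.posteriors.max(axis=1)
    out = pd.DataFrame({
        "participant_id": fit.participant_ids,
        "assigned_class": fit.assigned_class,
        "max_posterior": max_post,
    })
    for g in range(fit.model.n_classes):
        out[f"posterior_{g + 1}"] = fit.posteriors[:, g]
    out.attrs["mean_max_posterior"] = float(max_post.mean())
    return out


def fixed_effects_in_currency_units(fit: LcmmFit, cohort: Cohort) -> pd.DataFrame:
    """Per-class intercept (currency) and slope (currency per month)."""
    A = cohort.task.magnitude
    beta = fit.params.beta
    return pd.DataFrame({
        "class": np.arange(1, len(beta) + 1),
        "intercept_currency": A * beta[:, 0],
        "slope_currency_per_month": A * beta[:, 1] / fit.model.time_scale,
        "weight": fit.params.weights,
    })
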