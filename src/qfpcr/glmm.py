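"""Binomial random-intercept logistic mixed model (Laplace fit).

The dosage classifier rests on a multilevel logistic regression: the
binary response (trisomic vs normal diallelic genotype) is modeled with
``height_ratio`` and ``size_difference`` as fixed effects and the STR
marker as a random intercept,

    logit P(trisomic | x, marker j) = x'beta + u_j,   u_j ~ N(0, sigma_b^2).

Estimation maximizes the Laplace approximation of the marginal
likelihood.  The fixed effects and the random-intercept values are
optimized jointly inside a penalized iteratively-reweighted
least-squares (PIRLS) step; a derivative-free bounded search over
log sigma_b wraps it.  This profiling layout is the standard one-
quadrature-point scheme of mixed-model software, so fits reproduce what
``glmer``-style defaults would report on the same data.

Because trisomic and normal height ratios are nearly perfectly
separated in real panels, the fixed effects of a full model are
quasi-separated: coefficient magnitudes are optimizer-sensitive and
essentially unbounded, while fitted probabilities remain stable.  The
fitter therefore caps inner iterations, reports a ``separation_flag``
(max |linear predictor| above a configurable bound), and downstream
classification is built on fitted probabilities, never on coefficient
values.

An adaptive Gauss--Hermite quadrature evaluation of the marginal
log-likelihood (:func:`agq_loglik`, default order 50) is provided as an
independent accuracy oracle for the Laplace approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.special import expit, logsumexp

from .tables import DiallelicObservation

FIXED_TERMS = ("intercept", "height_ratio", "size_difference")

#: |linear predictor| above this at the optimum flags quasi-separation
DEFAULT_ETA_BOUND = 30.0
_LOG_SIGMA_BOUNDS = (math.log(1e-4), math.log(25.0))


class GlmmError(RuntimeError):
    """Raised for an unusable model specification or data."""


@dataclass(frozen=True)
class GlmmSpec:
    """Model specification: fixed terms and the grouping factor.

    The intercept is always included; ``grouping`` is the observation
    attribute holding the random-intercept level (the marker).
    """

    fixed_terms: tuple[str, ...] = FIXED_TERMS
    grouping: str = "marker"

    def __post_init__(self) -> None:
        terms = tuple(self.fixed_terms)
        if "intercept" not in terms:
            terms = ("intercept",) + terms
            object.__setattr__(self, "fixed_terms", terms)
        for t in terms:
            if t not in FIXED_TERMS:
                raise GlmmError(f"unknown fixed term {t!r}")

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_terms)


def standard_specs() -> list[GlmmSpec]:
    """The four-model comparison ladder: full, -size, -ratio, marker-only."""
    return [
        GlmmSpec(("intercept", "height_ratio", "size_difference")),
        GlmmSpec(("intercept", "height_ratio")),
        GlmmSpec(("intercept", "size_difference")),
        GlmmSpec(("intercept",)),
    ]


@dataclass
class GlmmFit:
    """A fitted binomial random-intercept model."""

    spec: GlmmSpec
    beta: dict[str, float]
    sigma_b: float
    conditional_modes: dict[str, float]
    logLik: float
    deviance_resid: float
    aic: float
    bic: float
    df_residual: int
    n_obs: int
    converged: bool
    separation_flag: bool

    @property
    def k(self) -> int:
        """Parameter count for information criteria (fixed effects + sigma)."""
        return self.spec.n_fixed + 1


def information_criteria(
    log_lik: float, n_fixed: int, n_obs: int
) -> tuple[float, float, int]:
    """(AIC, BIC, residual df) for a fit with ``n_fixed`` fixed effects.

    k = n_fixed + 1 counts the random-intercept standard deviation.
    """
    k = n_fixed + 1
    return 2 * k - 2 * log_lik, k * math.log(n_obs) - 2 * log_lik, n_obs - k


# ---------------------------------------------------------------------------
# design construction


def response_from_labels(data: Sequence[DiallelicObservation]) -> np.ndarray:
    """Trisomic = 1, normal = 0 (the coding behind the coefficient signs)."""
    return np.array(
        [1.0 if o.label.startswith("trisomic") else 0.0 for o in data]
    )


def _design(
    data: Sequence[DiallelicObservation], spec: GlmmSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    cols = []
    for term in spec.fixed_terms:
        if term == "intercept":
            cols.append(np.ones(len(data)))
        elif term == "height_ratio":
            cols.append(np.array([o.height_ratio for o in data]))
        else:
            cols.append(np.array([o.size_difference for o in data]))
    X = np.column_stack(cols)
    levels = sorted({getattr(o, spec.grouping) for o in data})
    index = {m: j for j, m in enumerate(levels)}
    g = np.array([index[getattr(o, spec.grouping)] for o in data], dtype=np.intp)
    return X, g, levels


def _log1pexp(eta: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, eta)


# ---------------------------------------------------------------------------
# inner PIRLS: joint Newton over (beta, u) at fixed sigma


def _pirls(
    X: np.ndarray,
    y: np.ndarray,
    g: np.ndarray,
    n_groups: int,
    sigma: float,
    start: np.ndarray | None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Maximize the sigma-penalized joint log-likelihood over (beta, u).

    Returns (beta, u, last relative change, converged).
    """
    n, p = X.shape
    G = n_groups
    mixed = sigma > 0
    v = np.zeros(p + (G if mixed else 0)) if start is None else start.copy()

    def split(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta = v[:p]
        u = v[p:] if mixed else np.zeros(G)
        return beta, u

    def pll(v: np.ndarray) -> float:
        beta, u = split(v)
        eta = X @ beta + u[g]
        val = float(np.sum(y * eta - _log1pexp(eta)))
        if mixed:
            val -= 0.5 * float(u @ u) / sigma**2
        return val

    f = pll(v)
    change = np.inf
    for _ in range(max_iter):
        beta, u = split(v)
        eta = X @ beta + u[g]
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        r = y - mu
        Xw = X * w[:, None]
        A = X.T @ Xw
        gb = X.T @ r
        if mixed:
            B = np.zeros((G, p))
            np.add.at(B, g, Xw)
            D = np.bincount(g, weights=w, minlength=G) + 1.0 / sigma**2
            gu = np.bincount(g, weights=r, minlength=G) - u / sigma**2
            H = np.zeros((p + G, p + G))
            H[:p, :p] = A
            H[:p, p:] = B.T
            H[p:, :p] = B
            H[np.arange(p, p + G), np.arange(p, p + G)] = D
            grad = np.concatenate([gb, gu])
        else:
            H = A
            grad = gb
        try:
            c = cho_factor(H + 1e-10 * np.eye(H.shape[0]), lower=True)
            step = cho_solve(c, grad)
        except np.linalg.LinAlgError:
            c = cho_factor(H + 1e-6 * np.eye(H.shape[0]), lower=True)
            step = cho_solve(c, grad)
        # step halving on the penalized objective
        t = 1.0
        for _half in range(30):
            v_new = v + t * step
            f_new = pll(v_new)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        change = abs(f_new - f) / (abs(f) + 1.0)
        v, f = v_new, f_new
        if change < tol:
            break
    beta, u = split(v)
    return beta, u, change, change < 1e-5


def _laplace_loglik(
    X: np.ndarray,
    y: np.ndarray,
    g: np.ndarray,
    n_groups: int,
    sigma: float,
    beta: np.ndarray,
    u: np.ndarray,
) -> float:
    """Laplace marginal log-likelihood at the joint (beta, u) optimum."""
    eta = X @ beta + u[g]
    mu = expit(eta)
    w = mu * (1.0 - mu)
    ll = float(np.sum(y * eta - _log1pexp(eta)))
    if sigma > 0:
        sum_w = np.bincount(g, weights=w, minlength=n_groups)
        ll -= 0.5 * float(u @ u) / sigma**2
        ll -= 0.5 * float(np.sum(np.log1p(sigma**2 * sum_w)))
    return ll


def fit_glmm(
    data: Sequence[DiallelicObservation],
    spec: GlmmSpec = GlmmSpec(),
    response: np.ndarray | None = None,
    sigma_b: float | None = None,
    eta_bound: float = DEFAULT_ETA_BOUND,
    max_inner_iter: int = 100,
) -> GlmmFit:
    """Fit the random-intercept logistic model by Laplace approximation.

    Parameters
    ----------
    data
        Observations carrying ``height_ratio``, ``size_difference`` and
        the grouping attribute.
    response
        Binary response; derived from the labels (trisomic = 1) when
        omitted.
    sigma_b
        Fix the random-intercept SD instead of estimating it
        (``0`` reduces the fit to an ordinary logistic GLM).
    eta_bound
        |linear predictor| above this at the optimum sets
        ``separation_flag``.

    Returns
    -------
    GlmmFit
        Never raises on non-convergence: the best point found is
        returned with ``converged=False``.  A singular fit
        (sigma_b -> 0) is reported, not an error.
    """
    if len(data) == 0:
        raise GlmmError("no observations")
    y = response_from_labels(data) if response is None else np.asarray(response, float)
    if len(y) != len(data):
        raise GlmmError("response length mismatch")
    if sigma_b is None and (np.all(y == 0) or np.all(y == 1)):
        raise GlmmError("need both response classes to fit")
    X, g, levels = _design(data, spec)
    G = len(levels)
    if G < 2 and sigma_b is None:
        raise GlmmError("grouping needs >= 2 levels for a mixed fit")

    state: dict = {"start": None, "start_glm": None}

    def profile(sigma: float) -> tuple[float, np.ndarray, np.ndarray, bool]:
        key = "start" if sigma > 0 else "start_glm"
        beta, u, _, conv = _pirls(
            X, y, g, G, sigma, state[key], max_iter=max_inner_iter
        )
        state[key] = np.concatenate([beta, u]) if sigma > 0 else beta.copy()
        return _laplace_loglik(X, y, g, G, sigma, beta, u), beta, u, conv

    if sigma_b is not None:
        ll, beta, u, conv = profile(float(sigma_b))
        sigma_hat = float(sigma_b)
        outer_ok = True
    else:
        res = minimize_scalar(
            lambda t: -profile(math.exp(t))[0],
            bounds=_LOG_SIGMA_BOUNDS,
            method="bounded",
            options={"xatol": 1e-6},
        )
        outer_ok = bool(res.success)
        sigma_hat = float(math.exp(res.x))
        ll, beta, u, conv = profile(sigma_hat)
        # boundary check: a singular (sigma ~ 0) fit may beat the interior
        ll0, beta0, u0, conv0 = profile(0.0)
        if ll0 > ll:
            sigma_hat, ll, beta, u, conv = 0.0, ll0, beta0, u0, conv0

    eta = X @ beta + u[g]
    dev_resid = float(np.sum(2.0 * (_log1pexp(eta) - y * eta)))
    aic, bic, df_resid = information_criteria(ll, spec.n_fixed, len(y))
    return GlmmFit(
        spec=spec,
        beta={t: float(b) for t, b in zip(spec.fixed_terms, beta)},
        sigma_b=sigma_hat,
        conditional_modes={m: float(u[j]) for j, m in enumerate(levels)},
        logLik=ll,
        deviance_resid=dev_resid,
        aic=aic,
        bic=bic,
        df_residual=df_resid,
        n_obs=len(y),
        converged=bool(conv and outer_ok),
        separation_flag=bool(np.max(np.abs(eta)) > eta_bound),
    )


# ---------------------------------------------------------------------------
# prediction


def predict_logit(
    fit: GlmmFit,
    obs: DiallelicObservation,
    use_marker_effect: bool = True,
) -> float:
    """Linear predictor for one observation.

    ``use_marker_effect`` adds the marker's conditional mode; an unseen
    marker falls back to the population-level prediction with a warning.
    """
    logit = 0.0
    for term, b in fit.beta.items():
        if term == "intercept":
            logit += b
        elif term == "height_ratio":
            logit += b * obs.height_ratio
        else:
            logit += b * obs.size_difference
    if use_marker_effect:
        marker = getattr(obs, fit.spec.grouping)
        if marker in fit.conditional_modes:
            logit += fit.conditional_modes[marker]
        else:
            warnings.warn(
                f"marker {marker!r} unseen in training; "
                "using population-level prediction",
                stacklevel=2,
            )
    return float(logit)


def logit_to_probability(logit: float | np.ndarray) -> float | np.ndarray:
    """p = exp(logit) / (1 + exp(logit)), underflow-safe (clamped at +-700)."""
    return expit(np.clip(logit, -700.0, 700.0))


def predict_probability(
    fit: GlmmFit, obs: DiallelicObservation, use_marker_effect: bool = True
) -> float:
    return float(logit_to_probability(predict_logit(fit, obs, use_marker_effect)))


# ---------------------------------------------------------------------------
# adaptive Gauss-Hermite oracle (independent of the Laplace code path)


def agq_loglik(
    data: Sequence[DiallelicObservation],
    spec: GlmmSpec,
    beta: Sequence[float],
    sigma_b: float,
    response: np.ndarray | None = None,
    order: int = 50,
) -> float:
    """Marginal log-likelihood by adaptive Gauss--Hermite quadrature.

    Evaluates the random-effect integral per group at fixed
    (beta, sigma_b) with ``order`` nodes centered and scaled at each
    group's conditional mode.  Serves as the accuracy oracle for the
    Laplace approximation; for sigma_b = 0 it reduces to the exact
    Bernoulli log-likelihood.
    """
    y = response_from_labels(data) if response is None else np.asarray(response, float)
    X, g, levels = _design(data, spec)
    offset = X @ np.asarray(beta, float)
    if sigma_b <= 0:
        return float(np.sum(y * offset - _log1pexp(offset)))
    nodes, weights = hermgauss(order)
    total = 0.0
    for j in range(len(levels)):
        mask = g == j
        o_j, y_j = offset[mask], y[mask]

        def nll_parts(u: float) -> tuple[float, float, float]:
            eta = o_j + u
            ll = float(np.sum(y_j * eta - np.logaddexp(0.0, eta)))
            mu = expit(eta)
            grad = float(np.sum(y_j - mu)) - u / sigma_b**2
            hess = float(np.sum(mu * (1 - mu))) + 1.0 / sigma_b**2
            return ll - 0.5 * u**2 / sigma_b**2, grad, hess

        # 1-D Newton for the group's conditional mode
        u_hat = 0.0
        for _ in range(50):
            _, grad, hess = nll_parts(u_hat)
            step = grad / hess
            u_hat += step
            if abs(step) < 1e-12:
                break
        _, _, hess = nll_parts(u_hat)
        s = 1.0 / math.sqrt(hess)
        u_k = u_hat + math.sqrt(2.0) * s * nodes
        eta_k = o_j[:, None] + u_k[None, :]
        ll_k = np.sum(
            y_j[:, None] * eta_k - np.logaddexp(0.0, eta_k), axis=0
        )
        log_terms = (
            np.log(weights)
            + nodes**2
            + ll_k
            - 0.5 * u_k**2 / sigma_b**2
            - 0.5 * math.log(2 * math.pi * sigma_b**2)
        )
        total += logsumexp(log_terms) + 0.5 * math.log(2.0 * s * s)
    return float(total)


# ---------------------------------------------------------------------------
# parametric bootstrap


def bootstrap_ci(
    fit: GlmmFit,
    data: Sequence[DiallelicObservation],
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Percentile parametric-bootstrap confidence intervals.

    Responses are simulated from the fitted model with redrawn random
    intercepts, the model is refitted, and per-parameter percentile
    intervals are taken over the converged replicates.  Replicates that
    fail to converge are dropped and counted; more than 50% failures is
    an error.
    """
    if seed is None:
        raise GlmmError("bootstrap requires an explicit seed")
    if n_boot < 1:
        raise GlmmError("n_boot must be >= 1")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable interval endpoints", stacklevel=2)
    rng = np.random.default_rng(seed)
    X, g, levels = _design(data, fit.spec)
    beta = np.array([fit.beta[t] for t in fit.spec.fixed_terms])
    draws: list[list[float]] = []
    n_failed = 0
    names = list(fit.spec.fixed_terms) + ["sigma_b"]
    for _ in range(n_boot):
        u = rng.normal(0.0, fit.sigma_b, size=len(levels))
        p = expit(X @ beta + u[g])
        y = (rng.random(len(p)) < p).astype(float)
        if y.min() == y.max():
            n_failed += 1
            continue
        try:
            bfit = fit_glmm(data, fit.spec, response=y)
        except (GlmmError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not bfit.converged and not bfit.separation_flag:
            n_failed += 1
            continue
        draws.append(
            [bfit.beta[t] for t in fit.spec.fixed_terms] + [bfit.sigma_b]
        )
    if n_failed > 0.5 * n_boot:
        raise GlmmError(f"{n_failed}/{n_boot} bootstrap replicates failed")
    arr = np.array(draws)
    alpha = (1.0 - level) / 2.0
    lo = np.percentile(arr, 100 * alpha, axis=0)
    hi = np.percentile(arr, 100 * (1 - alpha), axis=0)
    return {nm: (float(a), float(b)) for nm, a, b in zip(names, lo, hi)}


# ---------------------------------------------------------------------------
# model comparison


def compare_models(
    data: Sequence[DiallelicObservation],
    specs: Sequence[GlmmSpec] | None = None,
    response: np.ndarray | None = None,
):
    """Information-criteria comparison table, one row per model.

    Rows follow the given spec order (default: full, without size
    difference, without height ratio, marker-only).  A failed fit
    yields a row with NaN metrics and the error message; it never
    aborts the remaining fits.
    """
    import pandas as pd

    specs = standard_specs() if specs is None else list(specs)
    rows = []
    fits: list[GlmmFit | None] = []
    for spec in specs:
        name = "+".join(t for t in spec.fixed_terms if t != "intercept") or "marker_only"
        try:
            f = fit_glmm(data, spec, response=response)
        except GlmmError as exc:
            rows.append(
                {
                    "model": name,
                    "logLik": math.nan,
                    "deviance_resid": math.nan,
                    "AIC": math.nan,
                    "BIC": math.nan,
                    "df_residual": math.nan,
                    "error": str(exc),
                }
            )
            fits.append(None)
            continue
        rows.append(
            {
                "model": name,
                "logLik": f.logLik,
                "deviance_resid": f.deviance_resid,
                "AIC": f.aic,
                "BIC": f.bic,
                "df_residual": f.df_residual,
                "error": "",
            }
        )
        fits.append(f)
    table = pd.DataFrame(rows)
    table.attrs["fits"] = fits
    return table
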