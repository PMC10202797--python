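"""Multilevel binomial regression via Laplace-approximated maximum likelihood.

The model: for arm j of experiment i, with impressions n_ij and clicks y_ij,

    y_ij ~ Binomial(n_ij, theta_ij),   logit(theta_ij) = x_ij' beta + z_ij' b_i,

where b_i ~ N(0, Sigma) are experiment-level random effects (an intercept,
optionally plus varying slopes).  The marginal likelihood integrates the
random effects out; each experiment's integral is approximated by Laplace's
method around the conditional mode (the de-facto standard for binomial
mixed models).  An adaptive Gauss–Hermite quadrature evaluator of the same
marginal likelihood is provided as an independent cross-check for the
random-intercept model.

Estimation maximizes the Laplace log-likelihood by quasi-Newton (L-BFGS-B)
over the fixed effects and a log-Cholesky parameterization of Sigma.
Standard errors come from the inverse numerical Hessian over the fixed
effects at the optimum, holding Sigma fixed (the usual conditional-on-theta
convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "Standardization",
    "GlmmFit",
    "FitError",
    "RankDeficiencyError",
    "standardize_features",
    "LaplaceBinomialGLMM",
    "fit_glmm",
    "wald_inference",
    "odds_percent_change",
    "per_word_effect",
    "model_concordance",
]


class FitError(RuntimeError):
    """Estimation failed irrecoverably."""


class RankDeficiencyError(FitError):
    """The fixed-effect design matrix is not full rank."""


# --------------------------------------------------------------------------
# model specification and design matrix
# --------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Specification of one multilevel binomial regression.

    ``fixed_terms`` are covariate column names (a global intercept is
    always included).  ``interactions`` adds product terms ``a:b`` and
    ``squared_terms`` adds ``a^2`` columns.  ``random_slopes`` names
    covariates whose coefficients vary by experiment in addition to the
    random intercept; they must appear among the fixed terms.
    """

    fixed_terms: list[str]
    grouping: str = "experiment_id"
    response: tuple[str, str] = ("clicks", "impressions")
    random_slopes: list[str] = field(default_factory=list)
    covariance_structure: str = "full"  # "full" | "diagonal"
    interactions: list[tuple[str, str]] = field(default_factory=list)
    squared_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.covariance_structure not in ("full", "diagonal"):
            raise ValueError("covariance_structure must be 'full' or 'diagonal'")
        missing = [t for t in self.random_slopes if t not in self.fixed_terms]
        if missing:
            raise ValueError(f"random slopes {missing} are not among fixed_terms")

    @property
    def term_names(self) -> list[str]:
        names = ["(Intercept)"] + list(self.fixed_terms)
        names += [f"{a}:{b}" for a, b in self.interactions]
        names += [f"{t}^2" for t in self.squared_terms]
        return names


def build_design(spec: ModelSpec, rows: pd.DataFrame):
    """Construct (X, y, n, group_codes, z_columns) from a feature table."""
    n_rows = len(rows)
    cols = [np.ones(n_rows)]
    for t in spec.fixed_terms:
        cols.append(np.asarray(rows[t], dtype=float))
    for a, b in spec.interactions:
        cols.append(np.asarray(rows[a], dtype=float) * np.asarray(rows[b], dtype=float))
    for t in spec.squared_terms:
        cols.append(np.asarray(rows[t], dtype=float) ** 2)
    X = np.column_stack(cols)
    names = spec.term_names

    # rank check via QR: name the collinear columns
    r_diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
    bad = [names[k] for k in np.nonzero(r_diag < 1e-10 * max(r_diag.max(), 1.0))[0]]
    if bad:
        raise RankDeficiencyError(f"design matrix rank-deficient; collinear terms: {bad}")

    y = np.asarray(rows[spec.response[0]], dtype=float)
    n = np.asarray(rows[spec.response[1]], dtype=float)
    codes, _ = pd.factorize(rows[spec.grouping], sort=False)
    z_cols = [0] + [1 + spec.fixed_terms.index(t) for t in spec.random_slopes]
    return X, y, n, codes, z_cols


# --------------------------------------------------------------------------
# standardization
# --------------------------------------------------------------------------

@dataclass
class Standardization:
    """Per-variable sample mean and SD (n−1 denominator), unweighted over
    headline rows, used to z-standardize covariates before fitting."""

    means: dict[str, float]
    sds: dict[str, float]

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        out = rows.copy()
        for v in self.means:
            out[v] = (out[v] - self.means[v]) / self.sds[v]
        return out

    def inverse(self, rows: pd.DataFrame) -> pd.DataFrame:
        out = rows.copy()
        for v in self.means:
            out[v] = out[v] * self.sds[v] + self.means[v]
        return out


def standardize_features(rows: pd.DataFrame, variables: list[str]):
    """Z-standardize the listed columns (mean 0, sample SD 1).

    Returns the transformed copy and the :class:`Standardization` record
    needed to undo or re-apply the transform.  A constant column is a
    degenerate input and raises, naming the variable.
    """
    means, sds = {}, {}
    for v in variables:
        x = np.asarray(rows[v], dtype=float)
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        if not np.isfinite(sd) or sd <= 0.0:
            raise ValueError(f"variable {v!r} is constant; cannot standardize")
        means[v], sds[v] = float(np.mean(x)), sd
    std = Standardization(means=means, sds=sds)
    return std.transform(rows), std


# --------------------------------------------------------------------------
# Laplace marginal likelihood
# --------------------------------------------------------------------------

class LaplaceBinomialGLMM:
    """Laplace-approximated marginal likelihood for one model + dataset.

    Rows are grouped by experiment and padded to the widest experiment so
    the inner Newton mode-finding runs batched across all experiments.
    """

    def __init__(self, spec: ModelSpec, rows: pd.DataFrame):
        if rows.empty:
            raise FitError("no rows to fit")
        self.spec = spec
        X, y, n, codes, z_cols = build_design(spec, rows)
        self.n_obs = len(y)
        self.n_groups = int(codes.max()) + 1
        if self.n_groups < 2:
            raise FitError("need at least 2 experiments to fit a multilevel model")
        self.p = X.shape[1]
        self.q = len(z_cols)
        self.X, self.y, self.n = X, y, n

        order = np.argsort(codes, kind="stable")
        sizes = np.bincount(codes, minlength=self.n_groups)
        M = int(sizes.max())
        G = self.n_groups
        self.Xp = np.zeros((G, M, self.p))
        self.yp = np.zeros((G, M))
        self.np_ = np.zeros((G, M))
        self.mask = np.zeros((G, M))
        pos = np.zeros(G, dtype=int)
        for r in order:
            g = codes[r]
            k = pos[g]
            self.Xp[g, k] = X[r]
            self.yp[g, k] = y[r]
            self.np_[g, k] = n[r]
            self.mask[g, k] = 1.0
            pos[g] += 1
        self._z_cols = z_cols
        self.Zp = self.Xp[:, :, z_cols]
        # binomial combinatorial constant (so degenerate limits match the
        # plain binomial log-likelihood exactly)
        self.const = float(
            np.sum(special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1))
        )
        self._b_cache = np.zeros((G, self.q))

    def precondition(self) -> np.ndarray:
        """Scale non-intercept design columns to unit SD (in place).

        Pure reparameterization for numerical conditioning: estimates are
        mapped back to the original scale after optimization.  Returns the
        per-column scale factors (1 for the intercept).
        """
        sd = self.X.std(axis=0)
        scales = np.where(sd > 0, sd, 1.0)
        scales[0] = 1.0
        self.X = self.X / scales
        self.Xp = self.Xp / scales
        self.Zp = self.Xp[:, :, self._z_cols]
        return scales

    # ---- covariance parameterization --------------------------------------

    @property
    def n_theta(self) -> int:
        q = self.q
        return q if self.spec.covariance_structure == "diagonal" else q * (q + 1) // 2

    def chol_from_theta(self, theta: np.ndarray) -> np.ndarray:
        """Lower-triangular Cholesky factor from the log-Cholesky vector
        (log-diagonal first, then row-major strict lower triangle)."""
        q = self.q
        L = np.zeros((q, q))
        L[np.diag_indices(q)] = np.exp(theta[:q])
        if self.spec.covariance_structure == "full" and q > 1:
            L[np.tril_indices(q, k=-1)] = theta[q:]
        return L

    def sigma_from_theta(self, theta: np.ndarray) -> np.ndarray:
        L = self.chol_from_theta(theta)
        return L @ L.T

    # ---- inner problem -----------------------------------------------------

    def _penalized(self, b, eta0, sigma_inv):
        """Per-group joint log density (up to the Gaussian normalizer)."""
        eta = eta0 + np.einsum("gmq,gq->gm", self.Zp, b)
        ll = np.sum(self.mask * (self.yp * eta - self.np_ * np.logaddexp(0.0, eta)), axis=1)
        pen = 0.5 * np.einsum("gq,qr,gr->g", b, sigma_inv, b)
        return ll - pen

    def _inner_modes(self, eta0, sigma_inv, tol: float = 1e-8, max_iter: int = 100):
        """Batched Newton mode-finding with step-halving.

        Returns the per-group modes and Hessians of the negative penalized
        log density.  Non-convergence after step-halving raises FitError.
        """
        b = self._b_cache.copy()
        obj = self._penalized(b, eta0, sigma_inv)
        for _ in range(max_iter):
            eta = eta0 + np.einsum("gmq,gq->gm", self.Zp, b)
            prob = special.expit(eta)
            resid = self.mask * (self.yp - self.np_ * prob)
            grad = np.einsum("gmq,gm->gq", self.Zp, resid) - b @ sigma_inv
            if np.max(np.abs(grad)) <= tol:
                break
            w = self.mask * self.np_ * prob * (1.0 - prob)
            hess = np.einsum("gmq,gm,gmr->gqr", self.Zp, w, self.Zp) + sigma_inv
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
            # step-halving per group until the penalized objective improves
            # (tolerance relative to the objective scale, so rounding noise
            # near convergence does not trigger spurious halving)
            scale = np.ones((len(b), 1))
            slack = 1e-10 * (1.0 + np.abs(obj))
            for _ in range(30):
                cand = b + scale * step
                new_obj = self._penalized(cand, eta0, sigma_inv)
                worse = new_obj < obj - slack
                if not np.any(worse):
                    break
                scale[worse] *= 0.5
            b = b + scale * step
            obj = self._penalized(b, eta0, sigma_inv)
        else:
            raise FitError("inner Newton iterations failed to converge")
        eta = eta0 + np.einsum("gmq,gq->gm", self.Zp, b)
        prob = special.expit(eta)
        w = self.mask * self.np_ * prob * (1.0 - prob)
        hess = np.einsum("gmq,gm,gmr->gqr", self.Zp, w, self.Zp) + sigma_inv
        self._b_cache = b
        return b, hess

    # ---- marginal log-likelihoods ------------------------------------------

    def plain_loglik(self, beta: np.ndarray) -> float:
        """Binomial log-likelihood with no random effects (Sigma = 0)."""
        eta = self.X @ beta
        return float(np.sum(self.y * eta - self.n * np.logaddexp(0.0, eta)) + self.const)

    def loglik(self, beta: np.ndarray, theta: np.ndarray) -> float:
        """Laplace-approximated marginal log-likelihood."""
        sigma = self.sigma_from_theta(theta)
        sigma_inv = np.linalg.inv(sigma)
        eta0 = np.einsum("gmp,p->gm", self.Xp, beta)
        b, hess = self._inner_modes(eta0, sigma_inv)
        joint = self._penalized(b, eta0, sigma_inv)
        _, logdet = np.linalg.slogdet(sigma @ hess)
        return float(np.sum(joint) - 0.5 * np.sum(logdet) + self.const)

    def loglik_params(self, params: np.ndarray) -> float:
        return self.loglik(params[: self.p], params[self.p:])

    def agq_loglik(self, beta: np.ndarray, theta: np.ndarray, n_nodes: int = 25) -> float:
        """Adaptive Gauss–Hermite evaluation of the same marginal
        log-likelihood (random-intercept model only).  Used as an
        independent oracle for the Laplace approximation."""
        if self.q != 1:
            raise NotImplementedError("quadrature oracle covers the random-intercept model")
        sigma2 = float(self.sigma_from_theta(theta)[0, 0])
        sigma_inv = np.array([[1.0 / sigma2]])
        eta0 = np.einsum("gmp,p->gm", self.Xp, beta)
        b_hat, hess = self._inner_modes(eta0, sigma_inv)
        h = hess[:, 0, 0]  # (G,)
        nodes, weights = hermgauss(n_nodes)
        scale = np.sqrt(2.0 / h)  # (G,)
        bk = b_hat[:, 0][:, None] + scale[:, None] * nodes[None, :]  # (G, K)
        eta = eta0[:, :, None] + self.Zp[:, :, 0][:, :, None] * bk[:, None, :]
        ll = np.sum(
            self.mask[:, :, None] * (self.yp[:, :, None] * eta - self.np_[:, :, None] * np.logaddexp(0.0, eta)),
            axis=1,
        )  # (G, K)
        log_prior = -0.5 * bk**2 / sigma2 - 0.5 * np.log(2.0 * np.pi * sigma2)
        log_terms = np.log(weights)[None, :] + nodes[None, :] ** 2 + ll + log_prior
        per_group = np.log(scale) + special.logsumexp(log_terms, axis=1)
        return float(np.sum(per_group) + self.const)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class GlmmFit:
    """Result of one multilevel binomial fit."""

    terms: list[str]
    coefficients: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p_values: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    ci_level: float
    cov_re: np.ndarray
    re_terms: list[str]
    loglik: float
    n_iter: int
    converged: bool
    n_obs: int
    n_groups: int
    method: str = "laplace"
    standardization: Standardization | None = None

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se_of(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    def p_of(self, term: str) -> float:
        return float(self.p_values[self.terms.index(term)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.coefficients,
                "se": self.se,
                "z": self.z,
                "p": self.p_values,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def to_dict(self) -> dict:
        d = {
            "terms": self.terms,
            "coefficients": self.coefficients.tolist(),
            "se": self.se.tolist(),
            "z": self.z.tolist(),
            "p_values": self.p_values.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "ci_level": self.ci_level,
            "cov_re": self.cov_re.tolist(),
            "re_terms": self.re_terms,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "method": self.method,
        }
        if self.standardization is not None:
            d["standardization"] = {
                "means": self.standardization.means,
                "sds": self.standardization.sds,
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _start_values(problem: LaplaceBinomialGLMM) -> np.ndarray:
    """Fixed-effect starting values from a no-random-effect logistic fit
    (IRLS on the aggregated binomial counts)."""
    X, y, n = problem.X, problem.y, problem.n
    beta = np.zeros(problem.p)
    beta[0] = special.logit(np.clip(np.sum(y) / np.sum(n), 1e-10, 1 - 1e-10))
    for _ in range(25):
        eta = X @ beta
        prob = special.expit(eta)
        w = np.maximum(n * prob * (1.0 - prob), 1e-10)
        zwork = eta + (y - n * prob) / w
        wx = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ wx, wx.T @ zwork)
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _fixed_effect_hessian(fun, beta: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of -loglik over the fixed effects."""
    p = len(beta)
    h = 1e-5 * (1.0 + np.abs(beta))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            bpp = beta.copy(); bpp[i] += h[i]; bpp[j] += h[j]
            bpm = beta.copy(); bpm[i] += h[i]; bpm[j] -= h[j]
            bmp = beta.copy(); bmp[i] -= h[i]; bmp[j] += h[j]
            bmm = beta.copy(); bmm[i] -= h[i]; bmm[j] -= h[j]
            H[i, j] = H[j, i] = -(fun(bpp) - fun(bpm) - fun(bmp) + fun(bmm)) / (
                4.0 * h[i] * h[j]
            )
    return H


def fit_glmm(
    spec: ModelSpec,
    rows: pd.DataFrame,
    ci_level: float = 0.99,
    method: str = "laplace",
    fix_variance_zero: bool = False,
    standardization: Standardization | None = None,
    max_iter: int = 500,
    gtol: float = 1e-6,
    start_cov: float = 0.1,
    agq_nodes: int = 25,
) -> GlmmFit:
    """Fit the multilevel binomial regression by (quasi-Newton) maximum
    Laplace likelihood.

    Parameters of note: ``method`` selects the marginal-likelihood
    evaluator (``"laplace"`` or the quadrature oracle ``"agq"``, the
    latter for the random-intercept model only); ``fix_variance_zero``
    collapses the model to a plain logistic regression (used for the
    degenerate-limit cross-check); ``start_cov`` is the initial
    random-effect covariance (``start_cov``·identity).  Deterministic
    given data and starting values.
    """
    problem = LaplaceBinomialGLMM(spec, rows)
    # unit-SD column preconditioning (pure reparameterization; mapped back)
    scales = problem.precondition()
    z_scales = scales[[0] + [1 + spec.fixed_terms.index(t) for t in spec.random_slopes]]
    beta0 = _start_values(problem)

    if fix_variance_zero:
        res = optimize.minimize(
            lambda b: -problem.plain_loglik(b),
            beta0,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": gtol},
        )
        beta_hat = res.x
        ll = problem.plain_loglik(beta_hat)
        H = _fixed_effect_hessian(problem.plain_loglik, beta_hat)
        cov_re = np.zeros((problem.q, problem.q))
        n_iter, converged = res.nit, bool(res.success)
    else:
        if method == "laplace":
            evaluate = problem.loglik
        elif method == "agq":
            evaluate = lambda b, t: problem.agq_loglik(b, t, n_nodes=agq_nodes)  # noqa: E731
        else:
            raise ValueError(f"unknown method {method!r}")
        theta0 = np.zeros(problem.n_theta)
        theta0[: problem.q] = 0.5 * np.log(start_cov)
        x0 = np.concatenate([beta0, theta0])
        bounds = [(None, None)] * problem.p
        bounds += [(np.log(1e-6), 8.0)] * problem.q
        bounds += [(None, None)] * (problem.n_theta - problem.q)

        def negll(x):
            return -evaluate(x[: problem.p], x[problem.p:])

        res = optimize.minimize(
            negll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": gtol},
        )
        beta_hat, theta_hat = res.x[: problem.p], res.x[problem.p:]
        ll = evaluate(beta_hat, theta_hat)
        H = _fixed_effect_hessian(lambda b: evaluate(b, theta_hat), beta_hat)
        cov_re = problem.sigma_from_theta(theta_hat)
        n_iter, converged = res.nit, bool(res.success)

    # map estimates, covariance and random-effect covariance back to the
    # original column scales
    beta_hat = beta_hat / scales
    cov_re = cov_re / np.outer(z_scales, z_scales)
    try:
        cov_beta = np.linalg.inv(H) / np.outer(scales, scales)
        se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(problem.p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta_hat / se, np.nan)
    p_values = 2.0 * stats.norm.sf(np.abs(z))
    crit = stats.norm.ppf(1.0 - (1.0 - ci_level) / 2.0)
    re_terms = ["(Intercept)"] + list(spec.random_slopes)

    return GlmmFit(
        terms=spec.term_names,
        coefficients=beta_hat,
        se=se,
        z=z,
        p_values=p_values,
        ci_low=beta_hat - crit * se,
        ci_high=beta_hat + crit * se,
        ci_level=ci_level,
        cov_re=cov_re,
        re_terms=re_terms,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        n_obs=problem.n_obs,
        n_groups=problem.n_groups,
        method="plain" if fix_variance_zero else method,
        standardization=standardization,
    )


# --------------------------------------------------------------------------
# inference and effect translation
# --------------------------------------------------------------------------

def wald_inference(fit: GlmmFit, level: float = 0.99) -> pd.DataFrame:
    """Per-coefficient Wald z statistics, two-sided normal p values, and
    CIs at the requested level.  Coefficients with zero or non-finite SE
    get NaN inference (marked unavailable)."""
    se = np.asarray(fit.se, dtype=float)
    ok = np.isfinite(se) & (se > 0)
    z = np.where(ok, fit.coefficients / np.where(ok, se, 1.0), np.nan)
    p = np.where(ok, 2.0 * stats.norm.sf(np.abs(z)), np.nan)
    crit = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    return pd.DataFrame(
        {
            "term": fit.terms,
            "estimate": fit.coefficients,
            "se": se,
            "z": z,
            "p": p,
            "ci_low": np.where(ok, fit.coefficients - crit * se, np.nan),
            "ci_high": np.where(ok, fit.coefficients + crit * se, np.nan),
        }
    )


def odds_percent_change(beta: float) -> float:
    """Percent change in the click odds per one-SD covariate change:
    100 × (e^beta − 1)."""
    return 100.0 * (np.exp(beta) - 1.0)


def per_word_effect(beta_std: float, sd_raw: float, mean_length: float) -> float:
    """Percent odds change from one extra dictionary word.

    One extra word in a headline of average length shifts the raw word
    proportion by 1/mean_length; dividing by the raw proportion's SD
    converts that shift to the standardized scale on which ``beta_std``
    lives, and the odds translation turns it into a percentage.
    """
    if sd_raw <= 0 or mean_length <= 0:
        raise ValueError("sd_raw and mean_length must be positive")
    return odds_percent_change(beta_std * (1.0 / mean_length) / sd_raw)


def model_concordance(
    fit_a: GlmmFit, fit_b: GlmmFit, terms: list[str], alpha: float = 0.01
) -> dict:
    """Compare two fits term by term (sign and significance).

    When a term is discordant, interpretive precedence goes to ``fit_b``
    (by convention the more flexible varying-slopes model).
    """
    report: dict = {"terms": {}, "all_concordant": True}
    for t in terms:
        if t not in fit_a.terms or t not in fit_b.terms:
            raise KeyError(f"term {t!r} missing from one of the fits")
        ca, cb = fit_a.coef(t), fit_b.coef(t)
        sa, sb = fit_a.p_of(t) < alpha, fit_b.p_of(t) < alpha
        concordant = (np.sign(ca) == np.sign(cb)) and sa and sb
        report["terms"][t] = {
            "estimate_a": ca,
            "estimate_b": cb,
            "significant_a": bool(sa),
            "significant_b": bool(sb),
            "concordant": bool(concordant),
        }
        if not concordant:
            report["all_concordant"] = False
    report["note"] = (
        "Models agree on sign and significance for all compared terms."
        if report["all_concordant"]
        else "Models disagree for at least one term; interpretive precedence "
        "goes to the varying-slopes fit (fit_b)."
    )
    return report
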