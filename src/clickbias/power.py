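"""Simulation-based power analysis by parametric bootstrap.

The procedure mirrors a pre-registration power study: resample experiments
(RCTs) with replacement from a pilot feature table, simulate clicks from
the multilevel binomial model at chosen parameter values, refit the model
on each simulated dataset, and count how often the target coefficient is
detected.  Power is the detection fraction; at a true effect of zero the
same machinery estimates the type-I error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .glmm import FitError, ModelSpec, build_design, fit_glmm, standardize_features


def draw_random_effects(
    rng: np.random.Generator, cov: np.ndarray, size: int
) -> np.ndarray:
    """Draw N(0, cov) rows; accepts singular (PSD) covariances, including
    the zero matrix (no heterogeneity)."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    q = cov.shape[0]
    w, v = np.linalg.eigh(cov)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((size, q)) @ factor.T


@dataclass
class PowerConfig:
    """Configuration of one bootstrap power run.

    The published study used 1,000 datasets of 22,743 RCTs each;
    desk-scale defaults (200 datasets of 500 experiments) keep a run in
    the minutes range while preserving the procedure.  ``alpha`` defaults
    to 0.01, matching the 99%-CI reporting convention.
    """

    target: str = "negative"
    effect: float = 0.01
    n_datasets: int = 200
    n_experiments: int = 500
    alpha: float = 0.01
    seed: int = 0
    model: str = "random-intercept"  # "random-intercept" | "varying-slopes"

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.model not in ("random-intercept", "varying-slopes"):
            raise ValueError("model must be 'random-intercept' or 'varying-slopes'")


@dataclass
class PowerResult:
    power: float
    mc_se: float
    rejections: list[bool]
    n_failed: int
    unreliable: bool
    config: PowerConfig = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "power": self.power,
            "mc_se": self.mc_se,
            "n_datasets_used": len(self.rejections),
            "n_failed": self.n_failed,
            "unreliable": self.unreliable,
        }


def simulate_clicks(
    rows: pd.DataFrame,
    spec: ModelSpec,
    beta: np.ndarray,
    cov_re: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw clicks from the multilevel binomial model.

    Experiment-level random effects are drawn from N(0, cov_re), the
    linear predictor is formed per row, and clicks ~ Binomial(impressions,
    logistic(eta)).  Deterministic given the generator state.
    """
    X, _, n, codes, z_cols = build_design(spec, rows)
    q = len(z_cols)
    beta = np.asarray(beta, dtype=float)
    cov_re = np.atleast_2d(np.asarray(cov_re, dtype=float))
    if beta.shape[0] != X.shape[1]:
        raise ValueError(
            f"beta has length {beta.shape[0]}, design has {X.shape[1]} columns"
        )
    if cov_re.shape != (q, q):
        raise ValueError(f"cov_re must be {q}x{q} for this model, got {cov_re.shape}")
    n_groups = int(codes.max()) + 1
    b = draw_random_effects(rng, cov_re, n_groups)
    eta = X @ beta + np.sum(X[:, z_cols] * b[codes], axis=1)
    theta = special.expit(eta)
    return rng.binomial(n.astype(np.int64), theta)


def _model_spec(pilot: pd.DataFrame, config: PowerConfig) -> ModelSpec:
    covariates = [
        c for c in ("positive", "negative", "length", "complexity", "platform_age")
        if c in pilot.columns
    ]
    if config.target not in covariates:
        raise ValueError(f"target coefficient {config.target!r} not in pilot table")
    slopes = [c for c in ("positive", "negative") if c in covariates] \
        if config.model == "varying-slopes" else []
    return ModelSpec(fixed_terms=covariates, random_slopes=slopes)


def bootstrap_power(
    pilot: pd.DataFrame,
    beta: dict[str, float] | np.ndarray,
    cov_re: np.ndarray,
    config: PowerConfig,
) -> PowerResult:
    """Estimate power (or type-I error) by the bootstrap procedure.

    Per dataset: sample ``n_experiments`` experiments with replacement
    from the pilot table (each resampled copy becomes its own group),
    simulate clicks at the supplied parameters with the target
    coefficient set to ``config.effect``, re-standardize the covariates
    within the simulated dataset, refit, and flag a detection when the
    target's two-sided p value is below alpha — with a matching sign when
    a nonzero effect is configured (a wrong-sign detection is not a
    success), and with any sign at effect 0 (type-I calibration).

    Refit failures are excluded with a count; more than 10% failures
    flags the result unreliable.  Bit-reproducible for a fixed seed.
    """
    if pilot.empty:
        raise ValueError("pilot table is empty")
    spec = _model_spec(pilot, config)
    # truth is defined on the pilot's standardized covariate scale
    pilot_std, _ = standardize_features(pilot, spec.fixed_terms)
    if isinstance(beta, dict):
        beta_vec = np.array(
            [beta.get("(Intercept)", beta.get("intercept", 0.0))]
            + [beta.get(t, 0.0) for t in spec.fixed_terms]
        )
    else:
        beta_vec = np.asarray(beta, dtype=float)
    target_idx = 1 + spec.fixed_terms.index(config.target)
    beta_vec = beta_vec.copy()
    beta_vec[target_idx] = config.effect

    exp_ids = pilot_std["experiment_id"].unique()
    by_exp = {e: g.drop(columns=["experiment_id"]) for e, g in pilot_std.groupby("experiment_id")}

    child_seeds = np.random.SeedSequence(config.seed).spawn(config.n_datasets)
    rejections: list[bool] = []
    n_failed = 0
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        chosen = rng.choice(exp_ids, size=config.n_experiments, replace=True)
        parts = []
        for k, eid in enumerate(chosen):
            g = by_exp[eid].copy()
            g["experiment_id"] = f"bs{k}"  # resampled copies are distinct groups
            parts.append(g)
        data = pd.concat(parts, ignore_index=True)
        data["clicks"] = simulate_clicks(data, spec, beta_vec, cov_re, rng)
        try:
            data_std, _ = standardize_features(data, spec.fixed_terms)
            fit = fit_glmm(spec, data_std)
        except (FitError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        p = fit.p_of(config.target)
        est = fit.coef(config.target)
        if config.effect == 0.0:
            reject = p < config.alpha
        else:
            reject = (p < config.alpha) and (np.sign(est) == np.sign(config.effect))
        rejections.append(bool(reject))

    n_used = len(rejections)
    power = float(np.mean(rejections)) if n_used else float("nan")
    mc_se = float(np.sqrt(power * (1.0 - power) / n_used)) if n_used else float("nan")
    return PowerResult(
        power=power,
        mc_se=mc_se,
        rejections=rejections,
        n_failed=n_failed,
        unreliable=n_failed > 0.1 * config.n_datasets,
        config=config,
    )
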