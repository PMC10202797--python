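"""Synthetic headline-RCT archives with known ground truth.

The generator emulates the statistical structure of a headline A/B testing
archive — a few headline variations per experiment, tens of thousands of
impressions per experiment, ~15-word headlines with controllable rates of
positive / negative / emotion / negation words, a baseline CTR around
1.4%, and experiment-level random intercepts (optionally varying slopes).
Headlines are token strings without grammar: linguistic realism is a
non-goal, the statistical structure is the contract.

Ground truth is defined on the standardized scale of the realized data:
features are computed from the generated headlines with the package's own
scoring functions, standardized within the generated archive, and the true
linear predictor is applied to those standardized values.  Parameter
recovery by the fitting machinery is therefore exact in expectation
without knowledge of population feature moments.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .archive import Archive, ArmRecord, Experiment
from .features import FeatureOptions, build_feature_table
from .glmm import Standardization, standardize_features
from .lexicon import BASIC_EMOTIONS, DEFAULT_NEGATIONS, Lexicon

__all__ = ["GeneratorConfig", "TruthRecord", "make_lexicon", "generate_archive"]

#: Default true standardized coefficients (per-SD log-odds effects).
DEFAULT_COEFFICIENTS = {
    "positive": -0.008,
    "negative": 0.015,
    "length": 0.04,
    "complexity": -0.004,
    "platform_age": -0.309,
}

_ARM_SUPPORT = np.arange(3, 13)


def _arm_probs(mean: float) -> np.ndarray:
    """Geometric-ratio categorical on 3..12 with the requested mean."""
    j = _ARM_SUPPORT - 3

    def gap(log_r):
        w = np.exp(log_r * j)
        return np.sum(_ARM_SUPPORT * w) / np.sum(w) - mean

    log_r = optimize.brentq(gap, -12.0, -1e-9)
    w = np.exp(log_r * j)
    return w / w.sum()


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic archive.

    Defaults emulate the real archive's printed structure: mean 4.31 arms
    per experiment (categorical on 3..12), ~16,670 impressions per
    experiment (lognormal, split about evenly across arms), Poisson
    headline lengths with mean 15 (min 3), and a baseline CTR of
    logistic(intercept) ≈ 1.4%.  Per-token insertion probabilities set
    how often each dictionary category appears; the remainder of tokens
    is neutral vocabulary.  The seed is mandatory.
    """

    seed: int
    n_experiments: int = 500
    arms_mean: float = 4.31
    arms_probs: np.ndarray | None = None  # overrides arms_mean if given
    impressions_mean: float = 16670.0
    impressions_sigma: float = 0.5  # lognormal shape (log-scale SD)
    length_mean: float = 15.0
    length_min: int = 3
    category_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "positive": 50, "negative": 50, "moral": 30,
            **{e: 40 for e in BASIC_EMOTIONS},
        }
    )
    neutral_vocab_size: int = 2000
    insertion_probs: dict[str, float] = field(
        default_factory=lambda: {
            "positive": 0.028, "negative": 0.026, "moral": 0.01,
            "negation": 0.02, **{e: 0.012 for e in BASIC_EMOTIONS},
        }
    )
    intercept: float = float(special.logit(0.014))
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    random_intercept_sd: float = 0.3
    slope_sds: dict[str, float] = field(default_factory=dict)  # e.g. {"negative": 0.1}
    slope_correlation: float = 0.0  # common intercept–slope / slope–slope correlation
    date_start: _dt.date = _dt.date(2013, 1, 24)
    date_end: _dt.date = _dt.date(2015, 4, 14)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.insertion_probs.values())
        if not 0.0 <= total < 1.0:
            raise ValueError("insertion probabilities must sum to < 1")
        if self.arms_probs is None:
            self.arms_probs = _arm_probs(self.arms_mean)

    @property
    def re_terms(self) -> list[str]:
        return ["(Intercept)"] + sorted(self.slope_sds)

    def re_covariance(self) -> np.ndarray:
        """Random-effect covariance implied by the SDs and correlation."""
        sds = np.array(
            [self.random_intercept_sd] + [self.slope_sds[t] for t in sorted(self.slope_sds)]
        )
        q = len(sds)
        corr = np.full((q, q), self.slope_correlation)
        np.fill_diagonal(corr, 1.0)
        return corr * np.outer(sds, sds)


@dataclass
class TruthRecord:
    """Everything needed to recompute every generated row's true CTR."""

    intercept: float
    coefficients: dict[str, float]
    re_terms: list[str]
    re_covariance: np.ndarray
    random_effects: dict[str, np.ndarray]  # experiment_id -> b_i
    standardization: Standardization
    theta: np.ndarray  # true per-row CTR, aligned with the feature table
    lexicon: Lexicon
    config: GeneratorConfig

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "re_terms": self.re_terms,
            "re_covariance": self.re_covariance.tolist(),
            "random_effects": {k: v.tolist() for k, v in self.random_effects.items()},
            "standardization": {
                "means": self.standardization.means,
                "sds": self.standardization.sds,
            },
            "theta": self.theta.tolist(),
        }


_SYLLABLES = [
    "ba", "bo", "bu", "da", "di", "do", "fa", "fi", "ga", "go", "ka", "ki",
    "la", "lo", "lu", "ma", "mi", "mo", "na", "ni", "nu", "pa", "po", "ra",
    "ri", "ro", "sa", "si", "so", "ta", "ti", "tu", "va", "vi", "za", "zo",
]


def _make_words(n: int, rng: np.random.Generator, taken: set[str]) -> list[str]:
    """Unique pronounceable nonsense words with 1–4 syllable units (so the
    readability index sees a realistic mix of simple and complex words)."""
    words: list[str] = []
    while len(words) < n:
        k = int(rng.integers(1, 5))
        w = "".join(rng.choice(_SYLLABLES, size=k))
        if w not in taken and w not in DEFAULT_NEGATIONS:
            taken.add(w)
            words.append(w)
    return words


def make_lexicon(config: GeneratorConfig, rng: np.random.Generator) -> Lexicon:
    """Pairwise-disjoint synthetic word lists plus the fixed negation list.

    Deterministic given the generator state.
    """
    taken: set[str] = set()
    cats = {
        name: frozenset(_make_words(size, rng, taken))
        for name, size in config.category_sizes.items()
    }
    return Lexicon(name="synthetic", categories=cats, negation_terms=DEFAULT_NEGATIONS)


def _neutral_vocab(config: GeneratorConfig, rng: np.random.Generator, lexicon: Lexicon) -> list[str]:
    taken = set().union(*lexicon.categories.values())
    return _make_words(config.neutral_vocab_size, rng, taken)


def _draw_headline(
    config: GeneratorConfig,
    rng: np.random.Generator,
    lexicon: Lexicon,
    neutral: list[str],
    cat_names: list[str],
    cat_probs: np.ndarray,
    cat_words: list[list[str]],
) -> str:
    length = max(config.length_min, int(rng.poisson(config.length_mean)))
    idx = rng.choice(len(cat_names), size=length, p=cat_probs)
    toks = [cat_words[i][rng.integers(len(cat_words[i]))] for i in idx]
    return " ".join(toks)


def generate_archive(config: GeneratorConfig, rng: np.random.Generator | None = None):
    """Generate one archive plus its ground truth.

    Returns ``(archive, truth)``.  The archive passes validation and
    survives filtering unchanged by construction (≥3 arms per experiment,
    distinct headlines within an experiment).  Clicks are drawn as
    Binomial(impressions, theta) with logit(theta) the true linear
    predictor on the standardized features.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lexicon = make_lexicon(config, rng)
    neutral = _neutral_vocab(config, rng, lexicon)

    cat_names = list(config.insertion_probs.keys()) + ["neutral"]
    cat_probs = np.array(
        [config.insertion_probs[c] for c in cat_names[:-1]]
        + [1.0 - sum(config.insertion_probs.values())]
    )
    cat_words = [
        sorted(DEFAULT_NEGATIONS) if c == "negation"
        else (neutral if c == "neutral" else sorted(lexicon.category(c)))
        for c in cat_names
    ]

    n_days = (config.date_end - config.date_start).days
    experiments: list[Experiment] = []
    for i in range(config.n_experiments):
        n_arms = int(rng.choice(_ARM_SUPPORT, p=config.arms_probs))
        total_impressions = max(
            n_arms, int(np.rint(rng.lognormal(
                np.log(config.impressions_mean) - 0.5 * config.impressions_sigma**2,
                config.impressions_sigma,
            )))
        )
        per_arm = rng.multinomial(total_impressions, np.full(n_arms, 1.0 / n_arms))
        per_arm = np.maximum(per_arm, 1)
        date = config.date_start + _dt.timedelta(days=int(rng.integers(0, n_days + 1)))
        headlines: list[str] = []
        while len(headlines) < n_arms:
            h = _draw_headline(config, rng, lexicon, neutral, cat_names, cat_probs, cat_words)
            if h not in headlines:
                headlines.append(h)
        arms = [
            ArmRecord(
                experiment_id=f"exp{i:05d}",
                headline_text=h,
                impressions=int(m),
                clicks=0,
                created_at=date,
            )
            for h, m in zip(headlines, per_arm)
        ]
        experiments.append(Experiment(f"exp{i:05d}", arms))

    archive = Archive(experiments=experiments)
    table = build_feature_table(archive, lexicon, FeatureOptions())
    frame = table.frame

    variables = list(config.coefficients.keys())
    try:
        frame_std, std = standardize_features(frame, variables)
    except ValueError as exc:
        raise ValueError(
            f"degenerate generator configuration ({exc}); raise the relevant "
            "insertion probability or vocabulary variability"
        ) from exc

    from .power import draw_random_effects

    cov = config.re_covariance()
    b = draw_random_effects(rng, cov, config.n_experiments)
    slope_vars = sorted(config.slope_sds)

    codes, exp_order = pd.factorize(frame_std["experiment_id"], sort=False)
    eta = config.intercept + b[codes, 0]
    for var in variables:
        eta = eta + config.coefficients[var] * frame_std[var].to_numpy()
    for k, var in enumerate(slope_vars, start=1):
        eta = eta + b[codes, k] * frame_std[var].to_numpy()
    theta = special.expit(eta)
    clicks = rng.binomial(frame_std["impressions"].to_numpy().astype(np.int64), theta)

    # rebuild the archive with the simulated clicks (row order matches the
    # feature table: experiments then arms, in generation order)
    row = 0
    final_experiments: list[Experiment] = []
    for exp in experiments:
        arms = []
        for arm in exp.arms:
            arms.append(
                ArmRecord(
                    experiment_id=arm.experiment_id,
                    headline_text=arm.headline_text,
                    impressions=arm.impressions,
                    clicks=int(clicks[row]),
                    created_at=arm.created_at,
                )
            )
            row += 1
        final_experiments.append(Experiment(exp.experiment_id, arms))

    truth = TruthRecord(
        intercept=config.intercept,
        coefficients=dict(config.coefficients),
        re_terms=config.re_terms,
        re_covariance=cov,
        random_effects={eid: b[k] for k, eid in enumerate(exp_order)},
        standardization=std,
        theta=theta,
        lexicon=lexicon,
        config=config,
    )
    return Archive(experiments=final_experiments), truth
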