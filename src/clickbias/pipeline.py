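"""End-to-end analysis: features → multilevel models → auxiliary tests.

``run_analysis`` reproduces the full table structure of a headline
negativity study on any archive: archive filtering and summary, the KS
comparison of positive vs negative word-proportion distributions, the
random-intercept model (Model 1), the varying-slopes model (Model 2),
their concordance, the discrete-emotion model on the emotion-defined
subset, and equivalence tests for non-significant emotion terms — plus
the pre-registered robustness toggles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .archive import Archive, ArchiveSummary, filter_archive, summarize_archive
from .features import FeatureOptions, FeatureTable, build_feature_table
from .glmm import (
    FitError,
    GlmmFit,
    ModelSpec,
    fit_glmm,
    model_concordance,
    standardize_features,
)
from .inference import DEFAULT_EQUIVALENCE_BOUNDS, EquivalenceResult, KsResult, ks_two_sample
from .lexicon import Lexicon

logger = logging.getLogger(__name__)

EMOTION_MODEL_TERMS = ["anger", "fear", "joy", "sadness"]
CONTROL_TERMS = ["length", "complexity", "platform_age"]


class PipelineConfigError(ValueError):
    """The analysis configuration is inconsistent with the inputs."""


@dataclass
class AnalysisConfig:
    """Analysis options; all robustness toggles off reproduces exactly the
    two pre-registered sentiment models plus the emotion model."""

    negation_scope: int = 3
    complexity_metric: str = "fog"
    exclusive_polarity: bool = False
    net_sentiment: bool = False
    quadratic: bool = False
    moral: bool = False
    topic_column: str | None = None
    alpha: float = 0.01  # significance threshold; also triggers equivalence tests
    ci_level: float = 0.99
    equivalence_bounds: tuple[float, float] = DEFAULT_EQUIVALENCE_BOUNDS
    fit_varying_slopes: bool = True
    fit_emotions: bool = True


@dataclass
class AnalysisReport:
    summary: ArchiveSummary
    ks: KsResult | None
    model1: GlmmFit | None
    model2: GlmmFit | None
    concordance: dict | None
    emotion_model: GlmmFit | None
    equivalence: dict[str, EquivalenceResult]
    features: FeatureTable
    audit: dict[str, int]
    failures: dict[str, str]
    config: AnalysisConfig

    def to_files(self, out_dir) -> None:
        """Write CSV tables (full precision) plus a human-readable summary."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.features.frame.to_csv(out / "features.csv", index=False)
        self.summary.to_frame().to_csv(out / "archive_summary.csv", index=False)
        pd.DataFrame(self.summary.ccdf_points, columns=["ctr", "survival"]).to_csv(
            out / "ctr_ccdf.csv", index=False
        )
        for name, fit in (
            ("model1_random_intercept", self.model1),
            ("model2_varying_slopes", self.model2),
            ("model3_emotions", self.emotion_model),
        ):
            if fit is not None:
                fit.summary_frame().to_csv(out / f"{name}.csv", index=False)
        (out / "summary.txt").write_text(self.render(), encoding="utf-8")

    def render(self, decimals: int = 3) -> str:
        """Human-readable rendering (rounding happens only here)."""
        lines = [str(self.summary), ""]
        if self.ks is not None:
            lines.append(
                f"KS test, positive vs negative proportions: "
                f"D = {self.ks.statistic:.3f}, p = {self.ks.p_value:.3g}"
            )
        for title, fit in (
            ("Model 1 (random intercepts)", self.model1),
            ("Model 2 (varying slopes)", self.model2),
            ("Emotion model (random intercepts)", self.emotion_model),
        ):
            if fit is None:
                continue
            lines += ["", title + ":"]
            tbl = fit.summary_frame()
            for _, r in tbl.iterrows():
                lines.append(
                    f"  {r['term']:<22s} {r['estimate']:+.{decimals}f} "
                    f"({r['ci_low']:+.{decimals}f}, {r['ci_high']:+.{decimals}f})  "
                    f"p = {r['p']:.3g}"
                )
        if self.concordance is not None:
            lines += ["", "Concordance: " + self.concordance["note"]]
        for term, eq in self.equivalence.items():
            lines.append(
                f"Equivalence ({term}): {eq.verdict} "
                f"(CI ({eq.ci[0]:+.4f}, {eq.ci[1]:+.4f}) vs bounds "
                f"({eq.bounds[0]:+.4f}, {eq.bounds[1]:+.4f}), TOST p = {eq.tost_p:.3f})"
            )
        if self.audit:
            lines += ["", "Row audit:"]
            for k, v in self.audit.items():
                lines.append(f"  {k}: {v}")
        for name, msg in self.failures.items():
            lines.append(f"FAILED: {name}: {msg}")
        return "\n".join(lines) + "\n"


def _sentiment_terms(config: AnalysisConfig) -> list[str]:
    return ["net_sentiment"] if config.net_sentiment else ["positive", "negative"]


def _topic_design(frame: pd.DataFrame, topic_col: str, sentiment_terms: list[str]):
    """Dummy-code topics (most frequent topic as reference level) and name
    the topic×sentiment interaction pairs."""
    counts = frame[topic_col].value_counts()
    reference = counts.index[0]
    dummy_cols = []
    for label in counts.index[1:]:
        col = f"topic_{label}"
        frame[col] = (frame[topic_col] == label).astype(float)
        dummy_cols.append(col)
    interactions = [(t, d) for d in dummy_cols for t in sentiment_terms]
    return frame, dummy_cols, interactions, reference


def run_analysis(
    archive: Archive,
    lexicon: Lexicon,
    config: AnalysisConfig | None = None,
    topic_table: pd.DataFrame | None = None,
) -> AnalysisReport:
    """Execute the full analysis on one archive.

    ``topic_table`` supplies externally produced topic labels (columns:
    ``experiment_id``, ``headline``, and the configured topic column);
    topic labels are consumed, never inferred.  Unfittable models leave a
    partial report with the failure recorded.  Deterministic given
    archive, lexicon and configuration.
    """
    config = config or AnalysisConfig()
    filtered = filter_archive(archive)
    if not filtered.experiments:
        raise PipelineConfigError(
            "no experiments with >= 2 distinct arms remain after filtering"
        )
    summary = summarize_archive(filtered)

    table = build_feature_table(
        filtered,
        lexicon,
        FeatureOptions(
            negation_scope=config.negation_scope,
            complexity_metric=config.complexity_metric,
            exclusive_polarity=config.exclusive_polarity,
        ),
    )
    frame = table.frame.copy()
    audit = {
        "arms_in_archive": archive.n_arms,
        "arms_merged_away": filtered.n_merged_arms,
        "arms_in_single_arm_experiments": archive.n_arms
        - filtered.n_arms
        - filtered.n_merged_arms,
        "rows_analyzed": len(frame),
        **{f"rows_excluded_{k}": v for k, v in table.exclusions.items()},
    }

    if config.topic_column is not None:
        if topic_table is None or config.topic_column not in topic_table.columns:
            raise PipelineConfigError(
                f"topic option requires a topic table with column "
                f"{config.topic_column!r}"
            )
        frame = frame.merge(
            topic_table[["experiment_id", "headline", config.topic_column]],
            on=["experiment_id", "headline"],
            how="left",
        )
        if frame[config.topic_column].isna().any():
            raise PipelineConfigError("topic table does not cover every analyzed headline")

    sentiment = _sentiment_terms(config)
    failures: dict[str, str] = {}

    ks = None
    if not config.net_sentiment:
        ks = ks_two_sample(frame["positive"], frame["negative"])

    std_vars = sentiment + CONTROL_TERMS + (["moral"] if config.moral else [])
    try:
        frame_std, standardization = standardize_features(frame, std_vars)
    except ValueError as exc:
        raise PipelineConfigError(str(exc)) from exc

    fixed = list(std_vars)
    interactions: list[tuple[str, str]] = []
    if config.moral:
        interactions += [("moral", t) for t in sentiment]
    if config.topic_column is not None:
        frame_std, dummy_cols, topic_inter, reference = _topic_design(
            frame_std, config.topic_column, sentiment
        )
        fixed += dummy_cols
        interactions += topic_inter
        audit["topic_reference_level"] = reference
    squared = list(sentiment) if config.quadratic else []

    spec1 = ModelSpec(fixed_terms=fixed, interactions=interactions, squared_terms=squared)
    model1 = None
    try:
        model1 = fit_glmm(
            spec1, frame_std, ci_level=config.ci_level, standardization=standardization
        )
    except (FitError, ValueError) as exc:
        failures["model1"] = str(exc)

    model2 = None
    if config.fit_varying_slopes:
        spec2 = ModelSpec(
            fixed_terms=fixed,
            interactions=interactions,
            squared_terms=squared,
            random_slopes=sentiment,
        )
        try:
            model2 = fit_glmm(
                spec2, frame_std, ci_level=config.ci_level, standardization=standardization
            )
        except (FitError, ValueError) as exc:
            failures["model2"] = str(exc)
            if "convergence" in str(exc) and spec2.covariance_structure == "full":
                # diagonal fallback when the full covariance cannot be estimated
                spec2.covariance_structure = "diagonal"
                try:
                    model2 = fit_glmm(
                        spec2, frame_std,
                        ci_level=config.ci_level, standardization=standardization,
                    )
                    failures.pop("model2")
                except (FitError, ValueError) as exc2:
                    failures["model2"] = str(exc2)

    concordance = None
    if model1 is not None and model2 is not None:
        concordance = model_concordance(model1, model2, sentiment, alpha=config.alpha)

    emotion_model = None
    equivalence: dict[str, EquivalenceResult] = {}
    if config.fit_emotions:
        emo_frame = frame[frame["emotion_defined"]].copy()
        audit["rows_excluded_no_emotion_words"] = len(frame) - len(emo_frame)
        audit["rows_emotion_model"] = len(emo_frame)
        try:
            emo_std, emo_standardization = standardize_features(
                emo_frame, EMOTION_MODEL_TERMS + CONTROL_TERMS
            )
            emotion_model = fit_glmm(
                ModelSpec(fixed_terms=EMOTION_MODEL_TERMS + CONTROL_TERMS),
                emo_std,
                ci_level=config.ci_level,
                standardization=emo_standardization,
            )
        except (FitError, ValueError) as exc:
            failures["emotion_model"] = str(exc)
        if emotion_model is not None:
            from .inference import equivalence_test

            for term in EMOTION_MODEL_TERMS:
                if emotion_model.p_of(term) >= config.alpha:
                    equivalence[term] = equivalence_test(
                        emotion_model.coef(term),
                        emotion_model.se_of(term),
                        bounds=config.equivalence_bounds,
                        level=config.ci_level,
                    )

    return AnalysisReport(
        summary=summary,
        ks=ks,
        model1=model1,
        model2=model2,
        concordance=concordance,
        emotion_model=emotion_model,
        equivalence=equivalence,
        features=table,
        audit=audit,
        failures=failures,
        config=config,
    )
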