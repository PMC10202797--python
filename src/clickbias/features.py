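"""Per-headline covariates: sentiment, emotions, length, readability.

The scoring is a unigram dictionary approach with forward negation
handling.  Polarity scores are proportions of the headline's tokens that
fall in the positive / negative word lists after negation inversion;
emotion profiles are proportions over emotion-dictionary tokens only,
normalized to sum to one across the 8 basic emotions.  These quantify the
presence of words, not readers' felt emotion.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .archive import Archive, platform_age_days
from .lexicon import BASIC_EMOTIONS, Lexicon

logger = logging.getLogger(__name__)

_APOSTROPHES = str.maketrans({"’": "'", "ʼ": "'"})
# keep letters, digits and apostrophes; everything else (punctuation, '#',
# symbols) is stripped from tokens
_STRIP_RE = re.compile(r"[^\w']+", flags=re.UNICODE)
_SENTENCE_SPLIT_RE = re.compile(r"[.!?]+")


@dataclass(frozen=True)
class TokenizedHeadline:
    raw_text: str
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class SentimentScore:
    """Positive / negative word proportions of one headline.

    ``positive`` = n_positive / n_total and ``negative`` = n_negative /
    n_total where n_total is the headline's token count and the polarity
    counts are taken after negation inversion.
    """

    positive: float
    negative: float
    n_total: int


@dataclass(frozen=True)
class EmotionProfile:
    """Normalized 8-emotion word-proportion vector.

    ``defined`` is False when the headline contains no emotion-dictionary
    token outside a negation scope (the normalizing denominator would be
    zero); such rows are excluded from the emotion regression.
    """

    weights: dict[str, float]
    defined: bool

    def __getitem__(self, emotion: str) -> float:
        return self.weights[emotion]


def _clean_token(tok: str) -> str:
    tok = _STRIP_RE.sub("", tok.translate(_APOSTROPHES))
    return tok.replace("_", "").strip("'")


def preprocess(text: str) -> TokenizedHeadline:
    """Lowercase, whitespace-tokenize, and strip special characters.

    Punctuation and hashtag characters are removed from tokens; tokens
    emptied by stripping are dropped.  Internal apostrophes are kept so
    contracted negations (``don't``) survive as single tokens.
    """
    tokens = tuple(t for t in (_clean_token(w) for w in text.lower().split()) if t)
    return TokenizedHeadline(raw_text=text, tokens=tokens)


def negation_scope_mask(tokens, lexicon: Lexicon, scope: int = 3) -> list[bool]:
    """Flag tokens governed by a preceding in-scope negation term.

    A negation term puts the next *scope* tokens in its scope.  A token in
    the scope of one or more negations is flagged once (the nearest
    preceding negation governs; flips never stack).  With scope 0 this is
    the identity (no token flagged).
    """
    if scope < 0:
        raise ValueError("negation scope must be >= 0")
    flagged = [False] * len(tokens)
    remaining = 0
    for i, tok in enumerate(tokens):
        if remaining > 0:
            flagged[i] = True
            remaining -= 1
        if tok in lexicon.negation_terms:
            remaining = scope
    return flagged


def apply_negation(tokens, lexicon: Lexicon, scope: int = 3) -> list[str | None]:
    """Per-token polarity assignment after negation inversion.

    Returns one label per token: ``"positive"`` / ``"negative"`` for
    polarity-dictionary tokens (inverted when inside a negation scope, so
    'not happy' codes as negative), ``"skipped"`` for emotion-dictionary
    tokens inside a scope (there is no opposite emotion to flip to), and
    None for all other tokens.
    """
    flagged = negation_scope_mask(tokens, lexicon, scope)
    emotion_words = set().union(*lexicon.emotion_categories().values())
    labels: list[str | None] = []
    for tok, inside in zip(tokens, flagged):
        pos, neg = tok in lexicon.positive, tok in lexicon.negative
        if pos and neg:
            labels.append("both")  # counted in both categories either way
        elif pos:
            labels.append("negative" if inside else "positive")
        elif neg:
            labels.append("positive" if inside else "negative")
        elif inside and tok in emotion_words:
            labels.append("skipped")
        else:
            labels.append(None)
    return labels


def sentiment_scores(tokens, lexicon: Lexicon, scope: int = 3) -> SentimentScore | None:
    """Positive / negative proportions with negation handling.

    Returns None (undefined score) for an empty token list.  A token in
    both polarity lists counts once in each category.
    """
    if not tokens:
        return None
    labels = apply_negation(tokens, lexicon, scope)
    n_pos = sum(1 for lab in labels if lab in ("positive", "both"))
    n_neg = sum(1 for lab in labels if lab in ("negative", "both"))
    n_total = len(tokens)
    return SentimentScore(positive=n_pos / n_total, negative=n_neg / n_total, n_total=n_total)


def emotion_profile(tokens, lexicon: Lexicon, scope: int = 3) -> EmotionProfile:
    """Normalized basic-emotion profile of a headline.

    Counts tokens per emotion category, skipping tokens inside a negation
    scope, then divides by the total number of emotion-category hits so
    the vector sums to exactly one.  A token tagged with several emotions
    contributes once per emotion (to the numerators and the denominator).
    With no emotion hits the profile is undefined.
    """
    flagged = negation_scope_mask(tokens, lexicon, scope)
    cats = lexicon.emotion_categories()
    counts = {e: 0 for e in BASIC_EMOTIONS}
    for tok, inside in zip(tokens, flagged):
        if inside:
            continue
        for emo, words in cats.items():
            if tok in words:
                counts[emo] += 1
    denom = sum(counts.values())
    if denom == 0:
        return EmotionProfile(weights={e: 0.0 for e in BASIC_EMOTIONS}, defined=False)
    return EmotionProfile(
        weights={e: c / denom for e, c in counts.items()}, defined=True
    )


def moral_proportion(tokens, lexicon: Lexicon) -> float | None:
    """Fraction of tokens in the moral word list (no negation inversion:
    a negated moral word is still moralized language)."""
    if not tokens:
        return None
    moral = lexicon.category("moral")
    return sum(1 for t in tokens if t in moral) / len(tokens)


_VOWELS = set("aeiouy")


def count_syllables(word: str) -> int:
    """Deterministic syllable heuristic for readability indices.

    Counts maximal vowel groups (a, e, i, o, u, y), subtracts one for a
    terminal silent 'e' unless that would leave zero, floor of 1.  The
    rules are frozen: readability values are defined relative to this
    heuristic, not to any phonetic ground truth.
    """
    w = "".join(c for c in word.lower() if c.isalpha())
    if not w:
        return 1
    groups = len(re.findall(r"[aeiouy]+", w))
    if w.endswith("e") and groups > 1:
        groups -= 1  # terminal silent 'e', unless it is the only group
    return max(groups, 1)


def _sentences(text: str) -> list[tuple[str, ...]]:
    parts = _SENTENCE_SPLIT_RE.split(text)
    sents = [preprocess(p).tokens for p in parts]
    return [s for s in sents if s]


def gunning_fog(text: str) -> float | None:
    """Gunning Fog readability index: 0.4 × (ASL + 100 × n_wsy≥3 / n_w).

    ASL is the average sentence length in words; sentences split on
    terminal punctuation (. ! ?) before token stripping, and a headline
    with no terminal punctuation counts as one sentence.  Complex words
    are tokens with ≥ 3 syllables (no exclusions).  Undefined (None) for
    a text with no words.
    """
    sents = _sentences(text)
    n_words = sum(len(s) for s in sents)
    if n_words == 0:
        return None
    asl = n_words / len(sents)
    n_complex = sum(1 for s in sents for tok in s if count_syllables(tok) >= 3)
    return 0.4 * (asl + 100.0 * n_complex / n_words)


def flesch_kincaid_grade(text: str) -> float | None:
    """Alternative complexity metric: Flesch–Kincaid grade level,
    0.39 × ASL + 11.8 × syllables-per-word − 15.59 (same sentence and
    syllable rules as the Fog index)."""
    sents = _sentences(text)
    n_words = sum(len(s) for s in sents)
    if n_words == 0:
        return None
    asl = n_words / len(sents)
    spw = sum(count_syllables(tok) for s in sents for tok in s) / n_words
    return 0.39 * asl + 11.8 * spw - 15.59


def net_sentiment(score: SentimentScore | None) -> float | None:
    """Single net score: positive proportion minus negative proportion."""
    if score is None:
        return None
    return score.positive - score.negative


COMPLEXITY_METRICS = {"fog": gunning_fog, "flesch_kincaid": flesch_kincaid_grade}


@dataclass
class FeatureOptions:
    """Options for feature-table construction (robustness toggles)."""

    negation_scope: int = 3
    complexity_metric: str = "fog"
    exclusive_polarity: bool = False  # drop rows with both positive>0 and negative>0


@dataclass
class FeatureTable:
    """Assembled per-headline covariate rows plus an exclusion audit."""

    frame: pd.DataFrame
    exclusions: dict[str, int] = field(default_factory=dict)
    options: FeatureOptions = field(default_factory=FeatureOptions)


def build_feature_table(
    archive: Archive, lexicon: Lexicon, options: FeatureOptions | None = None
) -> FeatureTable:
    """One covariate row per arm of a (filtered) archive.

    Columns: experiment_id, headline, clicks, impressions, positive,
    negative, net_sentiment, the 8 emotion weights, emotion_defined,
    moral, length, complexity, platform_age.  Rows whose emotion profile
    is undefined are kept but flagged so the emotion model can drop them;
    rows removed by the exclusive-polarity filter are counted in the
    audit trail.
    """
    opts = options or FeatureOptions()
    if opts.complexity_metric not in COMPLEXITY_METRICS:
        raise ValueError(
            f"unknown complexity metric {opts.complexity_metric!r}; "
            f"choose from {sorted(COMPLEXITY_METRICS)}"
        )
    complexity_fn = COMPLEXITY_METRICS[opts.complexity_metric]
    epoch = archive.platform_epoch

    rows = []
    n_empty = 0
    n_both = 0
    for exp in archive.experiments:
        age = platform_age_days(exp, epoch)
        for arm in exp.arms:
            toks = preprocess(arm.headline_text).tokens
            senti = sentiment_scores(toks, lexicon, opts.negation_scope)
            if senti is None:
                n_empty += 1
                continue
            if opts.exclusive_polarity and senti.positive > 0 and senti.negative > 0:
                n_both += 1
                continue
            profile = emotion_profile(toks, lexicon, opts.negation_scope)
            row = {
                "experiment_id": exp.experiment_id,
                "headline": arm.headline_text,
                "clicks": arm.clicks,
                "impressions": arm.impressions,
                "positive": senti.positive,
                "negative": senti.negative,
                "net_sentiment": senti.positive - senti.negative,
                "moral": moral_proportion(toks, lexicon),
                "length": senti.n_total,
                "complexity": complexity_fn(arm.headline_text),
                "platform_age": age,
                "emotion_defined": profile.defined,
            }
            row.update({e: profile.weights[e] for e in BASIC_EMOTIONS})
            rows.append(row)

    exclusions = {"empty_headline": n_empty, "exclusive_polarity": n_both}
    for reason, n in exclusions.items():
        if n:
            logger.info("feature table: excluded %d rows (%s)", n, reason)
    return FeatureTable(frame=pd.DataFrame(rows), exclusions=exclusions, options=opts)
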