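"""Word-list lexicons for dictionary-based sentiment and emotion scoring.

A :class:`Lexicon` bundles named categories of lowercase word forms
(positive, negative, the 8 basic emotions, moral) together with a list of
negation terms.  Matching is exact unigram membership — no stemming or
lemmatization — which is the standard dictionary approach for short texts
such as headlines.

The package ships only small synthetic/demo lists; any user-supplied lists
in the same plain formats are accepted (the proprietary LIWC and
SentiStrength dictionaries are deliberately not bundled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

#: Plutchik's 8 basic emotions, in canonical order.
BASIC_EMOTIONS = (
    "anger",
    "anticipation",
    "disgust",
    "fear",
    "joy",
    "sadness",
    "surprise",
    "trust",
)

#: Default negation terms (user-overridable).
DEFAULT_NEGATIONS = frozenset(
    {
        "not", "no", "never", "none", "nobody", "nothing", "neither",
        "nor", "cannot", "can't", "don't", "doesn't", "didn't", "won't",
        "wouldn't", "shouldn't", "couldn't", "isn't", "aren't", "wasn't",
        "weren't", "hasn't", "haven't", "hadn't", "ain't", "without",
    }
)


class LexiconError(ValueError):
    """A word list violates a lexicon invariant."""


def _check_words(name: str, words) -> frozenset[str]:
    out = frozenset(words)
    for w in out:
        if not w or w != w.lower() or any(c.isspace() for c in w):
            raise LexiconError(
                f"category {name!r}: entry {w!r} must be lowercase, "
                "non-empty, and contain no whitespace"
            )
    return out


@dataclass(frozen=True)
class Lexicon:
    """Named word lists plus negation terms.

    Invariants enforced at construction: all entries lowercase with no
    internal whitespace, and negation terms disjoint from the positive and
    negative categories (a word cannot be both a polarity cue and its own
    negator).
    """

    name: str
    categories: dict[str, frozenset[str]] = field(default_factory=dict)
    negation_terms: frozenset[str] = DEFAULT_NEGATIONS

    def __post_init__(self) -> None:
        clean = {k: _check_words(k, v) for k, v in self.categories.items()}
        object.__setattr__(self, "categories", clean)
        object.__setattr__(
            self, "negation_terms", _check_words("negation", self.negation_terms)
        )
        for pol in ("positive", "negative"):
            overlap = self.categories.get(pol, frozenset()) & self.negation_terms
            if overlap:
                raise LexiconError(
                    f"negation terms overlap the {pol} category: {sorted(overlap)}"
                )

    def category(self, name: str) -> frozenset[str]:
        return self.categories.get(name, frozenset())

    @property
    def positive(self) -> frozenset[str]:
        return self.category("positive")

    @property
    def negative(self) -> frozenset[str]:
        return self.category("negative")

    def emotion_categories(self) -> dict[str, frozenset[str]]:
        return {e: self.category(e) for e in BASIC_EMOTIONS}


def load_wordlist(path) -> frozenset[str]:
    """Read a plain word list: one word per line, UTF-8, '#' comments."""
    words = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            words.append(line.lower())
    return frozenset(words)


def load_nrc_table(path, include_polarity: bool = False) -> dict[str, frozenset[str]]:
    """Read an NRC-style emotion association table.

    Format: three tab-separated columns per line — word, category, 0/1
    flag — as publicly distributed.  Rows with flag 0 are ignored.  The 8
    basic-emotion categories are always returned; ``positive``/``negative``
    rows are included only when *include_polarity* is set.
    """
    wanted = set(BASIC_EMOTIONS) | ({"positive", "negative"} if include_polarity else set())
    cats: dict[str, set[str]] = {c: set() for c in wanted}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise LexiconError(f"{path}: line {lineno} is not 3 tab-separated fields")
        word, cat, flag = parts[0].strip().lower(), parts[1].strip().lower(), parts[2].strip()
        if flag not in {"0", "1"}:
            raise LexiconError(f"{path}: line {lineno} flag must be 0 or 1, got {flag!r}")
        if flag == "1" and cat in cats:
            cats[cat].add(word)
    return {c: frozenset(v) for c, v in cats.items()}


def build_lexicon(
    name: str = "user",
    positive=None,
    negative=None,
    moral=None,
    nrc_path=None,
    negation_path=None,
    emotion_categories: dict | None = None,
) -> Lexicon:
    """Assemble a lexicon from word-list files and/or an NRC table."""
    cats: dict[str, frozenset[str]] = {}
    for label, src in (("positive", positive), ("negative", negative), ("moral", moral)):
        if src is not None:
            cats[label] = load_wordlist(src) if not isinstance(src, (set, frozenset)) else frozenset(src)
    if nrc_path is not None:
        cats.update(load_nrc_table(nrc_path))
    if emotion_categories:
        cats.update({k: frozenset(v) for k, v in emotion_categories.items()})
    negations = load_wordlist(negation_path) if negation_path else DEFAULT_NEGATIONS
    return Lexicon(name=name, categories=cats, negation_terms=negations)


def demo_lexicon() -> Lexicon:
    """The small open demo lexicon bundled with the package.

    Meant for tests and examples only — a real analysis should supply a
    full-coverage dictionary in the same formats.
    """
    root = resources.files("clickbias") / "data"
    with resources.as_file(root) as data_dir:
        return build_lexicon(
            name="demo",
            positive=data_dir / "demo_positive.txt",
            negative=data_dir / "demo_negative.txt",
            moral=data_dir / "demo_moral.txt",
            nrc_path=data_dir / "demo_emotions.tsv",
        )
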