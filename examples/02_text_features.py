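"""Score headlines with the dictionary sentiment/emotion pipeline.

Each headline gets: positive/negative word proportions (with negation
handling — 'not happy' counts as negative), a normalized profile over the
8 basic emotions, word count, and Gunning Fog readability.
"""

from clickbias import (
    demo_lexicon,
    emotion_profile,
    gunning_fog,
    preprocess,
    sentiment_scores,
)

lexicon = demo_lexicon()

headlines = [
    "WOW: This Beautiful Story Will Make You Happy",
    "Everything You Know Is Wrong, And That's Not Happy News",
    "Rage And Terror Strike Twice In One Awful Week",
    "A Plain Headline With No Dictionary Words At All",
]

for text in headlines:
    tokens = preprocess(text).tokens
    s = sentiment_scores(tokens, lexicon)
    profile = emotion_profile(tokens, lexicon)
    fog = gunning_fog(text)
    emotions = (
        ", ".join(f"{e} {w:.0%}" for e, w in profile.weights.items() if w > 0)
        if profile.defined
        else "undefined (no emotion words)"
    )
    print(f"\n{text}")
    print(f"  tokens ({s.n_total}): {' '.join(tokens)}")
    print(f"  positive {s.positive:.1%}  negative {s.negative:.1%}  fog {fog:.1f}")
    print(f"  emotions: {emotions}")

# Proportions are fractions of all words; emotion weights are fractions of
# emotion-dictionary words only and sum to one when defined.
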