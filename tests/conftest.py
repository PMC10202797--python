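"""Shared fixtures: toy archives and small seeded synthetic datasets."""

import datetime as dt

import pytest

from clickbias.archive import Archive, ArmRecord, Experiment
from clickbias.lexicon import demo_lexicon
from clickbias.synth import GeneratorConfig, generate_archive

D0 = dt.date(2013, 1, 24)


def arm(exp="e1", text="a headline", imp=1000, clicks=10, date=D0):
    return ArmRecord(
        experiment_id=exp, headline_text=text, impressions=imp, clicks=clicks,
        created_at=date,
    )


def toy_archive(spec):
    """Build an archive from {exp_id: [(text, impressions, clicks), ...]}."""
    experiments = [
        Experiment(eid, [arm(eid, t, n, c) for (t, n, c) in arms])
        for eid, arms in spec.items()
    ]
    return Archive(experiments=experiments)


@pytest.fixture(scope="session")
def demo_lex():
    return demo_lexicon()


@pytest.fixture(scope="session")
def small_synth():
    """A 120-experiment synthetic archive with its ground truth."""
    config = GeneratorConfig(seed=20210, n_experiments=120)
    archive, truth = generate_archive(config)
    return archive, truth
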