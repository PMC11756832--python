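import numpy as np
import pytest

from frailvoice import pipeline as pl
from frailvoice import cohort as ch
from frailvoice import features as ft


@pytest.fixture(scope="session")
def strong_cohort():
    """n=200 balanced cohort with frame features and functionals.

    Short (3 s) clips keep the session affordable; the severity gradient is the
    generator default, which separates classes acoustically.
    """
    cfg = pl.RunConfig(
        n=200, positive_prevalence=0.5, clip_duration=3.0, seed=424242
    )
    dataset, participants = pl.build_dataset(cfg, with_functionals=True)
    return cfg, dataset, participants


@pytest.fixture(scope="session")
def tiny_dataset():
    """n=24 cohort with frame features only; for fast training-path tests."""
    cfg = pl.RunConfig(
        n=24, positive_prevalence=0.5, clip_duration=2.0,
        ssl_corpus_size=8, ssl_epochs=2, seed=777,
    )
    dataset, participants = pl.build_dataset(cfg, with_functionals=False)
    return cfg, dataset, participants


@pytest.fixture()
def short_clip():
    """One 2-second synthetic clip (score 0, male)."""
    p = ch.Participant(
        id="P0", age=65, sex="male", kfrail_items=(0, 0, 0, 0, 0),
        kfrail_score=0, category="robust", label=0,
    )
    return ch.synthesize_speech(p, ch.AudioClassParams(duration=2.0), seed=9)
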