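import numpy as np
import pytest

from pragmalang.lexicon import load_example_lexicon
from pragmalang.simulate import default_config, generate_cohort
from pragmalang.transcripts import Task


@pytest.fixture(scope="session")
def example_lexicon():
    return load_example_lexicon()


@pytest.fixture(scope="session")
def narrative_cohort():
    """Small narrative cohort, 5 transcripts per group."""
    cfg = default_config(Task.NARRATIVE, n_per_group=5, seed=11)
    return generate_cohort(cfg, Task.NARRATIVE)


@pytest.fixture(scope="session")
def conversation_cohort():
    """Small conversation cohort, 5 transcripts per group."""
    cfg = default_config(Task.CONVERSATION, n_per_group=5, seed=13)
    return generate_cohort(cfg, Task.CONVERSATION)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_transcript(task, tags, id="t0", diagnosis="asd", sex="male", words=None):
    """Micro-transcript from (speaker, act) pairs or bare participant tags."""
    from pragmalang.transcripts import Speaker, Token, Transcript, Utterance

    utts = []
    for i, spec in enumerate(tags):
        if isinstance(spec, tuple):
            speaker, act = spec
            speaker = Speaker(speaker)
        else:
            speaker, act = Speaker.PARTICIPANT, spec
        text = (words or ["word"])
        toks = [Token(surface=w, normalized=w) for w in text]
        utts.append(Utterance(index=i, speaker=speaker, act=act, tokens=toks))
    return Transcript(
        id=id,
        task=Task(task),
        diagnosis=diagnosis,
        sex=sex,
        covariates={"viq": 100.0, "age": 12.0},
        utterances=utts,
    )
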