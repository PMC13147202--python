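"""Synthetic cohorts with planted group structure.

Everything downstream — sequence statistics, Markov-chain divergence,
lexicon percents, LPA, the stats harness — is exercised on cohorts produced
here, since the study design this emulates (four groups: autistic /
non-autistic x male / female; picture-book narrative and semi-structured
conversation tasks) has no public transcripts.

Each group is parameterized by a first-order Markov chain over speech-act
states (speaker-aware for conversation), utterance-length means, per-token
lexical emission rates for the example word categories, maze and
filled-pause injection rates, and covariate (VIQ, age) distributions. The
shipped defaults plant the study's headline effect directions:

* autistic groups carry less backchannel transition mass after examiner
  non-questions (0.15 vs 0.35);
* female groups emit complex-affect words at twice the male per-token rate
  (0.020 vs 0.010) and carry more participant-to-participant
  (self-elaboration) mass;
* VIQ differs by diagnosis (mean 105 vs 112, SD 13), so the covariate is
  non-trivial;
* narrative lengths match the observed scale (about 50 participant
  utterances of about 8 tokens, i.e. roughly 400 words).

Per-transcript randomness is split from the master seed with
``numpy.random.SeedSequence(seed).spawn``, so cohorts are reproducible and
order-independent across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .lexicon import Lexicon, load_example_lexicon
from .markov import MarkovChain, chain_states, kl_rate
from .transcripts import (
    DEFAULT_FILLED_PAUSES,
    Speaker,
    Task,
    Token,
    Transcript,
    Utterance,
)

__all__ = [
    "GroupParams",
    "SyntheticConfig",
    "GROUPS",
    "STUDY_GROUP_SIZES",
    "background_vocabulary",
    "default_group_params",
    "default_config",
    "generate_transcript",
    "generate_cohort",
    "generate_profile_data",
    "true_kl",
]

GROUPS = (
    ("asd", "male"),
    ("asd", "female"),
    ("non_asd", "male"),
    ("non_asd", "female"),
)

#: The emulated study's cell sizes (autistic M/F, non-autistic M/F).
STUDY_GROUP_SIZES = {
    ("asd", "male"): 73,
    ("asd", "female"): 27,
    ("non_asd", "male"): 40,
    ("non_asd", "female"): 47,
}


@dataclass
class GroupParams:
    transition: np.ndarray  # row-stochastic over chain_states(task)
    states: list[str]
    n_utterances: float = 50.0  # Poisson mean (participant turns; total for conversation)
    utterance_length: float = 7.0  # mean extra tokens (length = 1 + Poisson)
    examiner_length: float = 5.0
    lexical_rates: dict[str, float] = field(default_factory=dict)
    maze_rate: float = 0.06
    filled_pause_rate: float = 0.04
    viq_mean: float = 110.0
    viq_sd: float = 13.0
    age_mean: float = 13.0
    age_sd: float = 2.5
    profile_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        T = np.asarray(self.transition, dtype=float)
        if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must be non-negative and sum to 1")
        total = sum(self.lexical_rates.values())
        for p in (*self.lexical_rates.values(), self.maze_rate, self.filled_pause_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if total >= 1.0:
            raise ValueError("lexical emission rates must leave background mass")
        self.transition = T


@dataclass
class SyntheticConfig:
    groups: Mapping[tuple[str, str], GroupParams]
    n_per_group: int | Mapping[tuple[str, str], int] = 30
    seed: int = 0

    def size(self, group: tuple[str, str]) -> int:
        if isinstance(self.n_per_group, Mapping):
            return self.n_per_group[group]
        return int(self.n_per_group)


def background_vocabulary(n: int = 500) -> list[str]:
    """Deterministic neutral pseudo-word list, guaranteed not to match the
    example lexicon or the filled-pause list."""
    rng = np.random.default_rng(987654321)  # fixed: the vocabulary is a constant
    onsets = ["b", "d", "f", "g", "k", "l", "m", "n", "p", "r", "s", "t", "v", "z"]
    vowels = ["a", "e", "i", "o", "u"]
    lex = load_example_lexicon()
    from .lexicon import match_token

    words: list[str] = []
    seen = set(DEFAULT_FILLED_PAUSES)
    while len(words) < n:
        k = rng.integers(2, 4)
        w = "".join(
            onsets[rng.integers(len(onsets))] + vowels[rng.integers(len(vowels))]
            for _ in range(k)
        )
        if w in seen or match_token(lex, w):
            continue
        seen.add(w)
        words.append(w)
    return words


def _row(states: Sequence[str], masses: Mapping[str, float]) -> np.ndarray:
    row = np.zeros(len(states))
    for tag, p in masses.items():
        row[states.index(tag)] = p
    s = row.sum()
    if not np.isclose(s, 1.0, atol=1e-9):
        raise ValueError(f"row masses sum to {s}, expected 1: {masses}")
    return row


def _narrative_transition(diagnosis: str) -> tuple[np.ndarray, list[str]]:
    states = chain_states(Task.NARRATIVE)
    asd = diagnosis == "asd"
    nn, th = (0.07, 0.04) if asd else (0.04, 0.02)
    rows = {
        "START": {"statement": 0.95, "nonnarrative": 0.05},
        "statement": {
            "statement": 0.84 - nn - th,
            "question": 0.03,
            "character_speech": 0.05,
            "sound_effect": 0.04,
            "nonnarrative": nn,
            "thinking": th,
            "incomplete": 0.04,
        },
        "question": {
            "statement": 0.80,
            "question": 0.05,
            "nonnarrative": 0.05,
            "character_speech": 0.04,
            "sound_effect": 0.02,
            "thinking": 0.02,
            "incomplete": 0.02,
        },
        "character_speech": {
            "statement": 0.43,
            "character_speech": 0.30,
            "sound_effect": 0.15,
            "question": 0.02,
            "nonnarrative": 0.04,
            "thinking": 0.02,
            "incomplete": 0.04,
        },
        "sound_effect": {
            "statement": 0.53,
            "sound_effect": 0.20,
            "character_speech": 0.12,
            "question": 0.02,
            "nonnarrative": 0.05,
            "thinking": 0.03,
            "incomplete": 0.05,
        },
        "nonnarrative": {
            "statement": 0.55,
            "nonnarrative": 0.25,
            "thinking": 0.05,
            "question": 0.05,
            "character_speech": 0.02,
            "sound_effect": 0.02,
            "incomplete": 0.06,
        },
        "thinking": {
            "statement": 0.58,
            "thinking": 0.15,
            "nonnarrative": 0.12,
            "question": 0.04,
            "character_speech": 0.02,
            "sound_effect": 0.02,
            "incomplete": 0.07,
        },
        "incomplete": {
            "statement": 0.70,
            "incomplete": 0.10,
            "nonnarrative": 0.08,
            "question": 0.04,
            "character_speech": 0.03,
            "sound_effect": 0.03,
            "thinking": 0.02,
        },
    }
    T = np.array([_row(states, rows[s]) for s in states])
    return T, states


def _conversation_transition(diagnosis: str, sex: str) -> tuple[np.ndarray, list[str]]:
    states = chain_states(Task.CONVERSATION)
    backchannel_mass = 0.15 if diagnosis == "asd" else 0.35
    self_elab = 0.45 if sex == "female" else 0.35
    # participant row: self-elaboration mass split over participant tags,
    # remainder handed to the examiner
    part_split = {
        "initiation_statement": 0.24,
        "reply": 0.20,
        "clarification": 0.17,
        "question": 0.11,
        "backchannel": 0.08,
        "check_in": 0.08,
        "character_speech": 0.06,
        "incomplete": 0.06,
    }
    part_row = {tag: self_elab * w for tag, w in part_split.items()}
    exam_mass = 1.0 - self_elab
    part_row["examiner_question"] = exam_mass * 0.6
    part_row["examiner_statement"] = exam_mass * 0.4
    rows = {
        "START": {"examiner_question": 0.7, "examiner_statement": 0.3},
        "examiner_question": {
            "reply": 0.50,
            "clarification": 0.15,
            "initiation_statement": 0.08,
            "backchannel": 0.05,
            "question": 0.05,
            "incomplete": 0.07,
            "examiner_question": 0.05,
            "examiner_statement": 0.05,
        },
        "examiner_statement": {
            "backchannel": backchannel_mass,
            "examiner_question": 0.43 - backchannel_mass,
            "reply": 0.15,
            "initiation_statement": 0.15,
            "question": 0.08,
            "clarification": 0.05,
            "incomplete": 0.04,
            "examiner_statement": 0.10,
        },
    }
    for tag in (
        "initiation_statement",
        "question",
        "reply",
        "clarification",
        "backchannel",
        "check_in",
        "character_speech",
        "incomplete",
    ):
        rows[tag] = part_row
    T = np.array([_row(states, rows[s]) for s in states])
    return T, states


def default_group_params(
    task: Task, diagnosis: str, sex: str, profile_means: np.ndarray | None = None
) -> GroupParams:
    task = Task(task)
    if task is Task.NARRATIVE:
        T, states = _narrative_transition(diagnosis)
        n_utt, length = 50.0, 7.0
    else:
        T, states = _conversation_transition(diagnosis, sex)
        n_utt, length = 80.0, 5.0
    lexical_rates = {
        "SimpleAffectiveStates": 0.020,
        "ComplexAffectiveStates": 0.020 if sex == "female" else 0.010,
        "AffectiveBehaviors": 0.010,
        "CognitiveStates": 0.015,
        "CognitiveBehaviors": 0.010,
        "CausalExplanations": 0.010,
        "StoryElements": 0.015 if task is Task.NARRATIVE else 0.002,
        "Characters": 0.020 if task is Task.NARRATIVE else 0.002,
    }
    return GroupParams(
        transition=T,
        states=states,
        n_utterances=n_utt,
        utterance_length=length,
        lexical_rates=lexical_rates,
        viq_mean=105.0 if diagnosis == "asd" else 112.0,
        profile_means=profile_means,
    )


def default_config(
    task: Task,
    n_per_group: int | Mapping[tuple[str, str], int] = 30,
    seed: int = 0,
) -> SyntheticConfig:
    task = Task(task)
    groups = {
        (dx, sex): default_group_params(task, dx, sex) for dx, sex in GROUPS
    }
    return SyntheticConfig(groups=groups, n_per_group=n_per_group, seed=seed)


def _sample_tags(
    gp: GroupParams, task: Task, rng: np.random.Generator
) -> list[tuple[Speaker, str]]:
    n = max(1, int(rng.poisson(gp.n_utterances)))
    cum = np.cumsum(gp.transition, axis=1)
    draws = rng.random(n)
    out: list[tuple[Speaker, str]] = []
    state = 0  # START
    for u in draws:
        state = min(
            int(np.searchsorted(cum[state], u, side="right")), len(gp.states) - 1
        )
        tag = gp.states[state]
        speaker = (
            Speaker.EXAMINER if tag.startswith("examiner_") else Speaker.PARTICIPANT
        )
        out.append((speaker, tag))
    return out


def _sample_tokens(
    gp: GroupParams,
    speaker: Speaker,
    act: str,
    rng: np.random.Generator,
    vocab: list[str],
    category_words: dict[str, list[str]],
) -> list[Token]:
    mean = gp.utterance_length if speaker is Speaker.PARTICIPANT else gp.examiner_length
    n_tok = 1 + int(rng.poisson(mean))
    cats = list(gp.lexical_rates)
    probs = np.array([gp.lexical_rates[c] for c in cats])
    p_filler = gp.filled_pause_rate
    fillers = sorted(DEFAULT_FILLED_PAUSES)
    tokens: list[Token] = []
    for _ in range(n_tok):
        u = rng.random()
        if u < p_filler:
            word = fillers[rng.integers(len(fillers))]
            filled = True
        else:
            v = rng.random()
            acc = 0.0
            word = None
            if speaker is Speaker.PARTICIPANT:
                for c, pc in zip(cats, probs):
                    acc += pc
                    if v < acc:
                        pool = category_words[c]
                        word = pool[rng.integers(len(pool))]
                        break
            if word is None:
                word = vocab[rng.integers(len(vocab))]
            filled = word in DEFAULT_FILLED_PAUSES
        tokens.append(
            Token(
                surface=word,
                normalized=word,
                is_maze=bool(rng.random() < gp.maze_rate),
                is_filled_pause=filled,
            )
        )
    return tokens


def _category_words(lex: Lexicon) -> dict[str, list[str]]:
    """Single-word literal entries per base category (emittable words)."""
    return {
        cat: sorted(e for e in entries if " " not in e and not e.endswith("*"))
        for cat, entries in lex.categories.items()
    }


def generate_transcript(
    gp: GroupParams,
    task: Task,
    id: str,
    seed: int | np.random.SeedSequence,
    diagnosis: str = "asd",
    sex: str = "male",
    lexicon: Lexicon | None = None,
    vocab: list[str] | None = None,
    with_tokens: bool = True,
) -> Transcript:
    """One synthetic transcript; deterministic given the seed.

    ``with_tokens=False`` emits a single placeholder token per utterance —
    a fast path for tag-level simulations (sequence and Markov statistics
    do not read token content).
    """
    task = Task(task)
    rng = np.random.default_rng(seed)
    lex = lexicon if lexicon is not None else load_example_lexicon()
    vocab = vocab if vocab is not None else background_vocabulary()
    cat_words = _category_words(lex)
    missing = [c for c in gp.lexical_rates if not cat_words.get(c)]
    if missing:
        raise ValueError(f"lexical_rates name categories with no emittable words: {missing}")
    utterances: list[Utterance] = []
    for i, (speaker, tag) in enumerate(_sample_tags(gp, task, rng)):
        if with_tokens:
            tokens = _sample_tokens(gp, speaker, tag, rng, vocab, cat_words)
        else:
            tokens = [Token(surface="xxx", normalized="xxx")]
        utterances.append(Utterance(index=i, speaker=speaker, act=tag, tokens=tokens))
    viq = float(np.round(rng.normal(gp.viq_mean, gp.viq_sd), 1))
    age = float(np.round(np.clip(rng.normal(gp.age_mean, gp.age_sd), 8.0, 18.0), 1))
    return Transcript(
        id=id,
        task=task,
        diagnosis=diagnosis,
        sex=sex,
        covariates={"age": age, "viq": viq},
        utterances=utterances,
    )


def generate_cohort(
    cfg: SyntheticConfig,
    task: Task,
    with_tokens: bool = True,
) -> list[Transcript]:
    """One cohort: ``cfg.size(group)`` transcripts per (diagnosis, sex) group."""
    task = Task(task)
    lex = load_example_lexicon()
    vocab = background_vocabulary()
    total = sum(cfg.size(g) for g in cfg.groups)
    children = iter(np.random.SeedSequence(cfg.seed).spawn(total))
    out: list[Transcript] = []
    for (dx, sex), gp in cfg.groups.items():
        for i in range(cfg.size((dx, sex))):
            out.append(
                generate_transcript(
                    gp,
                    task,
                    id=f"{dx}_{sex}_{i:03d}",
                    seed=next(children),
                    diagnosis=dx,
                    sex=sex,
                    lexicon=lex,
                    vocab=vocab,
                    with_tokens=with_tokens,
                )
            )
    return out


def generate_profile_data(
    k: int,
    weights: Sequence[float],
    means: np.ndarray,
    variances: np.ndarray,
    n: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draws from a diagonal Gaussian mixture; returns (X, true labels)."""
    weights = np.asarray(weights, dtype=float)
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if weights.size != k or means.shape[0] != k or variances.shape[0] != k:
        raise ValueError("weights/means/variances must have k rows")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(k, size=n, p=weights)
    X = means[labels] + rng.standard_normal((n, means.shape[1])) * np.sqrt(
        variances[labels]
    )
    return X, labels


def true_kl(gp_a: GroupParams, gp_b: GroupParams) -> tuple[float, float, float]:
    """Analytic divergence rates between two planted chains:
    (forward, reverse, symmetric mean)."""
    if gp_a.states != gp_b.states:
        raise ValueError("state spaces differ")
    zeros = np.zeros_like(gp_a.transition, dtype=np.int64)
    ca = MarkovChain(states=list(gp_a.states), counts=zeros, P=gp_a.transition, alpha=0.0)
    cb = MarkovChain(states=list(gp_b.states), counts=zeros, P=gp_b.transition, alpha=0.0)
    f = kl_rate(ca, cb)
    r = kl_rate(cb, ca)
    return f, r, 0.5 * (f + r)
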