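"""LIWC-style dictionary matching over participant speech.

A lexicon is a set of named word categories. Entries are literal words,
trailing-``*`` wildcard stems (``happi*`` matches ``happily``), or multi-word
phrases (``as a result``). Composite categories sum their constituents; the
shipped default composition mirrors the affect/cognition hierarchy:

* AffectiveStatesAndBehaviors = SimpleAffectiveStates + ComplexAffectiveStates
  + AffectiveBehaviors
* CognitiveStatesAndBehaviors = CognitiveStates + CognitiveBehaviors
* AffectAndCognition = AffectiveStatesAndBehaviors + CognitiveStatesAndBehaviors

Category hits are reported as raw counts and as a percent of the participant
word count (maze material excluded, consistently with the word-count rule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .transcripts import Transcript

__all__ = [
    "Lexicon",
    "CategoryProfile",
    "DEFAULT_COMPOSITION",
    "load_lexicon",
    "load_example_lexicon",
    "match_token",
    "classify_transcript",
    "cohort_profiles",
]

logger = logging.getLogger(__name__)

DEFAULT_COMPOSITION: dict[str, list[str]] = {
    "AffectiveStatesAndBehaviors": [
        "SimpleAffectiveStates",
        "ComplexAffectiveStates",
        "AffectiveBehaviors",
    ],
    "CognitiveStatesAndBehaviors": ["CognitiveStates", "CognitiveBehaviors"],
    "AffectAndCognition": [
        "AffectiveStatesAndBehaviors",
        "CognitiveStatesAndBehaviors",
    ],
}


@dataclass
class Lexicon:
    """Named word categories plus a composition map for summed categories."""

    categories: dict[str, set[str]]
    composition: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, parts in self.composition.items():
            for part in parts:
                if part not in self.categories and part not in self.composition:
                    raise ValueError(
                        f"composite {name!r} references unknown category {part!r}"
                    )

    @property
    def category_names(self) -> list[str]:
        return list(self.categories) + list(self.composition)

    def multiword_entries(self) -> dict[tuple[str, ...], list[str]]:
        """Phrase entries -> list of owning base categories."""
        out: dict[tuple[str, ...], list[str]] = {}
        for cat, entries in self.categories.items():
            for e in entries:
                if " " in e:
                    out.setdefault(tuple(e.split()), []).append(cat)
        return out


@dataclass
class CategoryProfile:
    transcript_id: str
    word_count: int
    counts: dict[str, int]
    percents: dict[str, float]


def load_lexicon(
    stream: IO[str] | str,
    composition: Mapping[str, list[str]] | None = None,
) -> Lexicon:
    """Read a ``.dic``-style file: ``%``-delimited numbered category header
    block, then ``entry<TAB>category-ids`` lines."""
    import io

    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.rstrip("\n") for ln in stream]
    try:
        first = lines.index("%")
        second = lines.index("%", first + 1)
    except ValueError:
        raise ValueError("missing %-delimited category header block")
    id_to_name: dict[str, str] = {}
    for ln in lines[first + 1 : second]:
        if not ln.strip():
            continue
        cid, _, name = ln.strip().partition("\t")
        if not name:
            parts = ln.split()
            cid, name = parts[0], parts[1]
        id_to_name[cid] = name
    categories: dict[str, set[str]] = {name: set() for name in id_to_name.values()}
    for ln in lines[second + 1 :]:
        if not ln.strip():
            continue
        entry, _, ids = ln.rstrip().rpartition("\t")
        if not entry:  # space-separated fallback, single-word entries only
            parts = ln.split()
            entry, ids = parts[0], " ".join(parts[1:])
        entry = entry.strip().casefold()
        for cid in ids.split():
            if cid not in id_to_name:
                raise ValueError(
                    f"entry {entry!r} references undeclared category id {cid}"
                )
            cat = id_to_name[cid]
            if entry in categories[cat]:
                logger.warning("duplicate entry %r in category %r", entry, cat)
            categories[cat].add(entry)
    comp = dict(composition) if composition is not None else {}
    return Lexicon(categories=categories, composition=comp)


def load_example_lexicon() -> Lexicon:
    """The small example lexicon shipped with the package.

    It covers simple/complex affective states, affective and cognitive
    behaviors, cognitive states, causal markers, story elements and
    characters; real analyses supply their own ``.dic`` files.
    """
    text = (
        resources.files("pragmalang").joinpath("data/example.dic").read_text("utf-8")
    )
    return load_lexicon(text, composition=DEFAULT_COMPOSITION)


class _MatchIndex:
    """Literal-lookup plus stem-scan index over a lexicon's single-word entries."""

    def __init__(self, lex: Lexicon):
        self.literals: dict[str, set[str]] = {}
        self.stems: list[tuple[str, str]] = []  # (prefix, category)
        for cat, entries in lex.categories.items():
            for e in entries:
                if " " in e:
                    continue
                if e.endswith("*"):
                    self.stems.append((e[:-1], cat))
                else:
                    self.literals.setdefault(e, set()).add(cat)

    def __call__(self, token: str) -> set[str]:
        hits = set(self.literals.get(token, ()))
        for prefix, cat in self.stems:
            if cat not in hits and token.startswith(prefix):
                hits.add(cat)
        return hits


def match_token(lex: Lexicon, token: str) -> set[str]:
    """Base categories whose literal entries or wildcard stems match ``token``."""
    return _MatchIndex(lex)(token)


def classify_transcript(
    t: Transcript,
    lex: Lexicon,
    count_mazes: bool = False,
) -> CategoryProfile:
    """Category counts and percent-of-word-count for one transcript.

    Counts accumulate over countable participant tokens (maze tokens excluded
    unless ``count_mazes``). Phrase entries are matched greedily left to right
    within an utterance, longest phrase first; a phrase match counts once per
    owning category and consumes its tokens, which are then not matched as
    single words. When the word count is zero all percents are NaN.
    """
    counts = {name: 0 for name in lex.category_names}
    phrases = lex.multiword_entries()
    max_len = max((len(p) for p in phrases), default=0)
    index = _MatchIndex(lex)
    n_words = 0
    for utt in t.participant_utterances():
        toks = [
            tok.normalized
            for tok in utt.tokens
            if count_mazes or tok.countable
        ]
        n_words += len(toks)
        i = 0
        while i < len(toks):
            matched_phrase = False
            for length in range(min(max_len, len(toks) - i), 1, -1):
                gram = tuple(toks[i : i + length])
                if gram in phrases:
                    for cat in phrases[gram]:
                        counts[cat] += 1
                    i += length
                    matched_phrase = True
                    break
            if matched_phrase:
                continue
            for cat in index(toks[i]):
                counts[cat] += 1
            i += 1
    for comp in lex.composition:  # insertion order: constituents resolve first
        counts[comp] = sum(counts[c] for c in lex.composition[comp])
    if n_words > 0:
        percents = {c: 100.0 * counts[c] / n_words for c in counts}
    else:
        percents = {c: math.nan for c in counts}
    return CategoryProfile(
        transcript_id=t.id, word_count=n_words, counts=counts, percents=percents
    )


def cohort_profiles(
    transcripts: Sequence[Transcript] | Iterable[Transcript],
    lex: Lexicon,
    count_mazes: bool = False,
) -> pd.DataFrame:
    """One row per transcript with ``<cat>_count`` and ``<cat>_pct`` columns."""
    rows = []
    seen: set[str] = set()
    for t in transcripts:
        if t.id in seen:
            raise ValueError(f"duplicate transcript id {t.id!r}")
        seen.add(t.id)
        prof = classify_transcript(t, lex, count_mazes=count_mazes)
        row: dict[str, object] = {
            "id": t.id,
            "task": t.task.value,
            "diagnosis": t.diagnosis,
            "sex": t.sex,
            "word_count": prof.word_count,
        }
        row.update(t.covariates)
        for cat in lex.category_names:
            row[f"{cat}_count"] = prof.counts[cat]
            row[f"{cat}_pct"] = prof.percents[cat]
        rows.append(row)
    return pd.DataFrame(rows)
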