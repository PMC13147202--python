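"""Transcript data model and plain-text I/O.

Language samples are stored one participant-task per file in a minimal
SALT-inspired dialect::

    @id: P001
    @task: narrative
    @diagnosis: asd
    @sex: female
    @age: 13.5
    @viq: 104
    P statement\t(the the) the frog left
    E examiner_question\twhat happened next?

Header lines start with ``@``; each utterance line is
``<speaker-code> <act-tag>\\t<text>``. Mazes (false starts, repetitions,
reformulations) are enclosed in parentheses and excluded from word counts;
filled pauses (um, uh, ...) are ordinary countable words unless they fall
inside a maze, in which case the maze exclusion wins.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Mapping

import pandas as pd

__all__ = [
    "Speaker",
    "Task",
    "Token",
    "Utterance",
    "Transcript",
    "TranscriptFormatError",
    "NARRATIVE_TAGS",
    "CONVERSATION_TAGS",
    "EXAMINER_TAGS",
    "DEFAULT_FILLED_PAUSES",
    "parse_transcript",
    "write_transcript",
    "read_transcript",
    "save_transcript",
    "participant_word_count",
    "utterance_count",
    "counts_table",
]

DEFAULT_FILLED_PAUSES = frozenset({"um", "uh", "er", "hm", "mhm"})

#: Participant dialog-act tags for the picture-book narrative task (7 categories).
NARRATIVE_TAGS = (
    "statement",
    "question",
    "nonnarrative",
    "character_speech",
    "sound_effect",
    "thinking",
    "incomplete",
)

#: Participant dialog-act tags for the semi-structured conversation task (8 categories).
CONVERSATION_TAGS = (
    "initiation_statement",
    "question",
    "reply",
    "clarification",
    "backchannel",
    "check_in",
    "character_speech",
    "incomplete",
)

#: Examiner tags (both tasks).
EXAMINER_TAGS = ("examiner_question", "examiner_statement")

_TERMINAL_PUNCT = ".,!?;:\"'"


class Speaker(str, Enum):
    PARTICIPANT = "P"
    EXAMINER = "E"


class Task(str, Enum):
    NARRATIVE = "narrative"
    CONVERSATION = "conversation"


def participant_tags(task: Task) -> tuple[str, ...]:
    return NARRATIVE_TAGS if Task(task) is Task.NARRATIVE else CONVERSATION_TAGS


def admissible_tags(task: Task, speaker: Speaker) -> tuple[str, ...]:
    if Speaker(speaker) is Speaker.EXAMINER:
        return EXAMINER_TAGS
    return participant_tags(task)


class TranscriptFormatError(ValueError):
    """Raised for malformed transcript files; carries the offending line number."""

    def __init__(self, message: str, lineno: int | None = None):
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)
        self.lineno = lineno


@dataclass(frozen=True)
class Token:
    surface: str
    normalized: str
    is_maze: bool = False
    is_filled_pause: bool = False

    @property
    def countable(self) -> bool:
        """Counts toward word count: everything except maze material."""
        return not self.is_maze


@dataclass
class Utterance:
    index: int
    speaker: Speaker
    act: str
    tokens: list[Token] = field(default_factory=list)

    @property
    def text(self) -> str:
        """Surface text with parentheses restored around maximal maze runs."""
        parts: list[str] = []
        run: list[str] = []
        for tok in self.tokens:
            if tok.is_maze:
                run.append(tok.surface)
            else:
                if run:
                    parts.append("(" + " ".join(run) + ")")
                    run = []
                parts.append(tok.surface)
        if run:
            parts.append("(" + " ".join(run) + ")")
        return " ".join(parts)


@dataclass
class Transcript:
    id: str
    task: Task
    diagnosis: str  # "asd" | "non_asd"
    sex: str  # "male" | "female"
    covariates: dict[str, float] = field(default_factory=dict)
    utterances: list[Utterance] = field(default_factory=list)

    def participant_utterances(self) -> list[Utterance]:
        return [u for u in self.utterances if u.speaker is Speaker.PARTICIPANT]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Transcript):
            return NotImplemented
        return (
            self.id == other.id
            and self.task == other.task
            and self.diagnosis == other.diagnosis
            and self.sex == other.sex
            and self.covariates == other.covariates
            and self.utterances == other.utterances
        )


def _normalize(word: str) -> str:
    return word.strip(_TERMINAL_PUNCT).casefold()


def tokenize(
    text: str,
    filled_pauses: frozenset[str] = DEFAULT_FILLED_PAUSES,
) -> list[Token]:
    """Whitespace tokenization with parenthesized maze spans.

    Terminal punctuation is stripped and words case-folded for the
    ``normalized`` form; hyphenated forms are kept whole.
    """
    tokens: list[Token] = []
    in_maze = False
    for raw in text.split():
        surface = raw
        opened = surface.startswith("(")
        if opened:
            in_maze = True
            surface = surface[1:]
        closes = surface.endswith(")")
        if closes:
            surface = surface[:-1]
        if not surface:
            if closes:
                in_maze = False
            continue
        norm = _normalize(surface)
        if not norm:
            if closes:
                in_maze = False
            continue
        tokens.append(
            Token(
                surface=surface,
                normalized=norm,
                is_maze=in_maze,
                is_filled_pause=norm in filled_pauses,
            )
        )
        if closes:
            in_maze = False
    return tokens


def parse_transcript(
    stream: IO[str] | str,
    filled_pauses: frozenset[str] = DEFAULT_FILLED_PAUSES,
) -> Transcript:
    """Parse one transcript from a text stream (or a literal string)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    header: dict[str, str] = {}
    utterances: list[Utterance] = []
    task: Task | None = None
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("@"):
            if ":" not in line:
                raise TranscriptFormatError(f"malformed header {line!r}", lineno)
            key, _, value = line[1:].partition(":")
            header[key.strip()] = value.strip()
            continue
        # utterance line
        if task is None:
            task = _require_task(header)
        prefix, tab, text = line.partition("\t")
        if not tab:
            raise TranscriptFormatError(
                f"utterance line lacks a tab separator: {line!r}", lineno
            )
        fields = prefix.split()
        if len(fields) != 2:
            raise TranscriptFormatError(
                f"expected '<speaker> <act>' before the tab, got {prefix!r}", lineno
            )
        code, act = fields
        try:
            speaker = Speaker(code)
        except ValueError:
            raise TranscriptFormatError(f"unknown speaker code {code!r}", lineno)
        if act not in admissible_tags(task, speaker):
            raise TranscriptFormatError(
                f"act tag {act!r} is not valid for speaker {speaker.value} "
                f"in a {task.value} transcript",
                lineno,
            )
        tokens = tokenize(text, filled_pauses)
        if not tokens and act != "incomplete":
            warnings.warn(
                f"line {lineno}: empty utterance with act {act!r}", stacklevel=2
            )
        utterances.append(
            Utterance(index=len(utterances), speaker=speaker, act=act, tokens=tokens)
        )
    if task is None:
        task = _require_task(header)
    for key in ("id", "diagnosis", "sex"):
        if key not in header:
            raise TranscriptFormatError(f"missing required header @{key}")
    covariates: dict[str, float] = {}
    for key in ("age", "viq"):
        if key in header:
            try:
                covariates[key] = float(header[key])
            except ValueError:
                raise TranscriptFormatError(f"non-numeric @{key}: {header[key]!r}")
    return Transcript(
        id=header["id"],
        task=task,
        diagnosis=header["diagnosis"],
        sex=header["sex"],
        covariates=covariates,
        utterances=utterances,
    )


def _require_task(header: Mapping[str, str]) -> Task:
    if "task" not in header:
        raise TranscriptFormatError("missing required header @task")
    try:
        return Task(header["task"])
    except ValueError:
        raise TranscriptFormatError(f"unknown task {header['task']!r}")


def write_transcript(t: Transcript, stream: IO[str]) -> None:
    """Serialize ``t`` so that :func:`parse_transcript` reproduces it."""
    stream.write(f"@id: {t.id}\n")
    stream.write(f"@task: {Task(t.task).value}\n")
    stream.write(f"@diagnosis: {t.diagnosis}\n")
    stream.write(f"@sex: {t.sex}\n")
    for key, value in t.covariates.items():
        stream.write(f"@{key}: {value:g}\n")
    for utt in t.utterances:
        stream.write(f"{utt.speaker.value} {utt.act}\t{utt.text}\n")


def transcript_to_string(t: Transcript) -> str:
    buf = io.StringIO()
    write_transcript(t, buf)
    return buf.getvalue()


def read_transcript(path, **kwargs) -> Transcript:
    with open(path, encoding="utf-8") as fh:
        return parse_transcript(fh, **kwargs)


def save_transcript(t: Transcript, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        write_transcript(t, fh)


def participant_word_count(t: Transcript) -> int:
    """Participant words excluding maze/reformulation material.

    Filled pauses outside mazes are counted; examiner tokens never count.
    """
    return sum(
        tok.countable
        for utt in t.participant_utterances()
        for tok in utt.tokens
    )


def utterance_count(t: Transcript, speaker: Speaker) -> int:
    speaker = Speaker(speaker)
    return sum(u.speaker is speaker for u in t.utterances)


def counts_table(transcripts: Iterable[Transcript]) -> pd.DataFrame:
    """Per-transcript word and utterance counts (one row per transcript)."""
    rows = []
    for t in transcripts:
        rows.append(
            {
                "id": t.id,
                "task": Task(t.task).value,
                "diagnosis": t.diagnosis,
                "sex": t.sex,
                "word_count": participant_word_count(t),
                "utterance_count_participant": utterance_count(t, Speaker.PARTICIPANT),
                "utterance_count_examiner": utterance_count(t, Speaker.EXAMINER),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "task",
            "diagnosis",
            "sex",
            "word_count",
            "utterance_count_participant",
            "utterance_count_examiner",
        ],
    )
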