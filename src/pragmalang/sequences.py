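"""Speech-act proportions, diversity, and a-priori sequence statistics.

Two a-priori sequence inventories are implemented, both defined over
adjacent utterance pairs:

Narrative (participant utterances only — examiner turns are dropped before
pairing):

* ``on_topic_consecutive`` — both members in {statement, question,
  character_speech, sound_effect}
* ``off_topic_consecutive`` — both members in {nonnarrative, thinking}
* ``storytelling_consecutive`` — both members in {character_speech,
  sound_effect}

Conversation (speaker-aware, full turn order):

* ``non_obligatory_response`` — examiner non-question followed by a
  participant utterance that is not a backchannel (see note below)
* ``backchannel_seq`` — examiner non-question followed by a participant
  backchannel
* ``self_elaboration`` — a participant utterance followed by another
  participant utterance
* ``expected_after_question`` — examiner question followed by participant
  reply or clarification
* ``unexpected_after_question`` — examiner question followed by participant
  backchannel or initiation statement

Each sequence is reported as a raw count plus an opportunity-normalized rate;
opportunities are the number of pairs whose first member could have started
the sequence (examiner non-questions, examiner questions, or participant-opened
pairs). Runs longer than two contribute one count per adjacent pair.

Note: "non-obligatory response to examiner speech" is under-specified in the
coding scheme this mirrors; the rule used here (any non-backchannel
participant response to an examiner non-question) is a documented choice and
can be changed via ``non_obligatory_includes_backchannel``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .transcripts import Speaker, Task, Transcript

__all__ = [
    "SequenceProfile",
    "NARRATIVE_SEQUENCES",
    "CONVERSATION_SEQUENCES",
    "ON_TOPIC_TAGS",
    "OFF_TOPIC_TAGS",
    "STORYTELLING_TAGS",
    "speech_act_proportions",
    "speech_act_diversity",
    "count_narrative_sequences",
    "count_conversation_sequences",
]

ON_TOPIC_TAGS = frozenset({"statement", "question", "character_speech", "sound_effect"})
OFF_TOPIC_TAGS = frozenset({"nonnarrative", "thinking"})
STORYTELLING_TAGS = frozenset({"character_speech", "sound_effect"})

NARRATIVE_SEQUENCES = (
    "on_topic_consecutive",
    "off_topic_consecutive",
    "storytelling_consecutive",
)
CONVERSATION_SEQUENCES = (
    "non_obligatory_response",
    "backchannel_seq",
    "self_elaboration",
    "expected_after_question",
    "unexpected_after_question",
)


@dataclass
class SequenceProfile:
    transcript_id: str
    task: Task
    counts: dict[str, int]
    opportunities: dict[str, int]

    @property
    def rates(self) -> dict[str, float]:
        return {
            name: (self.counts[name] / self.opportunities[name])
            if self.opportunities[name] > 0
            else float("nan")
            for name in self.counts
        }


def _require_task(t: Transcript, task: Task) -> None:
    if Task(t.task) is not task:
        raise ValueError(
            f"transcript {t.id!r} has task {Task(t.task).value!r}; "
            f"expected {task.value!r}"
        )


def speech_act_proportions(t: Transcript) -> dict[str, float]:
    """Per participant tag: 100 x tag count / participant utterance count."""
    from .transcripts import participant_tags

    utts = t.participant_utterances()
    tags = participant_tags(t.task)
    if not utts:
        return {tag: float("nan") for tag in tags}
    n = len(utts)
    out = {tag: 0.0 for tag in tags}
    for u in utts:
        out[u.act] += 1
    return {tag: 100.0 * c / n for tag, c in out.items()}


def speech_act_diversity(t: Transcript) -> int:
    """Number of distinct participant tags used (narrative task, range 0-7)."""
    _require_task(t, Task.NARRATIVE)
    return len({u.act for u in t.participant_utterances()})


def count_narrative_sequences(t: Transcript) -> SequenceProfile:
    _require_task(t, Task.NARRATIVE)
    tags = [u.act for u in t.participant_utterances()]
    pairs = list(zip(tags, tags[1:]))
    counts = dict.fromkeys(NARRATIVE_SEQUENCES, 0)
    for a, b in pairs:
        if a in ON_TOPIC_TAGS and b in ON_TOPIC_TAGS:
            counts["on_topic_consecutive"] += 1
        if a in OFF_TOPIC_TAGS and b in OFF_TOPIC_TAGS:
            counts["off_topic_consecutive"] += 1
        if a in STORYTELLING_TAGS and b in STORYTELLING_TAGS:
            counts["storytelling_consecutive"] += 1
    opportunities = dict.fromkeys(NARRATIVE_SEQUENCES, len(pairs))
    return SequenceProfile(t.id, Task.NARRATIVE, counts, opportunities)


def count_conversation_sequences(
    t: Transcript,
    non_obligatory_includes_backchannel: bool = False,
) -> SequenceProfile:
    _require_task(t, Task.CONVERSATION)
    utts = t.utterances
    counts = dict.fromkeys(CONVERSATION_SEQUENCES, 0)
    n_exam_nonq = 0  # pairs opened by an examiner non-question
    n_exam_q = 0  # pairs opened by an examiner question
    n_part_first = 0  # pairs opened by a participant utterance
    for a, b in zip(utts, utts[1:]):
        a_exam = a.speaker is Speaker.EXAMINER
        b_part = b.speaker is Speaker.PARTICIPANT
        if a_exam and a.act != "examiner_question":
            n_exam_nonq += 1
            if b_part:
                if b.act == "backchannel":
                    counts["backchannel_seq"] += 1
                    if non_obligatory_includes_backchannel:
                        counts["non_obligatory_response"] += 1
                else:
                    counts["non_obligatory_response"] += 1
        elif a_exam:
            n_exam_q += 1
            if b_part and b.act in ("reply", "clarification"):
                counts["expected_after_question"] += 1
            if b_part and b.act in ("backchannel", "initiation_statement"):
                counts["unexpected_after_question"] += 1
        else:
            n_part_first += 1
            if b_part:
                counts["self_elaboration"] += 1
    opportunities = {
        "non_obligatory_response": n_exam_nonq,
        "backchannel_seq": n_exam_nonq,
        "self_elaboration": n_part_first,
        "expected_after_question": n_exam_q,
        "unexpected_after_question": n_exam_q,
    }
    return SequenceProfile(t.id, Task.CONVERSATION, counts, opportunities)
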