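"""Core data model for time-aligned dyadic conversation.

All times are milliseconds (int or float). The atomic record is a
:class:`WordToken`; a :class:`Turn` is a maximal glued run of one speaker's
tokens; lexical resources are rows of :class:`LexiconEntry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

__all__ = [
    "WordToken",
    "Turn",
    "LexiconEntry",
    "SpeakerMeta",
    "ValidationError",
    "FormatError",
]


class ValidationError(ValueError):
    """An input record violates a data-model invariant."""


class FormatError(ValueError):
    """A file does not conform to the expected external format."""


# Substring marking laughter inside Switchboard-style orthography.
LAUGHTER_MARKER = "[laughter"


@dataclass(frozen=True)
class WordToken:
    """One time-aligned phonological word.

    ``pos`` uses the Penn tagset; the tag ``UH`` marks interjections,
    fillers and discourse markers. ``dialog_act`` is a label from the
    NXT dialog-act inventory (see :mod:`turntaking.coding`) or ``None``.
    """

    conversation_id: str
    speaker_id: str
    orth: str
    start_ms: float
    end_ms: float
    pos: Optional[str] = None
    lemma: Optional[str] = None
    dialog_act: Optional[str] = None
    laughter: bool = False
    n_syllables: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.start_ms >= 0 and self.end_ms > self.start_ms):
            raise ValidationError(
                f"token {self.orth!r} ({self.conversation_id}/{self.speaker_id}): "
                f"need 0 <= start_ms < end_ms, got [{self.start_ms}, {self.end_ms}]"
            )
        if self.n_syllables is not None and self.n_syllables < 0:
            raise ValidationError(f"token {self.orth!r}: negative n_syllables")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    @property
    def is_laughter(self) -> bool:
        """Laughter flag OR transcript convention (``[laughter...`` in orth)."""
        return self.laughter or LAUGHTER_MARKER in self.orth.lower()


@dataclass
class Turn:
    """A maximal stretch of one speaker's talk.

    ``dialog_acts`` is the order-preserving deduplicated act sequence over
    the turn's tokens; ``parses`` holds bracketed-tree roots
    (:class:`turntaking.trees.TreeNode`).
    """

    tokens: Sequence[WordToken]
    parses: list = field(default_factory=list)
    speaker_sex: Optional[str] = None  # "male" / "female" / None

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValidationError("a Turn needs at least one token")
        speakers = {t.speaker_id for t in self.tokens}
        if len(speakers) != 1:
            raise ValidationError(f"a Turn must have one speaker, got {sorted(speakers)}")
        for a, b in zip(self.tokens, self.tokens[1:]):
            if b.start_ms < a.start_ms:
                raise ValidationError("Turn tokens must be time-ordered")

    @property
    def conversation_id(self) -> str:
        return self.tokens[0].conversation_id

    @property
    def speaker_id(self) -> str:
        return self.tokens[0].speaker_id

    @property
    def start_ms(self) -> float:
        return self.tokens[0].start_ms

    @property
    def end_ms(self) -> float:
        return self.tokens[-1].end_ms

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    @property
    def dialog_acts(self) -> list:
        """Order-preserving deduplicated dialog-act sequence over the tokens."""
        acts: list = []
        for t in self.tokens:
            if t.dialog_act is not None and (not acts or acts[-1] != t.dialog_act):
                acts.append(t.dialog_act)
        return acts

    @property
    def has_laughter(self) -> bool:
        return any(t.is_laughter for t in self.tokens)

    def with_sex(self, sex: Optional[str]) -> "Turn":
        return replace(self, speaker_sex=sex)


@dataclass(frozen=True)
class LexiconEntry:
    """Per-(lemma, POS) lexical statistics.

    ``frequency`` is a corpus count; ``concreteness`` a unitless rating
    (typically a 1-5 scale); ``surprisal`` a bits-per-word-scale value;
    ``contextual_diversity`` the number of distinct conversations the
    (lemma, POS) occurs in.
    """

    lemma: str
    pos: str
    frequency: float
    concreteness: Optional[float] = None
    surprisal: Optional[float] = None
    contextual_diversity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise ValidationError(f"lexicon entry {self.lemma!r}: negative frequency")


@dataclass(frozen=True)
class SpeakerMeta:
    speaker_id: str
    sex: str  # "male" or "female"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"speaker {self.speaker_id}: sex must be male/female")


def validate_no_overlap(tokens: Sequence[WordToken]) -> None:
    """Check that one speaker's tokens in one conversation never overlap.

    ``tokens`` must already be sorted by start time and belong to a single
    (conversation, speaker) pair. Raises :class:`ValidationError` naming
    the offending tokens.
    """
    for i, (a, b) in enumerate(zip(tokens, tokens[1:])):
        if b.start_ms < a.end_ms:
            raise ValidationError(
                f"overlapping tokens for speaker {a.speaker_id} in "
                f"{a.conversation_id}: {a.orth!r} [{a.start_ms}, {a.end_ms}] and "
                f"{b.orth!r} [{b.start_ms}, {b.end_ms}] (rows {i}, {i + 1})"
            )
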