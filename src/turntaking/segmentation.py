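"""Turn construction and floor transfer offsets (FTOs).

Turns are approximated by "gluing" a speaker's phonological words together
whenever the silent gap between consecutive words is under 180 ms. The FTO
of a floor transfer is the signed time from the end of the prior turn (T1)
to the onset of the next turn by the other speaker (T2): negative when the
turns overlap, positive when there is a gap. Transfers with |FTO| beyond
2200 ms are treated as lapses/long overlaps and excluded.

The stripped variant re-measures the FTO to the first T2 word that is not
a turn-preserving placeholder ("uh", "um", "well", or POS tag UH), since
such turn-initial hesitations hold the floor while planning continues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import pandas as pd

from .types import Turn, WordToken

__all__ = ["FloorTransfer", "glue_turns", "extract_floor_transfers",
           "strip_placeholders", "transfers_to_frame",
           "DEFAULT_MAX_GAP_MS", "DEFAULT_FTO_LIMIT_MS", "PLACEHOLDER_WORDS"]

DEFAULT_MAX_GAP_MS = 180.0
DEFAULT_FTO_LIMIT_MS = 2200.0
PLACEHOLDER_WORDS = frozenset({"uh", "um", "well"})
_PUNCT = re.compile(r"[^\w']+")


@dataclass
class FloorTransfer:
    """A (T1, T2) pair of consecutive turns by different speakers.

    ``fto_ms`` is exactly ``t2.start_ms - t1.end_ms``. ``fto_stripped_ms``
    (set by :func:`strip_placeholders`) measures to the first
    non-placeholder T2 word and is absent when T2 is all placeholders.
    ``contained`` flags T2s that end at or before T1's end (fully
    overlapped turns, e.g. mid-turn backchannels).
    """

    t1: Turn
    t2: Turn
    fto_ms: float = field(init=False)
    fto_stripped_ms: Optional[float] = None
    t2_all_placeholder: bool = False
    contained: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.t1.speaker_id == self.t2.speaker_id:
            raise ValueError("a floor transfer needs two distinct speakers")
        self.fto_ms = self.t2.start_ms - self.t1.end_ms
        self.contained = self.t2.end_ms <= self.t1.end_ms

    @property
    def conversation_id(self) -> str:
        return self.t1.conversation_id


def glue_turns(tokens: Sequence[WordToken],
               max_gap_ms: float = DEFAULT_MAX_GAP_MS) -> List[Turn]:
    """Glue same-speaker tokens with inter-token gaps < ``max_gap_ms``.

    Tokens must come from a single conversation and satisfy the data-model
    invariants. Returns turns of all speakers sorted by onset (ties broken
    by speaker id, stably).
    """
    by_speaker: dict = {}
    for t in tokens:
        by_speaker.setdefault(t.speaker_id, []).append(t)
    turns: List[Turn] = []
    for spk in sorted(by_speaker):
        toks = sorted(by_speaker[spk], key=lambda t: t.start_ms)
        run: List[WordToken] = []
        for tok in toks:
            if run and tok.start_ms - run[-1].end_ms >= max_gap_ms:
                turns.append(Turn(run))
                run = []
            run.append(tok)
        if run:
            turns.append(Turn(run))
    turns.sort(key=lambda u: (u.start_ms, u.speaker_id))
    return turns


def extract_floor_transfers(turns: Sequence[Turn],
                            fto_limit_ms: float = DEFAULT_FTO_LIMIT_MS,
                            include_contained: bool = True) -> List[FloorTransfer]:
    """Floor transfers between onset-consecutive turns of different speakers.

    Walks the onset-sorted turn sequence; each consecutive pair with
    different speakers yields one transfer (same-speaker pairs yield none,
    and a turn serves as T2 of one transfer and T1 of the next). Transfers
    with |FTO| > ``fto_limit_ms`` are dropped; the boundary value itself is
    kept. ``include_contained=False`` additionally skips T2s that end
    inside T1, treating them as non-competing (the T1 of the following
    transfer is then the containing turn).
    """
    order = sorted(turns, key=lambda u: (u.start_ms, u.speaker_id))
    out: List[FloorTransfer] = []
    prev: Optional[Turn] = None
    for turn in order:
        if prev is not None and turn.speaker_id != prev.speaker_id:
            tr = FloorTransfer(prev, turn)
            if tr.contained and not include_contained:
                continue  # prev stays T1 for the next candidate
            if abs(tr.fto_ms) <= fto_limit_ms:
                out.append(tr)
        prev = turn
    return out


def is_placeholder(token: WordToken, method: str = "lexical") -> bool:
    """Turn-preserving placeholder test.

    ``lexical``: case-insensitive match on {uh, um, well} after stripping
    punctuation. ``pos``: Penn tag UH (interjection/filler/discourse
    marker).
    """
    if method == "lexical":
        return _PUNCT.sub("", token.orth.lower()) in PLACEHOLDER_WORDS
    if method == "pos":
        return token.pos == "UH"
    raise ValueError(f"unknown placeholder method {method!r}")


def strip_placeholders(transfer: FloorTransfer,
                       method: str = "lexical") -> FloorTransfer:
    """Set ``fto_stripped_ms``: FTO to the first non-placeholder T2 word.

    If every T2 word is a placeholder the transfer is flagged
    ``t2_all_placeholder`` and ``fto_stripped_ms`` stays absent (such T2s
    are excluded from the stripped analysis). Modifies and returns the
    transfer.
    """
    first_real = next((tok for tok in transfer.t2.tokens
                       if not is_placeholder(tok, method)), None)
    if first_real is None:
        transfer.t2_all_placeholder = True
        transfer.fto_stripped_ms = None
    else:
        transfer.t2_all_placeholder = False
        transfer.fto_stripped_ms = first_real.start_ms - transfer.t1.end_ms
    return transfer


def transfers_to_frame(transfers: Sequence[FloorTransfer],
                       turn_index: Optional[dict] = None) -> pd.DataFrame:
    """Tabulate transfers (the `extract` output format).

    ``turn_index`` optionally maps id(turn) -> index in the glued turn
    list, giving stable t1_index/t2_index keys.
    """
    rows = []
    for tr in transfers:
        rows.append({
            "conversation_id": tr.conversation_id,
            "t1_index": turn_index.get(id(tr.t1)) if turn_index else None,
            "t2_index": turn_index.get(id(tr.t2)) if turn_index else None,
            "t1_speaker": tr.t1.speaker_id, "t2_speaker": tr.t2.speaker_id,
            "fto_ms": tr.fto_ms, "fto_stripped_ms": tr.fto_stripped_ms,
            "t2_all_placeholder": tr.t2_all_placeholder,
            "contained": tr.contained,
        })
    return pd.DataFrame(rows)
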