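"""Sequence-organization coding of floor transfers.

Each NXT dialog act maps onto sequence-organization properties: whether it
initiates (first pair part: questions, openings), responds (second pair
part: answers, acknowledgements), is a response token (backchannels and
acknowledgements — short listener signals), and its valence
(positive/negative response). Each act also lists the acts that would make
a well-formed next turn (e.g. a yes/no question projects a yes or no).

A transfer is coded on T1's *final* act and T2's *first* act: T1's last
action is what T2 responds to, and T2's initial action is its response.
An adjacency pair requires the conjunction: T2's act is an expected next
of T1's act AND T1 initiates AND T2 responds (statement→statement is a
well-formed continuation but not an adjacency pair).

Preference follows conversation-analytic practice: among transfers where
T1 asks a question or makes an offer ("open-q", "tag-q", "wh-q", "yn-q",
"yn-decl-q", "commit"), a T2 that includes an accepting act ("affirm",
"yes", "answer") is a preferred response, any other T2 dispreferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, FrozenSet, Mapping, Optional

import pandas as pd

from .segmentation import FloorTransfer

__all__ = ["ActRecord", "ActScheme", "SequenceCodes", "default_scheme",
           "load_scheme", "code_transfer", "code_preference", "laughter_class",
           "CodingError", "QUESTION_COMMIT_ACTS", "ACCEPTING_ACTS",
           "BACKCHANNEL_ACTS"]

QUESTION_COMMIT_ACTS = frozenset(
    {"open-q", "tag-q", "wh-q", "yn-q", "yn-decl-q", "commit"})
ACCEPTING_ACTS = frozenset({"affirm", "yes", "answer"})
BACKCHANNEL_ACTS = frozenset({"backchannel", "backchannel-q"})


class CodingError(KeyError):
    """A dialog-act label is not covered by the scheme."""


@dataclass(frozen=True)
class ActRecord:
    act: str
    expected_next: FrozenSet[str]
    initiating: bool
    responding: bool
    response_token: bool
    valence: Optional[str]  # "positive" / "negative" / None

    def __post_init__(self) -> None:
        if self.response_token and not self.responding:
            raise ValueError(f"{self.act}: response tokens must be responding acts")


class ActScheme:
    """The dialog-act → sequence-organization mapping (one row per act)."""

    def __init__(self, records: Mapping[str, ActRecord]):
        self.records: Dict[str, ActRecord] = dict(records)

    def __getitem__(self, act: str) -> ActRecord:
        try:
            return self.records[act]
        except KeyError:
            raise CodingError(f"dialog act {act!r} is not in the scheme") from None

    def __contains__(self, act: str) -> bool:
        return act in self.records

    def __len__(self) -> int:
        return len(self.records)

    @property
    def acts(self) -> list:
        return list(self.records)


def load_scheme(path) -> ActScheme:
    """Load a scheme CSV (columns act, expected_next, initiating,
    responding, response_token, valence; expected_next ';'-separated)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = {}
    for r in df.itertuples(index=False):
        exp = frozenset(x for x in r.expected_next.split(";") if x)
        records[r.act] = ActRecord(
            act=r.act, expected_next=exp,
            initiating=r.initiating == "1", responding=r.responding == "1",
            response_token=r.response_token == "1",
            valence=r.valence if r.valence else None)
    return ActScheme(records)


def default_scheme() -> ActScheme:
    """The shipped NXT dialog-act inventory mapping."""
    with resources.as_file(
            resources.files("turntaking").joinpath("data/act_scheme.csv")) as p:
        return load_scheme(p)


@dataclass
class SequenceCodes:
    """Sequence-organization coding of one floor transfer."""

    t1_act: str
    t2_act: str
    t1_initiating: bool
    t1_responding: bool
    t1_response_token: bool
    t1_backchannel: bool
    t2_initiating: bool
    t2_responding: bool
    t2_response_token: bool
    t2_backchannel: bool
    t2_valence: str  # "positive" / "negative" / "none"
    adjacency_pair: bool
    preference: str  # "preferred" / "dispreferred" / "not_applicable"
    t1_laughter: bool
    t2_laughter: bool


def _coding_acts(transfer: FloorTransfer) -> tuple:
    acts1, acts2 = transfer.t1.dialog_acts, transfer.t2.dialog_acts
    if not acts1 or not acts2:
        raise CodingError("both turns of a transfer need dialog acts to be coded")
    return acts1[-1], acts2[0]


def code_preference(transfer: FloorTransfer, scheme: ActScheme) -> str:
    """Preferred/dispreferred/not_applicable status of T2's response.

    Gated on T1's coding act being a question or commit; within that set,
    preferred iff any T2 act is an accepting act.
    """
    t1_act, _ = _coding_acts(transfer)
    if t1_act not in QUESTION_COMMIT_ACTS:
        return "not_applicable"
    t2_acts = set(transfer.t2.dialog_acts)
    return "preferred" if t2_acts & ACCEPTING_ACTS else "dispreferred"


def laughter_class(transfer: FloorTransfer) -> str:
    """Four-way laughter classification: both (invited laughter), t1_only,
    t2_only (volunteered), neither."""
    l1, l2 = transfer.t1.has_laughter, transfer.t2.has_laughter
    if l1 and l2:
        return "both"
    if l1:
        return "t1_only"
    if l2:
        return "t2_only"
    return "neither"


def code_transfer(transfer: FloorTransfer, scheme: ActScheme,
                  backchannel_any_act: bool = True) -> SequenceCodes:
    """Code a floor transfer for all sequence-organization variables.

    ``backchannel_any_act=True`` flags a turn as backchannel when *any* of
    its acts is backchannel/backchannel-q; otherwise only the coding act
    counts.
    """
    t1_act, t2_act = _coding_acts(transfer)
    r1, r2 = scheme[t1_act], scheme[t2_act]
    for a in set(transfer.t1.dialog_acts) | set(transfer.t2.dialog_acts):
        scheme[a]  # raise CodingError on any unknown label
    if backchannel_any_act:
        t1_bc = bool(set(transfer.t1.dialog_acts) & BACKCHANNEL_ACTS)
        t2_bc = bool(set(transfer.t2.dialog_acts) & BACKCHANNEL_ACTS)
    else:
        t1_bc, t2_bc = t1_act in BACKCHANNEL_ACTS, t2_act in BACKCHANNEL_ACTS
    return SequenceCodes(
        t1_act=t1_act, t2_act=t2_act,
        t1_initiating=r1.initiating, t1_responding=r1.responding,
        t1_response_token=r1.response_token, t1_backchannel=t1_bc,
        t2_initiating=r2.initiating, t2_responding=r2.responding,
        t2_response_token=r2.response_token, t2_backchannel=t2_bc,
        t2_valence=r2.valence or "none",
        adjacency_pair=(t2_act in r1.expected_next
                        and r1.initiating and r2.responding),
        preference=code_preference(transfer, scheme),
        t1_laughter=transfer.t1.has_laughter,
        t2_laughter=transfer.t2.has_laughter,
    )
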