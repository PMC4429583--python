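"""End-to-end convenience wrapper: tokens → turns → transfers → features.

Glues tokens into turns per conversation, extracts and placeholder-strips
floor transfers, codes sequence organization, computes both turns'
processing profiles, and assembles the complete-case feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd

from .coding import ActScheme, SequenceCodes, code_transfer, default_scheme
from .features import build_feature_matrix
from .measures import ProcessingProfile, turn_profile
from .segmentation import (DEFAULT_FTO_LIMIT_MS, DEFAULT_MAX_GAP_MS,
                           FloorTransfer, extract_floor_transfers, glue_turns,
                           strip_placeholders)
from .types import SpeakerMeta, Turn, WordToken

__all__ = ["CorpusAnalysis", "process_corpus"]


@dataclass
class CorpusAnalysis:
    turns_by_conv: Dict[str, List[Turn]]
    transfers: List[FloorTransfer]
    codes: List[SequenceCodes]
    t1_profiles: List[ProcessingProfile]
    t2_profiles: List[ProcessingProfile]
    features: pd.DataFrame
    drop_log: Dict[str, int]


def process_corpus(tokens_by_conv: Mapping[str, List[WordToken]],
                   lexicon: Mapping[Tuple[str, str], object],
                   unit_stats: Optional[pd.DataFrame] = None,
                   parses: Optional[Mapping[Tuple[str, int], list]] = None,
                   speakers: Optional[Mapping[str, SpeakerMeta]] = None,
                   scheme: Optional[ActScheme] = None,
                   max_gap_ms: float = DEFAULT_MAX_GAP_MS,
                   fto_limit_ms: float = DEFAULT_FTO_LIMIT_MS,
                   include_contained: bool = True,
                   placeholder_method: str = "lexical",
                   response: str = "raw") -> CorpusAnalysis:
    """Run the full analysis pipeline over a token corpus.

    ``parses`` maps (conversation_id, turn_index) to a list of bracketed
    trees, indexed by the glued turns' onset order. ``response`` selects
    the raw or placeholder-stripped FTO as the model response.
    """
    scheme = scheme or default_scheme()
    turns_by_conv: Dict[str, List[Turn]] = {}
    transfers: List[FloorTransfer] = []
    for conv in sorted(tokens_by_conv):
        turns = glue_turns(tokens_by_conv[conv], max_gap_ms=max_gap_ms)
        for i, turn in enumerate(turns):
            if parses is not None:
                turn.parses = list(parses.get((conv, i), []))
            if speakers is not None and turn.speaker_id in speakers:
                turn.speaker_sex = speakers[turn.speaker_id].sex
        turns_by_conv[conv] = turns
        transfers.extend(extract_floor_transfers(
            turns, fto_limit_ms=fto_limit_ms,
            include_contained=include_contained))
    if placeholder_method != "none":
        for tr in transfers:
            strip_placeholders(tr, method=placeholder_method)
    profile_cache: Dict[int, ProcessingProfile] = {}

    def prof(turn: Turn) -> ProcessingProfile:
        key = id(turn)
        if key not in profile_cache:
            profile_cache[key] = turn_profile(turn, lexicon, unit_stats)
        return profile_cache[key]

    codes = [code_transfer(tr, scheme) for tr in transfers]
    t1p = [prof(tr.t1) for tr in transfers]
    t2p = [prof(tr.t2) for tr in transfers]
    features, drop_log = build_feature_matrix(transfers, codes, t1p, t2p,
                                              response=response)
    return CorpusAnalysis(turns_by_conv=turns_by_conv, transfers=transfers,
                          codes=codes, t1_profiles=t1p, t2_profiles=t2p,
                          features=features, drop_log=drop_log)
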