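"""Turn gluing, floor transfer extraction, placeholder stripping."""

import numpy as np
import pytest

from turntaking import (FloorTransfer, WordToken, extract_floor_transfers,
                        glue_turns, strip_placeholders)
from turntaking.segmentation import is_placeholder

from conftest import make_token, make_turn


def _tokens(speaker, spans, **kw):
    return [make_token(speaker, s, e, orth=f"w{i}", **kw)
            for i, (s, e) in enumerate(spans)]


class TestGlueTurns:
    def test_single_token_single_turn(self):
        turns = glue_turns(_tokens("A", [(0, 100)]))
        assert len(turns) == 1 and len(turns[0].tokens) == 1

    def test_gap_threshold_is_strict(self):
        # gap of 179 ms glues; gap of exactly 180 ms splits
        glued = glue_turns(_tokens("A", [(0, 100), (279, 400)]))
        assert len(glued) == 1
        split = glue_turns(_tokens("A", [(0, 100), (280, 400)]))
        assert len(split) == 2

    def test_empty_input(self):
        assert glue_turns([]) == []

    def test_idempotent_on_existing_turns(self, rng):
        toks = _random_stream(rng, n=40)
        turns = glue_turns(toks)
        again = glue_turns([t for u in turns for t in u.tokens])
        assert [(u.start_ms, u.end_ms, u.speaker_id) for u in turns] == \
               [(u.start_ms, u.end_ms, u.speaker_id) for u in again]

    def test_monotone_in_gap_threshold(self, rng):
        toks = _random_stream(rng, n=60)
        counts = [len(glue_turns(toks, max_gap_ms=g))
                  for g in (50, 120, 180, 400, 1000)]
        assert counts == sorted(counts, reverse=True)

    def test_matches_interval_merging_oracle(self, rng):
        for _ in range(200):
            toks = _random_stream(rng, n=int(rng.integers(1, 25)))
            assert _turn_spans(glue_turns(toks)) == _oracle_spans(toks, 180.0)


def _random_stream(rng, n=20, speakers=("A", "B")):
    toks = []
    for spk in speakers:
        t = float(rng.uniform(0, 300))
        for _ in range(n):
            dur = float(rng.uniform(30, 600))
            toks.append(make_token(spk, t, t + dur))
            t += dur + float(rng.uniform(0, 500))
    return toks


def _turn_spans(turns):
    return sorted((u.speaker_id, u.start_ms, u.end_ms) for u in turns)


def _oracle_spans(tokens, gap):
    """Transitive closure of the pairwise 'gap < threshold' relation."""
    out = []
    for spk in {t.speaker_id for t in tokens}:
        toks = sorted([t for t in tokens if t.speaker_id == spk],
                      key=lambda t: t.start_ms)
        merged = [[toks[0]]]
        for a in toks[1:]:
            if a.start_ms - merged[-1][-1].end_ms < gap:
                merged[-1].append(a)
            else:
                merged.append([a])
        out += [(spk, m[0].start_ms, m[-1].end_ms) for m in merged]
    return sorted(out)


class TestExtractFloorTransfers:
    def test_gap_sign(self):
        t1 = make_turn("A", [(0, 1000)])
        t2 = make_turn("B", [(1200, 1500)])
        (tr,) = extract_floor_transfers([t1, t2])
        assert tr.fto_ms == 200

    def test_overlap_sign(self):
        t1 = make_turn("A", [(0, 1000)])
        t2 = make_turn("B", [(900, 1500)])
        (tr,) = extract_floor_transfers([t1, t2])
        assert tr.fto_ms == -100

    def test_beyond_limit_dropped_boundary_kept(self):
        t1 = make_turn("A", [(0, 1000)])
        far = make_turn("B", [(3301, 3500)])     # FTO = +2301 -> dropped
        edge = make_turn("B", [(3200, 3500)])    # FTO = +2200 -> kept
        assert extract_floor_transfers([t1, far]) == []
        assert len(extract_floor_transfers([t1, edge])) == 1

    def test_same_speaker_yields_no_transfer(self):
        t1 = make_turn("A", [(0, 500)])
        t2 = make_turn("A", [(900, 1200)])
        assert extract_floor_transfers([t1, t2]) == []

    def test_fewer_than_two_turns(self):
        assert extract_floor_transfers([make_turn("A", [(0, 500)])]) == []

    def test_turn_chain_shares_middle_turn(self):
        a1 = make_turn("A", [(0, 500)])
        b = make_turn("B", [(600, 900)])
        a2 = make_turn("A", [(1000, 1300)])
        trs = extract_floor_transfers([a1, b, a2])
        assert len(trs) == 2
        assert trs[0].t2 is b and trs[1].t1 is b

    def test_contained_flag_and_exclusion(self):
        a1 = make_turn("A", [(0, 2000)])
        bc = make_turn("B", [(500, 900)])        # fully inside A's turn
        a2 = make_turn("A", [(2150, 2400)])
        b2 = make_turn("B", [(2600, 2900)])
        trs = extract_floor_transfers([a1, bc, a2, b2])
        assert [tr.contained for tr in trs] == [True, False, False]
        # excluded backchannels do not become T1 of the next transfer,
        # and A1->A2 is a same-speaker pair, so only A2->B2 remains
        trs2 = extract_floor_transfers([a1, bc, a2, b2],
                                       include_contained=False)
        assert len(trs2) == 1 and trs2[0].t1 is a2 and trs2[0].t2 is b2

    def test_filter_conservation(self, rng):
        for _ in range(50):
            turns = glue_turns(_random_stream(rng, n=10))
            all_trs = extract_floor_transfers(turns, fto_limit_ms=np.inf)
            kept = extract_floor_transfers(turns, fto_limit_ms=2200)
            dropped = [t for t in all_trs if abs(t.fto_ms) > 2200]
            assert len(kept) + len(dropped) == len(all_trs)


class TestStripPlaceholders:
    def test_leading_placeholder_arithmetic(self):
        t1 = make_turn("A", [(0, 700)])
        t2 = make_turn("B", [(800, 950), (1100, 1300)], orths=["um", "yes"])
        tr = strip_placeholders(FloorTransfer(t1, t2))
        assert tr.fto_ms == 100
        assert tr.fto_stripped_ms == 400
        assert not tr.t2_all_placeholder

    def test_all_placeholder_t2_flagged(self):
        t1 = make_turn("A", [(0, 700)])
        t2 = make_turn("B", [(800, 950), (1000, 1200)], orths=["uh", "um"])
        tr = strip_placeholders(FloorTransfer(t1, t2))
        assert tr.t2_all_placeholder and tr.fto_stripped_ms is None

    def test_no_leading_placeholder_is_identity(self):
        t1 = make_turn("A", [(0, 700)])
        t2 = make_turn("B", [(800, 950)], orths=["sure"])
        tr = strip_placeholders(FloorTransfer(t1, t2))
        assert tr.fto_stripped_ms == tr.fto_ms

    def test_pos_method(self):
        t1 = make_turn("A", [(0, 700)])
        t2 = make_turn("B", [(800, 950), (1000, 1200)],
                       orths=["oh", "right"], pos=["UH", "RB"])
        tr = strip_placeholders(FloorTransfer(t1, t2), method="pos")
        assert tr.fto_stripped_ms == 300

    def test_lexical_test_strips_punctuation_case(self):
        tok = make_token("A", 0, 100, orth="Um,")
        assert is_placeholder(tok, "lexical")
        assert not is_placeholder(make_token("A", 0, 100, orth="umbrella"),
                                  "lexical")

    def test_stripped_never_below_raw(self, small_corpus):
        from turntaking import process_corpus
        ana = process_corpus(small_corpus.tokens_by_conv,
                             small_corpus.lexicon,
                             small_corpus.unit_stats, small_corpus.parses,
                             small_corpus.speakers)
        for tr in ana.transfers:
            if tr.fto_stripped_ms is not None:
                assert tr.fto_stripped_ms >= tr.fto_ms
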