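"""Per-turn processing measures: lexicon building, profiles, speech rate."""

import math

import numpy as np
import pandas as pd
import pytest

from turntaking import (WordToken, build_frequency_lexicon, lemmatize,
                        turn_profile, speech_rate_delta)
from turntaking.measures import coarse_pos, token_lemma
from turntaking.trees import parse_bracketed_tree
from turntaking.types import LexiconEntry

from conftest import make_token, make_turn


def make_turn_from(tokens):
    from turntaking import Turn
    return Turn(tokens)


@pytest.mark.parametrize("orth,pos,lemma", [
    ("cats", "NNS", "cat"),
    ("boxes", "NNS", "box"),
    ("ponies", "NNS", "pony"),
    ("cat", "NN", "cat"),
    ("glass", "NN", "glass"),
    ("running", "VBG", "run"),
    ("hoped", "VBD", "hope"),
    ("makes", "VBZ", "make"),
    ("tried", "VBD", "try"),
    ("telling", "VBG", "tell"),
    ("walks", "VBZ", "walk"),
    ("Quickly", "RB", "quickly"),
])
def test_lemmatize_deinflects_nouns_and_verbs(orth, pos, lemma):
    assert lemmatize(orth, pos) == lemma


def test_coarse_pos_families():
    assert coarse_pos("NNS") == "NN"
    assert coarse_pos("VBD") == "VB"
    assert coarse_pos("PRP$") == "PRP"
    assert coarse_pos("UH") == "UH"


class TestFrequencyLexicon:
    def test_inflection_collapses(self):
        toks = [make_token("A", 0, 100, orth="cats", pos="NNS"),
                make_token("A", 200, 300, orth="cat", pos="NN")]
        lex = build_frequency_lexicon({"c0": toks})
        assert lex[("cat", "NN")].frequency == 2
        assert len(lex) == 1

    def test_single_conversation_diversity(self):
        toks = [make_token("A", i * 200, i * 200 + 100, orth=w, pos="NN")
                for i, w in enumerate(["sun", "moon", "sun"])]
        lex = build_frequency_lexicon({"c0": toks})
        assert all(e.contextual_diversity == 1 for e in lex.values())

    def test_counts_match_brute_force_tally(self, rng):
        words = ["dog", "dogs", "run", "running", "blue"]
        pos = {"dog": "NN", "dogs": "NNS", "run": "VB", "running": "VBG",
               "blue": "JJ"}
        corpus = {}
        tally = {}
        for c in range(4):
            toks = []
            for i in range(30):
                w = str(rng.choice(words))
                toks.append(make_token("A", i * 200, i * 200 + 100,
                                       orth=w, pos=pos[w], conv=f"c{c}"))
                key = (lemmatize(w, pos[w]), coarse_pos(pos[w]))
                tally[key] = tally.get(key, 0) + 1
            corpus[f"c{c}"] = toks
        lex = build_frequency_lexicon(corpus)
        assert {k: e.frequency for k, e in lex.items()} == tally


def _lex(entries):
    return {(e.lemma, e.pos): e for e in entries}


SIMPLE_LEX = _lex([
    LexiconEntry("a", "NN", 10, concreteness=4.0, surprisal=2.0,
                 contextual_diversity=3),
    LexiconEntry("b", "NN", 30, concreteness=2.0, surprisal=2.0,
                 contextual_diversity=5),
    LexiconEntry("c", "NN", 60, concreteness=3.0, surprisal=2.0,
                 contextual_diversity=1),
])


class TestTurnProfile:
    def test_equal_surprisals_give_zero_uniformity(self):
        turn = make_turn("A", [(0, 100), (150, 250), (300, 400)],
                         orths=["a", "b", "c"], pos=["NN"] * 3)
        prof = turn_profile(turn, SIMPLE_LEX)
        assert prof.info_uniformity == 0.0
        assert prof.n_covered_words == 3

    def test_mean_absolute_deviation_by_hand(self):
        lex = _lex([LexiconEntry("a", "NN", 1, surprisal=1.0),
                    LexiconEntry("b", "NN", 1, surprisal=3.0)])
        turn = make_turn("A", [(0, 100), (150, 250)], orths=["a", "b"],
                         pos=["NN", "NN"])
        assert turn_profile(turn, lex).info_uniformity == 1.0

    def test_syntax_measures_from_parses(self):
        turn = make_turn("A", [(0, 100)], orths=["a"], pos=["NN"])
        turn.parses = [parse_bracketed_tree(
            "(S (NP (PRP I)) (VP (VBP agree) (SBAR (S (NP (PRP it)) "
            "(VP (VBZ works))))))")]
        prof = turn_profile(turn, SIMPLE_LEX)
        assert prof.n_clauses == 2 and prof.tree_height == 5

    def test_no_lexicon_hits_yields_absent_fields(self):
        turn = make_turn("A", [(0, 100)], orths=["zzz"], pos=["NN"])
        prof = turn_profile(turn, SIMPLE_LEX)
        assert prof.mean_concreteness is None
        assert prof.n_covered_words == 0

    def test_uniformity_scale_equivariance(self, rng):
        words = ["a", "b", "c"]
        for c in (0.5, 2.0, 7.0):
            base = _lex([LexiconEntry(w, "NN", 1, surprisal=s)
                         for w, s in zip(words, [1.0, 4.0, 6.5])])
            scaled = _lex([LexiconEntry(w, "NN", 1, surprisal=s * c)
                           for w, s in zip(words, [1.0, 4.0, 6.5])])
            turn = make_turn("A", [(0, 100), (150, 250), (300, 400)],
                             orths=words, pos=["NN"] * 3)
            assert turn_profile(turn, scaled).info_uniformity == pytest.approx(
                abs(c) * turn_profile(turn, base).info_uniformity)

    def test_log_frequency_invariant_under_corpus_duplication(self):
        turn = make_turn("A", [(0, 100), (150, 250)], orths=["a", "b"],
                         pos=["NN", "NN"])
        doubled = _lex([LexiconEntry(e.lemma, e.pos, 2 * e.frequency,
                                     e.concreteness, e.surprisal,
                                     e.contextual_diversity)
                        for e in SIMPLE_LEX.values()])
        f1 = turn_profile(turn, SIMPLE_LEX).mean_log_frequency
        f2 = turn_profile(turn, doubled).mean_log_frequency
        assert f1 == pytest.approx(f2)


class TestSpeechRate:
    UNIT_STATS = pd.DataFrame({"unit": ["a", "b"], "mean_ms": [100.0, 200.0],
                               "sd_ms": [10.0, 10.0]})

    def test_observed_equals_expected_gives_zero(self):
        turn = make_turn("A", [(0, 100), (150, 350)], orths=["a", "b"])
        assert speech_rate_delta(turn, self.UNIT_STATS) == pytest.approx(0.0)

    def test_twice_expected_gives_plus_one(self):
        turn = make_turn("A", [(0, 200), (250, 650)], orths=["a", "b"])
        assert speech_rate_delta(turn, self.UNIT_STATS) == pytest.approx(1.0)

    def test_unseen_unit_falls_back_to_global_mean(self):
        turn = make_turn("A", [(0, 150)], orths=["zzz"])
        assert speech_rate_delta(turn, self.UNIT_STATS) == pytest.approx(0.0)

    def test_empty_stats_rejected(self):
        turn = make_turn("A", [(0, 150)], orths=["a"])
        with pytest.raises(ValueError):
            speech_rate_delta(turn, pd.DataFrame({"unit": [], "mean_ms": []}))

    def test_uniformly_slower_speaker_recovered(self, small_corpus, rng):
        """Turns whose word durations are uniformly 1.5x the expected-table
        means come out with rate_delta = +0.5."""
        stats = small_corpus.unit_stats
        units = stats.sample(30, random_state=1)
        deltas = []
        for _ in range(10):
            sub = units.sample(8, random_state=int(rng.integers(1 << 30)))
            t, toks = 0.0, []
            for u, m in zip(sub["unit"], sub["mean_ms"]):
                toks.append(make_token("A", t, t + 1.5 * m, orth=str(u)))
                t += 1.5 * m + 50
            deltas.append(speech_rate_delta(make_turn_from(toks), stats))
        assert np.mean(deltas) == pytest.approx(0.5, abs=1e-9)
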