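"""Per-turn processing measures.

Computes the nine processing predictors for a hand-built turn: duration,
speech-rate delta, mean log frequency, concreteness, surprisal,
information uniformity, contextual diversity, syntax tree height and
clause count.
"""

import pandas as pd

from turntaking import Turn, WordToken, parse_bracketed_tree, turn_profile
from turntaking.types import LexiconEntry

lexicon = {
    ("i", "PRP"): LexiconEntry("i", "PRP", 9000, concreteness=1.5,
                               surprisal=3.0, contextual_diversity=300),
    ("think", "VB"): LexiconEntry("think", "VB", 2500, concreteness=2.1,
                                  surprisal=6.0, contextual_diversity=280),
    ("cat", "NN"): LexiconEntry("cat", "NN", 120, concreteness=4.9,
                                surprisal=11.0, contextual_diversity=40),
}
unit_stats = pd.DataFrame({"unit": ["i", "think", "cats"],
                           "mean_ms": [120.0, 300.0, 380.0],
                           "sd_ms": [30.0, 60.0, 70.0]})

turn = Turn([
    WordToken("demo", "A", "I", 0, 150, pos="PRP"),
    WordToken("demo", "A", "think", 200, 560, pos="VBP"),
    WordToken("demo", "A", "cats", 620, 1080, pos="NNS"),  # lemma "cat"
])
turn.parses = [parse_bracketed_tree(
    "(S (NP (PRP I)) (VP (VBP think) (SBAR (S (NP (NNS cats))))))")]

p = turn_profile(turn, lexicon, unit_stats)
print(f"duration           : {p.duration_ms:.0f} ms over {p.n_words} words")
print(f"rate delta         : {p.rate_delta:+.3f} "
      "(positive = slower than the corpus expectation)")
print(f"mean log frequency : {p.mean_log_frequency:.2f}")
print(f"mean concreteness  : {p.mean_concreteness:.2f} (1-5 scale)")
print(f"mean surprisal     : {p.mean_surprisal:.2f} bits")
print(f"info uniformity    : {p.info_uniformity:.2f} "
      "(mean |surprisal - turn mean|; 0 = perfectly even)")
print(f"contextual diversity: {p.mean_contextual_diversity:.0f} conversations")
print(f"tree height        : {p.tree_height} | clauses: {p.n_clauses}")
print(f"lexicon coverage   : {p.n_covered_words}/{p.n_words} words "
      "(inflected 'cats'/NNS matched as cat/NN)")
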