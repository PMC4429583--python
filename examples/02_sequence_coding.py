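"""Sequence-organization coding of floor transfers.

Codes question-answer pairs, backchannels and dispreferred responses
with the NXT dialog-act inventory: adjacency-pair status requires T2's
first act to be an expected next of T1's final act AND T1 to initiate
AND T2 to respond.
"""

from turntaking import (FloorTransfer, Turn, WordToken, code_transfer,
                        default_scheme, laughter_class)

scheme = default_scheme()
print(f"inventory: {len(scheme)} dialog acts")
r = scheme["yn-q"]
print(f"yn-q: initiating={r.initiating}, expected next = "
      f"{sorted(r.expected_next)}")


def turn(spk, act, start, end, laughter=False):
    return Turn([WordToken("demo", spk, "word", start, end,
                           dialog_act=act, laughter=laughter)])


pairs = [
    ("question -> answer     ", turn("A", "yn-q", 0, 800),
     turn("B", "yes", 1000, 1300)),
    ("question -> hedge      ", turn("A", "yn-q", 0, 800),
     turn("B", "hedge", 1000, 1300)),
    ("statement -> statement ", turn("A", "statement", 0, 800),
     turn("B", "statement", 1000, 1300)),
    ("statement -> backchannel", turn("A", "statement", 0, 800),
     turn("B", "backchannel", 900, 1100)),
]
for label, t1, t2 in pairs:
    sc = code_transfer(FloorTransfer(t1, t2), scheme)
    print(f"{label}: adjacency_pair={str(sc.adjacency_pair):5s} "
          f"preference={sc.preference:14s} t2_backchannel={sc.t2_backchannel}")

tr = FloorTransfer(turn("A", "statement", 0, 800, laughter=True),
                   turn("B", "apprec", 700, 1000, laughter=True))
print(f"laughter in both turns -> {laughter_class(tr)!r} (invited laughter)")
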