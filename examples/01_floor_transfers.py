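"""Floor transfer offsets from time-aligned words.

Builds a ten-second, two-speaker exchange by hand, glues the words into
turns (gap < 180 ms), extracts floor transfers, and strips turn-initial
placeholders. Positive FTOs are gaps, negative FTOs overlaps; the
stripped FTO is measured to the first non-placeholder word of T2.
"""

from turntaking import (WordToken, extract_floor_transfers, glue_turns,
                        strip_placeholders)


def tok(spk, orth, start, end):
    return WordToken("demo", spk, orth, start, end)


tokens = [
    # A asks a question; the two words glue into one turn (gap 120 ms)
    tok("A", "any", 0, 300), tok("A", "kids", 420, 800),
    # B hesitates ("um"), then answers; turn starts 150 ms after A's ends
    tok("B", "um", 950, 1200), tok("B", "two", 1320, 1570),
    # A appreciates in overlap (starts 120 ms before B finishes)
    tok("A", "oh", 1450, 1700), tok("A", "nice", 1750, 2050),
]

turns = glue_turns(tokens)
print(f"{len(tokens)} tokens -> {len(turns)} turns")
for i, turn in enumerate(turns):
    words = " ".join(t.orth for t in turn.tokens)
    print(f"  turn {i} [{turn.speaker_id}] {turn.start_ms:5.0f}-"
          f"{turn.end_ms:5.0f} ms: {words!r}")

print("\nfloor transfers:")
for tr in extract_floor_transfers(turns):
    strip_placeholders(tr)
    kind = "overlap" if tr.fto_ms < 0 else "gap"
    print(f"  {tr.t1.speaker_id}->{tr.t2.speaker_id}: "
          f"FTO = {tr.fto_ms:+5.0f} ms ({kind}), "
          f"placeholder-stripped = {tr.fto_stripped_ms:+5.0f} ms")
print("\nThe um-initial answer has a raw FTO of +150 ms but a stripped")
print("FTO of +520 ms: the hesitation held the floor for 370 ms.")
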