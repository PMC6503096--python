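"""Encode melodies as key-invariant relative-interval patterns.

An order-n pattern spans n+2 notes; every note after the first becomes its
semitone offset from the window's first note. Three classic five-note scale
descents encode to the three order-3 patterns found in all 32 Beethoven
piano sonatas.
"""

from meloinfo.encoding import encode, pattern_label
from meloinfo.score_io import MelodyLine

descents = [(72, 70, 69, 67, 65), (72, 70, 68, 67, 65), (72, 71, 69, 67, 66)]
for pitches in descents:
    stream = encode(MelodyLine(1, 1, pitches), order=3)
    ctx, nxt = stream.pairs[0]
    print(pitches, "->", pattern_label(ctx + (nxt,)))

# Transposition changes nothing: the same descent a fourth higher encodes
# identically, which is why the statistics track interval shape, not key.
up = tuple(p + 5 for p in descents[0])
print(up, "->", pattern_label(
    encode(MelodyLine(1, 1, up), 3).pairs[0][0]
    + (encode(MelodyLine(1, 1, up), 3).pairs[0][1],)
))
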