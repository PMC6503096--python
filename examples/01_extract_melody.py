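"""Extract the highest-pitch melody line from a small MusicXML score.

Builds a two-chord, one-grace-note measure in memory, reads it, and shows
how chord tones collapse to the top voice and grace notes drop out.
"""

from meloinfo.score_io import extract_highest_line, read_movement

XML = b"""<?xml version="1.0"?>
<score-partwise version="3.1">
  <part-list><score-part id="P1"><part-name>Demo</part-name></score-part></part-list>
  <part id="P1"><measure number="1">
    <attributes><divisions>1</divisions></attributes>
    <note><pitch><step>C</step><octave>4</octave></pitch><duration>1</duration></note>
    <note><chord/><pitch><step>E</step><octave>4</octave></pitch><duration>1</duration></note>
    <note><chord/><pitch><step>G</step><octave>4</octave></pitch><duration>1</duration></note>
    <note><grace/><pitch><step>B</step><octave>5</octave></pitch></note>
    <note><pitch><step>F</step><octave>4</octave></pitch><duration>1</duration></note>
  </measure></part>
</score-partwise>
"""

events = read_movement(XML)
print("events (pitch, grace):", [(e.pitch, e.grace) for e in events])

line = extract_highest_line(events, piece_no=1, movement_no=1)
print("melody line:", line.pitches)
# The C4/E4/G4 chord keeps only G4 (67); the grace B5 is excluded entirely,
# so the line is G4 then F4 - the top sounding pitch at each onset.
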