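"""Mine the phrases that occur in every piece of a corpus.

Generates a small synthetic corpus with three planted order-2 patterns and
recovers them (plus whatever else happens to be ubiquitous). Also shows the
packaged reference inventory for the 32-sonata corpus.
"""

from meloinfo.encoding import encode
from meloinfo.familiar import find_ubiquitous, load_reference_patterns
from meloinfo.markov import estimate_table
from meloinfo.simulate import beethoven_like, build_scenario

corpus = build_scenario(beethoven_like(seed=7, notes_per_movement=500))
tables = {}
for (piece, _), line in corpus.movements.items():
    tables.setdefault(piece, []).append(estimate_table(encode(line, 2)))

phrase_set = find_ubiquitous(tables, order=2)
print(f"{len(phrase_set.patterns)} order-2 patterns occur in all {len(tables)} pieces:")
print("  ", " ".join(phrase_set.labels()))
some_piece = min(phrase_set.per_piece_mean_tp)
print(f"piece {some_piece} mean familiar TP = {phrase_set.per_piece_mean_tp[some_piece]:.3f}")

print("\nreference inventory sizes (32 Beethoven piano sonatas):")
patterns = load_reference_patterns(warn=lambda msg: print("  note:", msg))
for order, plist in sorted(patterns.items()):
    print(f"  order {order}: {len(plist)} patterns")
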