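"""Transition probabilities, surprisal, entropy, and mutual information.

Estimates an order-1 transition table from a toy melody and prints the
three information measures the lifetime analysis tracks per piece.
"""

from meloinfo.encoding import encode
from meloinfo.markov import (
    conditional_entropy,
    estimate_table,
    information_content,
    mutual_information,
)
from meloinfo.score_io import MelodyLine

# an alternating figure with an occasional leap
line = MelodyLine(1, 1, (60, 62, 60, 62, 60, 62, 67, 62, 60, 62, 60, 62))
table = estimate_table(encode(line, order=1))

tp = table.conditional_probability((2,), 0)
print(f"TP(offset 0 | context +2) = {tp:.3f}")
print(f"surprisal of that transition = {information_content(tp):.3f} bits")
print(f"conditional entropy H(next|context) = {conditional_entropy(table):.3f} bits")
print(f"mutual information = {mutual_information(table):.3f} bits")
# Low entropy means the melody is predictable from one preceding interval;
# the MI is the share of next-note uncertainty the context removes.
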