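"""Score a test alignment against a reference with the sum-of-pairs metric.

The SP score counts residue pairs: of all pairs of residues placed in one
column by the reference, the fraction the test alignment also puts
together.  Here the "test" deliberately shifts one sequence to show how
the score reacts.
"""

from memsa import Alignment, sp_score

reference = Alignment([
    ("s1", "MKLV-AF"),
    ("s2", "MKLVQAF"),
    ("s3", "M-LVQAF"),
])

perfect = sp_score(reference, reference)
print(f"reference vs itself:      SP = {perfect:.3f}   (always 1.0)")

shifted = Alignment([
    ("s1", "MKLV-AF-"),
    ("s2", "MKLVQAF-"),
    ("s3", "-M-LVQAF"),
])
partial = sp_score(shifted, reference)
print(f"third sequence shifted:   SP = {partial:.3f}   "
      "(s3's pairs are lost, s1-s2 pairs survive)")
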