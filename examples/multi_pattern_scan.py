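"""Locate several patterns in one text pass with the Wu-Manber matcher.

The matcher preprocesses the pattern set into SHIFT/HASH/PREFIX tables and
skips ahead by block, which is how the aligner re-locates region strings
inside their source sequence when stitching region alignments together.
"""

from memsa import build_tables, locate_anchors, scan

patterns = ["GPCR", "KDEL", "RGD"]
text = "MRGDLLKDELSSGPCRTTKDELA"

tables = build_tables(patterns, block_size=2)
print(f"match window m = {tables.m}, default shift = {tables.default_shift}")

for hit in scan(tables, text):
    p = patterns[hit.pattern_index]
    print(f"  {p!r} at position {hit.text_position} "
          f"(text[{hit.text_position}:{hit.text_position + len(p)}])")

# stitching use-case: region strings sliced from a sequence are re-anchored
regions = ["MRGD", "LLKDELSS", "GPCRTTKDELA"]
starts = locate_anchors(regions, text)
print(f"\nregion anchors {starts} tile the sequence contiguously")
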