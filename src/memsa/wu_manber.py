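"""Wu-Manber multi-pattern exact string matching.

The matcher preprocesses the pattern set into three tables over character
blocks of size S (2 or 3):

* SHIFT — how far the scan window may jump when its last block cannot end
  a pattern prefix of length m (m = the shortest pattern length);
* HASH — for blocks that can end such a prefix (shift 0), the candidate
  patterns to verify;
* PREFIX — each candidate's first S characters, checked before the full
  comparison to discard most candidates cheaply.

Blocks are addressed by their literal string (a dict), which preserves the
algorithm's shift/filter/verify behaviour while making hash collisions a
non-issue.  Patterns shorter than S cannot index the tables and are found
by a naive scan merged into the results.

The aligner uses this matcher to re-locate region strings inside their
source sequence when stitching region alignments back together.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import NamedTuple


class MatchHit(NamedTuple):
    pattern_index: int
    text_position: int


@dataclass
class WuManberTables:
    """Preprocessed SHIFT/HASH/PREFIX structures for one pattern set."""

    patterns: list[str]
    block_size: int
    m: int  # match-window width = shortest tabled pattern length (0 if none)
    shift: dict[str, int]
    hash: dict[str, list[int]]
    prefix: dict[int, str]
    fallback: list[int]  # indices of patterns shorter than the block size
    default_shift: int = 0


def build_tables(patterns: list[str], block_size: int = 2) -> WuManberTables:
    """Preprocess a pattern set into Wu-Manber tables.

    The match window m is the shortest length among patterns of length >=
    block size.  A block ending at 0-based position j within a pattern's
    first m characters gets SHIFT m-1-j; blocks that end no prefix get the
    default shift m - S.  Blocks with shift 0 gain a HASH entry listing the
    candidate patterns, each with its PREFIX (first S characters).
    """
    if block_size not in (2, 3):
        raise ValueError("block size must be 2 or 3")
    if not patterns:
        raise ValueError("empty pattern list")
    for p in patterns:
        if not p:
            raise ValueError("empty string pattern")

    tabled = [i for i, p in enumerate(patterns) if len(p) >= block_size]
    fallback = [i for i, p in enumerate(patterns) if len(p) < block_size]
    if not tabled:
        return WuManberTables(patterns, block_size, 0, {}, {}, {}, fallback, 0)

    m = min(len(patterns[i]) for i in tabled)
    s = block_size
    shift: dict[str, int] = {}
    hash_table: dict[str, list[int]] = defaultdict(list)
    prefix: dict[int, str] = {}
    for idx in tabled:
        p = patterns[idx]
        for j in range(s - 1, m):  # j = end position of the block within p[:m]
            block = p[j - s + 1 : j + 1]
            value = m - 1 - j
            if block not in shift or value < shift[block]:
                shift[block] = value
        tail = p[m - s : m]
        hash_table[tail].append(idx)
        prefix[idx] = p[:s]
    return WuManberTables(
        patterns, s, m, shift, dict(hash_table), prefix, fallback, m - s
    )


def _naive_indices(pattern: str, text: str) -> list[int]:
    hits = []
    start = text.find(pattern)
    while start != -1:
        hits.append(start)
        start = text.find(pattern, start + 1)
    return hits


def scan(tables: WuManberTables, text: str) -> list[MatchHit]:
    """Find every occurrence of every pattern in the text.

    Hits are sorted by (text position, pattern index).  Fallback patterns
    (shorter than the block size) are located naively and merged in.
    """
    hits: list[MatchHit] = []
    s, m = tables.block_size, tables.m
    if m >= s:
        pos = m - 1  # index of the window's last character
        n = len(text)
        while pos < n:
            block = text[pos - s + 1 : pos + 1]
            jump = tables.shift.get(block, tables.default_shift)
            if jump > 0:
                pos += jump
                continue
            window_start = pos - m + 1
            for idx in tables.hash.get(block, ()):
                p = tables.patterns[idx]
                if text.startswith(tables.prefix[idx], window_start) and text.startswith(
                    p, window_start
                ):
                    hits.append(MatchHit(idx, window_start))
            pos += 1
    for idx in tables.fallback:
        hits.extend(
            MatchHit(idx, at) for at in _naive_indices(tables.patterns[idx], text)
        )
    hits.sort(key=lambda h: (h.text_position, h.pattern_index))
    return hits


def locate_anchors(region_strings: list[str], full_sequence: str) -> list[int]:
    """Re-locate ordered region strings as a contiguous tiling of a sequence.

    The regions were sliced from the sequence, so a consistent chain of
    matches — strictly increasing starts with each region beginning where
    the previous one ends — must exist; the leftmost such chain is
    returned (one 0-based start per region, empty regions included at
    their implied offset).  Raises ``ValueError`` if no chain exists,
    which indicates corrupted segmentation upstream.
    """
    nonempty = [(i, r) for i, r in enumerate(region_strings) if r]
    if not nonempty:
        if region_strings and full_sequence:
            raise ValueError("no consistent anchor chain (all regions empty)")
        return [0] * len(region_strings)

    tables = build_tables([r for _, r in nonempty])
    occurrences: dict[int, set[int]] = {i: set() for i, _ in nonempty}
    for idx, at in scan(tables, full_sequence):
        occurrences[nonempty[idx][0]].add(at)

    # Offsets of each region relative to the start of the tiling.
    offsets = []
    total = 0
    for r in region_strings:
        offsets.append(total)
        total += len(r)
    if total != len(full_sequence):
        raise ValueError("region strings do not tile the full sequence length")

    first_idx, first_region = nonempty[0]
    for cand in sorted(occurrences[first_idx]):
        base = cand - offsets[first_idx]
        if base < 0:
            continue
        if all(base + offsets[i] in occurrences[i] for i, _ in nonempty):
            # regions tile, so only base = 0 can succeed; keep the general
            # chain check anyway as the corruption guard.
            return [base + off for off in offsets]
    raise ValueError("no consistent anchor chain for region strings")
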