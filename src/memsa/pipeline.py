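"""End-to-end region-aware progressive alignment workflow.

The driver: predict (or import) topology, slice each sequence into loop and
TM region strings, group sequences by TM count and take the largest group
as the *dominant class*, align each region slot independently across the
dominant class with progressive DP over one shared UPGMA guide tree, stitch
the slot alignments back into a full-length seed alignment (verifying with
the multi-pattern matcher that every member's regions still tile its
sequence), then merge the remaining off-class sequences onto the seed
profile one at a time.  Also provides the sum-of-pairs (SP) accuracy score
against a reference alignment, the per-column consensus, and the TM-Info
region report.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .align_core import (
    GuideTree,
    Profile,
    build_distance_matrix,
    kmer_distance,
    profile_align,
    progressive_align,
    upgma,
)
from .score_model import GapModel, SubstitutionMatrix, load_matrix
from .seqio import GAP, Alignment, SequenceRecord
from .topology import (
    INSIDE,
    OUTSIDE,
    TMHELIX,
    SegmentedSequence,
    TopologyAnnotation,
    TopologyPredictorParams,
    TopologySegment,
    classify_by_tm_count,
    predict_topology,
    segment_sequence,
)

logger = logging.getLogger("memsa")

TM_LABEL = "TM"
LOOP_LABEL = "loop"
MIXED_LABEL = "mixed"


@dataclass
class AlignConfig:
    """Aligner configuration with the published defaults.

    By default TM regions are scored with PHAT and loop regions with
    BLOSUM62; setting ``matrix`` forces one matrix everywhere.  Gap
    penalties default to open 8, extend 1.  ``max_seqs`` mirrors the
    historical server-load cap and is not an algorithmic limit (0 disables
    it).
    """

    matrix: str | None = None
    tm_matrix: str = "PHAT"
    loop_matrix: str = "BLOSUM62"
    gap_open: int = 8
    gap_extend: int = 1
    predictor: TopologyPredictorParams = field(default_factory=TopologyPredictorParams)
    max_seqs: int = 5000
    kmer_k: int = 3

    @property
    def resolved_tm_matrix(self) -> str:
        return (self.matrix or self.tm_matrix).upper()

    @property
    def resolved_loop_matrix(self) -> str:
        return (self.matrix or self.loop_matrix).upper()

    @property
    def gaps(self) -> GapModel:
        return GapModel(self.gap_open, self.gap_extend)

    def echo(self) -> dict:
        """The effective parameters, for logging and result provenance."""
        return {
            "tm_matrix": self.resolved_tm_matrix,
            "loop_matrix": self.resolved_loop_matrix,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "window": self.predictor.window,
            "threshold": self.predictor.threshold,
            "min_helix_len": self.predictor.min_helix_len,
            "max_helix_len": self.predictor.max_helix_len,
            "max_seqs": self.max_seqs,
            "kmer_k": self.kmer_k,
        }


@dataclass
class RegionBlockSet:
    """Per-slot alignments for the dominant class: loop0, TM1, loop1, ... loopK."""

    labels: list[str]  # TM_LABEL or LOOP_LABEL per slot, topology order
    blocks: list[Alignment]
    member_ids: list[str]


@dataclass
class TMAlignResult:
    """Full result bundle of one aligner run."""

    alignment: Alignment
    consensus: str
    tm_info: pd.DataFrame
    tree: GuideTree | None
    params: dict
    dominant_tm_count: int
    seed_alignment: Alignment | None
    segmented: list[SegmentedSequence]

    @property
    def column_labels(self) -> list[str] | None:
        return self.alignment.column_labels


# ---------------------------------------------------------------------------
# Scoring / reporting operations
# ---------------------------------------------------------------------------

def consensus(alignment: Alignment, majority_fraction: float = 0.5) -> str:
    """Per-column majority symbol (gap included), 'X' when no majority.

    A symbol wins a column only when its frequency strictly exceeds
    ``majority_fraction``; count ties prefer residues over the gap symbol,
    then alphabetical order.
    """
    n = len(alignment.rows)
    out = []
    for j in range(alignment.width):
        counts = Counter(row[j] for _, row in alignment.rows)
        symbol, count = min(counts.items(), key=lambda kv: (-kv[1], kv[0] == GAP, kv[0]))
        out.append(symbol if count / n > majority_fraction else "X")
    return "".join(out)


def _residue_columns(alignment: Alignment) -> dict[str, list[int]]:
    """Per row: the alignment column of each residue, in residue order."""
    out: dict[str, list[int]] = {}
    for rid, row in alignment.rows:
        out[rid] = [j for j, c in enumerate(row) if c != GAP]
    return out


def sp_score(test: Alignment, reference: Alignment) -> float:
    """Fraction of reference-aligned residue pairs recovered by the test.

    Over every pair of sequences and every reference column in which both
    have residues, the residue pair counts toward the denominator; it
    counts toward the numerator when the same two residues share a column
    in the test alignment.  Columns with gaps contribute only their
    residue-residue pairs.
    """
    if set(test.ids) != set(reference.ids):
        raise ValueError("test and reference alignments have different ids")
    for rid in reference.ids:
        if test.degapped(rid) != reference.degapped(rid):
            raise ValueError(f"degapped residues differ for {rid!r}")

    test_cols = _residue_columns(test)
    ref_ids = reference.ids
    ref_rows = dict(reference.rows)
    residue_counter = {rid: 0 for rid in ref_ids}
    num = denom = 0
    for j in range(reference.width):
        present: list[tuple[str, int]] = []
        for rid in ref_ids:
            if ref_rows[rid][j] != GAP:
                present.append((rid, residue_counter[rid]))
                residue_counter[rid] += 1
        for x in range(len(present)):
            rid_x, rx = present[x]
            col_x = test_cols[rid_x][rx]
            for y in range(x + 1, len(present)):
                rid_y, ry = present[y]
                denom += 1
                if col_x == test_cols[rid_y][ry]:
                    num += 1
    if denom == 0:
        raise ValueError("reference alignment has no aligned residue pairs")
    return num / denom


def tm_info(segmented: Sequence[SegmentedSequence]) -> pd.DataFrame:
    """Per-sequence region report: label, 1-based coordinates, length, substring."""
    rows = []
    for seg in segmented:
        for k, s in enumerate(seg.annotation.segments):
            rows.append(
                {
                    "record_id": seg.record.id,
                    "tm_count": seg.tm_count,
                    "segment": k + 1,
                    "label": s.label,
                    "start": s.start + 1,
                    "end": s.end,
                    "length": s.length,
                    "sequence": seg.record.residues[s.start : s.end],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "record_id", "tm_count", "segment", "label",
            "start", "end", "length", "sequence",
        ],
    )


# ---------------------------------------------------------------------------
# Region blocks and stitching
# ---------------------------------------------------------------------------

def _slot_strings(seg: SegmentedSequence, n_helices: int) -> list[str]:
    """A member's 2K+1 region substrings; missing terminal loops become ''."""
    slots: list[str] = []
    regions = list(seg.region_strings)
    i = 0
    for slot in range(2 * n_helices + 1):
        want_tm = slot % 2 == 1
        if i < len(regions) and (regions[i][0] == TMHELIX) == want_tm:
            slots.append(regions[i][1])
            i += 1
        elif want_tm:
            raise ValueError(
                f"{seg.record.id!r}: expected TM helix at region slot {slot}"
            )
        else:
            slots.append("")
    if i != len(regions):
        raise ValueError(f"{seg.record.id!r}: region count does not match TM count")
    return slots


def _harmonize_tm_boundaries(
    dominant: list[SegmentedSequence],
    tree: GuideTree | None,
    config: AlignConfig,
) -> list[SegmentedSequence]:
    """Make helix boundary calls consistent across the dominant class.

    Per-sequence hydropathy prediction places each boundary independently,
    so homologous helices often differ by a residue or two of trim or
    overhang between members; region-wise alignment then puts those edge
    residues in different region slots, where they can never be aligned.
    Because TM helices are conserved blocks within a family, the class
    itself is the best boundary evidence: each TM slot is pre-aligned
    semi-globally, the majority-occupancy column window is taken as the
    family's helix extent, and every member's boundaries are adjusted to
    that window — residues outside it are pushed back into the flanking
    loops, and gap columns inside it pull the adjacent loop residues in
    (never emptying an interior loop).  Purely deterministic; uses only
    the members themselves.
    """
    if len(dominant) < 2:
        return dominant
    n_helices = dominant[0].tm_count
    if n_helices == 0:
        return dominant
    gaps = config.gaps
    tm_mat = load_matrix(config.resolved_tm_matrix)
    per_member = [_slot_strings(seg, n_helices) for seg in dominant]
    ids = [seg.record.id for seg in dominant]
    lens = [[len(s) for s in strings] for strings in per_member]
    n = len(dominant)

    for k in range(n_helices):
        slot = 2 * k + 1
        items = [(rid, strings[slot]) for rid, strings in zip(ids, per_member)]
        aln = progressive_align(items, tree, tm_mat, gaps, free_ends=True)
        rows = dict(aln.rows)
        occupancy = [
            sum(rows[rid][j] != GAP for rid in ids) for j in range(aln.width)
        ]
        core = [j for j, occ in enumerate(occupancy) if occ * 2 > n]
        if not core:
            continue
        jlo, jhi = core[0], core[-1] + 1
        for m, rid in enumerate(ids):
            row = rows[rid]
            push_left = sum(c != GAP for c in row[:jlo])
            push_right = sum(c != GAP for c in row[jhi:])
            window = row[jlo:jhi]
            first = next((x for x, c in enumerate(window) if c != GAP), len(window))
            last = next((x for x, c in enumerate(reversed(window)) if c != GAP), len(window))
            pull_left = first
            pull_right = last
            # pulls are limited by the flanking loop (interior loops keep
            # >= 1 residue so helices never become adjacent)
            left_keep = 1 if slot - 1 > 0 else 0
            right_keep = 1 if slot + 1 < 2 * n_helices else 0
            pull_left = min(pull_left, max(0, lens[m][slot - 1] + push_left - left_keep))
            pull_right = min(pull_right, max(0, lens[m][slot + 1] + push_right - right_keep))
            new_helix = lens[m][slot] + pull_left + pull_right - push_left - push_right
            if new_helix < 1:  # degenerate call; leave this member's helix alone
                continue
            lens[m][slot - 1] += push_left - pull_left
            lens[m][slot] = new_helix
            lens[m][slot + 1] += push_right - pull_right

    out: list[SegmentedSequence] = []
    for m, seg in enumerate(dominant):
        if lens[m] == [len(s) for s in per_member[m]]:
            out.append(seg)
            continue
        segments = []
        pos = 0
        n_loops = 0
        for slot, length in enumerate(lens[m]):
            if length <= 0:
                if slot % 2 == 0:
                    n_loops += 1
                continue
            if slot % 2 == 1:
                label = TMHELIX
            else:
                label = OUTSIDE if n_loops % 2 == 0 else INSIDE
                n_loops += 1
            segments.append(TopologySegment(label, pos, pos + length))
            pos += length
        annotation = TopologyAnnotation(seg.record.id, segments)
        out.append(segment_sequence(seg.record, annotation))
    return out


def build_region_blocks(
    dominant: list[SegmentedSequence],
    tree: GuideTree | None,
    config: AlignConfig,
) -> RegionBlockSet:
    """Align each region slot independently across the dominant class."""
    n_helices = dominant[0].tm_count
    gaps = config.gaps
    tm_mat = load_matrix(config.resolved_tm_matrix)
    loop_mat = load_matrix(config.resolved_loop_matrix)
    per_member = [_slot_strings(seg, n_helices) for seg in dominant]
    ids = [seg.record.id for seg in dominant]

    labels: list[str] = []
    blocks: list[Alignment] = []
    for slot in range(2 * n_helices + 1):
        is_tm = slot % 2 == 1
        labels.append(TM_LABEL if is_tm else LOOP_LABEL)
        items = [(rid, strings[slot]) for rid, strings in zip(ids, per_member)]
        if len(items) == 1:
            blocks.append(Alignment(items))
        else:
            matrix = tm_mat if is_tm else loop_mat
            # TM slots are aligned semi-globally: helix boundary calls can
            # disagree by a residue or two between members, and free end
            # gaps let the DP recover the shared register instead of
            # forcing an off-register gapless alignment.  Loop slots stay
            # global: their length variation is genuine indel history.
            blocks.append(
                progressive_align(items, tree, matrix, gaps, free_ends=is_tm)
            )
    return RegionBlockSet(labels, blocks, ids)


def stitch(
    blocks: RegionBlockSet, segmented: Sequence[SegmentedSequence]
) -> Alignment:
    """Concatenate slot alignments into the full-length seed alignment.

    Before concatenation, each member's degapped slot rows are re-located
    inside its original sequence with the multi-pattern matcher; they must
    form a contiguous left-to-right tiling, guaranteeing that no TM helix
    was disrupted by the region-wise stage.
    """
    from .wu_manber import locate_anchors

    by_id = {seg.record.id: seg for seg in segmented}
    for rid in blocks.member_ids:
        regions = [blk.degapped(rid) for blk in blocks.blocks]
        starts = locate_anchors(regions, by_id[rid].record.residues)
        if any(b - a != len(r) for a, b, r in zip(starts, starts[1:], regions)):
            raise ValueError(f"anchor chain for {rid!r} is not contiguous")

    rows = [
        (rid, "".join(blk.row(rid) for blk in blocks.blocks))
        for rid in blocks.member_ids
    ]
    labels: list[str] = []
    for label, blk in zip(blocks.labels, blocks.blocks):
        labels.extend([label] * blk.width)
    out = Alignment(rows, labels)
    out.check_roundtrip([by_id[rid].record for rid in blocks.member_ids])
    return out


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def _merge_off_class(
    seed: Alignment,
    off_class: list[SegmentedSequence],
    matrix: SubstitutionMatrix,
    config: AlignConfig,
) -> tuple[Profile, list[str]]:
    """Merge off-class sequences onto the seed profile, nearest first.

    Each sequence is aligned to the current profile as a whole; only whole
    gap columns enter the seed, so relative gap placement among seed
    columns is never modified.  Columns introduced here are labelled
    ``mixed``.
    """
    profile = Profile.from_alignment(seed)
    labels = list(seed.column_labels or [LOOP_LABEL] * seed.width)
    anchor = consensus(seed).replace(GAP, "").replace("X", "") or seed.rows[0][1].replace(GAP, "")
    ranked = sorted(
        enumerate(off_class),
        key=lambda item: (
            kmer_distance(item[1].record.residues, anchor, config.kmer_k),
            item[0],
        ),
    )
    for _, seg in ranked:
        result = profile_align(
            profile,
            Profile.from_sequence(seg.record.id, seg.record.residues),
            matrix,
            config.gaps,
        )
        new_labels: list[str] = []
        pos = 0
        for op in result.ops:
            if op == "L":
                new_labels.append(MIXED_LABEL)
            else:
                new_labels.append(labels[pos])
                pos += 1
        profile, labels = result.profile, new_labels
    return profile, labels


def align_tm(
    records: Sequence[SequenceRecord],
    config: AlignConfig | None = None,
    topologies: Mapping[str, TopologyAnnotation] | None = None,
) -> TMAlignResult:
    """Run the full region-aware alignment workflow on unaligned records.

    ``topologies`` (parsed from an annotation file) overrides the built-in
    hydropathy predictor when supplied and must then cover every input id.
    """
    if config is None:
        config = AlignConfig()
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    if 0 < config.max_seqs < len(records):
        raise ValueError(
            f"{len(records)} sequences exceed max_seqs={config.max_seqs}"
        )
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")

    if topologies is not None:
        missing = [r.id for r in records if r.id not in topologies]
        if missing:
            raise ValueError(f"topology annotation missing for: {', '.join(missing)}")
        annotations = {r.id: topologies[r.id] for r in records}
    else:
        annotations = {r.id: predict_topology(r, config.predictor) for r in records}

    segmented = [segment_sequence(r, annotations[r.id]) for r in records]
    groups, dominant_count = classify_by_tm_count(segmented)
    logger.info(
        "classified %d sequences into %d TM-count groups; dominant count %d (%d members)",
        len(records), len(groups), dominant_count, len(groups[dominant_count]),
    )

    if dominant_count == 0:
        logger.warning(
            "no transmembrane helices in the dominant class; falling back to "
            "plain progressive alignment"
        )
        tree = upgma(build_distance_matrix(records, config.kmer_k))
        matrix = load_matrix(config.resolved_loop_matrix)
        aln = progressive_align(records, tree, matrix, config.gaps)
        aln = Alignment(aln.rows, [LOOP_LABEL] * aln.width).strip_all_gap_columns()
        aln.check_roundtrip(records)
        return TMAlignResult(
            alignment=aln,
            consensus=consensus(aln),
            tm_info=tm_info(segmented),
            tree=tree,
            params=config.echo(),
            dominant_tm_count=0,
            seed_alignment=None,
            segmented=segmented,
        )

    dominant = groups[dominant_count]
    off_class = [seg for seg in segmented if seg.tm_count != dominant_count]
    tree = (
        upgma(build_distance_matrix(dominant, config.kmer_k))
        if len(dominant) >= 2
        else None
    )

    dominant = _harmonize_tm_boundaries(dominant, tree, config)
    harmonized = {seg.record.id: seg for seg in dominant}
    segmented = [harmonized.get(seg.record.id, seg) for seg in segmented]
    blocks = build_region_blocks(dominant, tree, config)
    seed = stitch(blocks, dominant)
    logger.info(
        "seed alignment: %d members, %d region slots, width %d",
        len(dominant), len(blocks.blocks), seed.width,
    )

    if off_class:
        merge_matrix = load_matrix(config.resolved_tm_matrix)
        profile, labels = _merge_off_class(seed, off_class, merge_matrix, config)
        full = profile.to_alignment(labels)
    else:
        full = seed

    row_map = dict(full.rows)
    ordered = Alignment([(rid, row_map[rid]) for rid in ids], full.column_labels)
    final = ordered.strip_all_gap_columns()
    final.check_roundtrip(records)
    logger.info("final alignment: %d rows, width %d", len(final.rows), final.width)

    return TMAlignResult(
        alignment=final,
        consensus=consensus(final),
        tm_info=tm_info(segmented),
        tree=tree,
        params=config.echo(),
        dominant_tm_count=dominant_count,
        seed_alignment=seed,
        segmented=segmented,
    )
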