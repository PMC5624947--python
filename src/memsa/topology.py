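"""Transmembrane topology: prediction, segmentation, and TM-count classification.

A membrane protein's topology assigns every residue to one of three region
classes: ``inside`` (cytoplasmic loop), ``TMhelix`` (membrane-spanning
alpha helix) or ``outside`` (non-cytoplasmic loop).  The aligner needs only
the segment boundaries; it treats the two loop classes symmetrically.

Topology can come from two sources: an imported annotation file (see
:mod:`memsa.seqio`) or the built-in hydropathy predictor in this module,
which slides a Kyte-Doolittle window along the sequence and calls maximal
high-hydropathy runs as helices.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

if TYPE_CHECKING:  # pragma: no cover
    from .seqio import SequenceRecord

INSIDE = "inside"
TMHELIX = "TMhelix"
OUTSIDE = "outside"
LABELS = frozenset({INSIDE, TMHELIX, OUTSIDE})

# X (unknown residue) is treated as hydropathy-neutral.
_KD = dict(KYTE_DOOLITTLE)
_KD["X"] = 0.0


@dataclass(frozen=True)
class TopologySegment:
    """One contiguous region: ``label`` over ``[start, end)`` (0-based, half-open)."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown topology label {self.label!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid segment bounds [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TopologyAnnotation:
    """Ordered segments tiling a sequence contiguously.

    Invariants (checked on construction): segments start at 0, are contiguous
    and non-overlapping, and no two adjacent segments share a label (adjacent
    same-label segments are merged by :meth:`from_segments`).
    """

    record_id: str
    segments: list[TopologySegment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"annotation for {self.record_id!r} has no segments")
        if self.segments[0].start != 0:
            raise ValueError(
                f"annotation for {self.record_id!r} does not start at the first residue"
            )
        for prev, cur in zip(self.segments, self.segments[1:]):
            if cur.start != prev.end:
                raise ValueError(
                    f"annotation for {self.record_id!r}: coverage gap or overlap "
                    f"at position {prev.end}"
                )
            if cur.label == prev.label:
                raise ValueError(
                    f"annotation for {self.record_id!r}: adjacent segments share "
                    f"label {cur.label!r} (merge them)"
                )

    @classmethod
    def from_segments(
        cls, record_id: str, segments: list[TopologySegment]
    ) -> "TopologyAnnotation":
        """Build an annotation, merging adjacent segments with equal labels."""
        merged: list[TopologySegment] = []
        for seg in sorted(segments, key=lambda s: s.start):
            if merged and merged[-1].label == seg.label and merged[-1].end == seg.start:
                merged[-1] = TopologySegment(seg.label, merged[-1].start, seg.end)
            else:
                merged.append(seg)
        return cls(record_id, merged)

    @property
    def length(self) -> int:
        return self.segments[-1].end

    @property
    def tm_count(self) -> int:
        return sum(1 for s in self.segments if s.label == TMHELIX)

    def tm_segments(self) -> list[TopologySegment]:
        return [s for s in self.segments if s.label == TMHELIX]


@dataclass
class SegmentedSequence:
    """A sequence decomposed into its region substrings, in topology order."""

    record: "SequenceRecord"
    annotation: TopologyAnnotation
    region_strings: list[tuple[str, str]]

    @property
    def tm_count(self) -> int:
        return self.annotation.tm_count


@dataclass(frozen=True)
class TopologyPredictorParams:
    """Hydropathy-window predictor parameters.

    window
        odd sliding-window width (residues) for Kyte-Doolittle averaging.
    threshold
        mean hydropathy at/above which a position is membrane-like.
    min_helix_len / max_helix_len
        accepted helix length range; shorter runs are dropped, longer runs
        are split recursively at their lowest-scoring interior stretch.
    boundary_delta
        hydropathy margin used when refining run boundaries on the raw
        per-residue values: only residues above this value pull a helix
        boundary outward.  Set between C (2.5) and M (1.9) on the
        Kyte-Doolittle scale so that boundary refinement is driven by the
        five most hydrophobic residues (I, L, V, F, C) while the
        ambivalent M and A do not drag boundaries into loops.
    """

    window: int = 19
    threshold: float = 1.6
    min_helix_len: int = 15
    max_helix_len: int = 35
    boundary_delta: float = 2.2

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd positive integer")
        if not 0 < self.min_helix_len <= self.max_helix_len:
            raise ValueError("need 0 < min_helix_len <= max_helix_len")


def hydropathy_profile(residues: str, window: int) -> np.ndarray:
    """Per-residue mean Kyte-Doolittle hydropathy over a centred window.

    The window is truncated at the sequence ends: the value at position *i*
    is the mean over the available positions in ``[i-w//2, i+w//2]``.
    """
    if not residues:
        raise ValueError("empty sequence")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    values = np.array([_KD[r] for r in residues], dtype=float)
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _max_sum_interval(values: np.ndarray) -> tuple[int, int, float]:
    """Leftmost maximal-sum contiguous interval (Kadane); empty if all < 0."""
    best_sum = 0.0
    best = (0, 0)
    cur_sum = 0.0
    cur_start = 0
    for i, v in enumerate(values):
        if cur_sum <= 0:
            cur_sum = v
            cur_start = i
        else:
            cur_sum += v
        if cur_sum > best_sum:
            best_sum = cur_sum
            best = (cur_start, i + 1)
    return best[0], best[1], best_sum


def _split_run(start: int, end: int, margins: np.ndarray, params: TopologyPredictorParams,
               out: list[tuple[int, int]]) -> None:
    """Recursively clamp a hydrophobic interval to the accepted length range.

    An over-long interval usually means two helices bridged by a short loop
    that the smoothing window blurred over; the whole lowest-scoring
    interior stretch (the minimal-sum subinterval of the hydropathy
    margins — the bridging loop) is removed and both sides are
    reprocessed.  A uniformly hydrophobic interval with no negative
    stretch is halved at its centre instead.
    """
    length = end - start
    if length < params.min_helix_len:
        return
    if length <= params.max_helix_len:
        out.append((start, end))
        return
    cs, ce, low = _max_sum_interval(-margins[start:end])
    if low > 0:  # a genuinely negative (loop-like) stretch exists
        _split_run(start, start + cs, margins, params, out)
        _split_run(start + ce, end, margins, params, out)
    else:  # uniformly hydrophobic: halve, sacrificing one residue as a loop
        mid = start + length // 2
        _split_run(start, mid, margins, params, out)
        _split_run(mid + 1, end, margins, params, out)


def predict_topology(
    record: "SequenceRecord", params: TopologyPredictorParams | None = None
) -> TopologyAnnotation:
    """Call TM helices from the Kyte-Doolittle hydropathy profile.

    Candidate helices are maximal runs of window hydropathy >= threshold.
    Each run's boundaries are then refined on the raw per-residue values
    (the windowed profile blurs boundaries by up to half a window): within
    the run expanded by half a window on each side — capped at the midpoint
    to any neighbouring run — the helix is the maximal-sum interval of
    ``hydropathy - boundary_delta``.  Refined runs shorter than
    ``min_helix_len`` are discarded; longer than ``max_helix_len`` are split
    at their lowest-scoring interior stretch, recursively (two helices
    bridged by a short smoothed-over loop separate there).  Non-helix
    stretches are
    labelled alternately, ``outside`` for the N-terminal stretch; hydropathy
    alone cannot orient the protein, so the inside/outside assignment is a
    reporting convention only.
    """
    if params is None:
        params = TopologyPredictorParams()
    profile = hydropathy_profile(record.residues, params.window)
    values = np.array([_KD[r] for r in record.residues], dtype=float)
    n = len(record.residues)

    runs: list[tuple[int, int]] = []
    start = None
    for i in range(n):
        if profile[i] >= params.threshold:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, n))

    half = params.window // 2
    margins = values - params.boundary_delta
    helices: list[tuple[int, int]] = []
    for idx, (s, e) in enumerate(runs):
        lo = max(0, s - half)
        hi = min(n, e + half)
        if idx > 0:
            lo = max(lo, (runs[idx - 1][1] + s) // 2)
        if idx + 1 < len(runs):
            hi = min(hi, (e + runs[idx + 1][0] + 1) // 2)
        rs, re, total = _max_sum_interval(margins[lo:hi])
        if total <= 0:
            continue
        _split_run(lo + rs, lo + re, margins, params, helices)

    # Adjacent refined runs may touch; keep a >= 1 residue loop between
    # helices by trimming the leading residue of the later one.
    cleaned: list[tuple[int, int]] = []
    for s, e in helices:
        if cleaned and s <= cleaned[-1][1]:
            s = cleaned[-1][1] + 1
        if e - s >= params.min_helix_len:
            cleaned.append((s, e))
    helices = cleaned

    segments: list[TopologySegment] = []
    pos = 0
    n_passed = 0
    for s, e in helices:
        if s > pos:
            label = OUTSIDE if n_passed % 2 == 0 else INSIDE
            segments.append(TopologySegment(label, pos, s))
        segments.append(TopologySegment(TMHELIX, s, e))
        n_passed += 1
        pos = e
    if pos < n:
        label = OUTSIDE if n_passed % 2 == 0 else INSIDE
        segments.append(TopologySegment(label, pos, n))
    return TopologyAnnotation(record.id, segments)


def segment_sequence(
    record: "SequenceRecord", annotation: TopologyAnnotation
) -> SegmentedSequence:
    """Slice a sequence into its (label, substring) regions."""
    if annotation.length != len(record.residues):
        raise ValueError(
            f"annotation length {annotation.length} != sequence length "
            f"{len(record.residues)} for {record.id!r}"
        )
    regions = [
        (seg.label, record.residues[seg.start : seg.end]) for seg in annotation.segments
    ]
    return SegmentedSequence(record, annotation, regions)


def classify_by_tm_count(
    segmented: list[SegmentedSequence],
) -> tuple[dict[int, list[SegmentedSequence]], int]:
    """Group sequences by TM-helix count and pick the dominant class.

    The dominant class is the largest group; ties break toward the larger
    TM count (richer anchoring for the seed alignment).
    """
    if not segmented:
        raise ValueError("no sequences to classify")
    groups: dict[int, list[SegmentedSequence]] = defaultdict(list)
    for seg in segmented:
        groups[seg.tm_count].append(seg)
    dominant = max(groups, key=lambda c: (len(groups[c]), c))
    return dict(groups), dominant
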