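"""Split-read (gapped) alignment of short reads against a k-mer-indexed reference.

The aligner places a read either as one contiguous segment or as two
same-strand segments separated by a reference gap (a candidate intron), with
substitutions as the only within-segment differences.  Scoring is
``matches - mismatches``; a two-segment placement carries no gap penalty but
each segment must satisfy the anchor-length and mismatch-cap constraints.
Soft clipping of up to ``max_soft_clip`` bases is allowed at the read ends of
contiguous placements only; split placements must cover the whole read.

Both read orientations are always attempted (the data are unstranded).
Segment read coordinates refer to the *oriented* read (the reverse complement
for ``-`` placements).

Ties between equal-score placements are broken deterministically: lowest
reference coordinate of the first segment, ``+`` strand before ``-``, fewer
segments first, then lowest split point.  Within one diagonal (or diagonal
pair) the canonical candidate uses the smallest soft clips / leftmost split
point among score-equal choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from microexon.genome_model import SequenceRecord, revcomp

__all__ = [
    "MapParams",
    "AlignmentSegment",
    "SplitAlignment",
    "ReferenceIndex",
    "map_read",
    "map_read_bruteforce",
    "write_alignments_tsv",
    "write_sam",
]


@dataclass(frozen=True)
class MapParams:
    k: int = 15
    min_anchor: int = 12
    max_mismatch_frac: float = 0.04
    min_intron_gap: int = 30
    max_intron_gap: int = 10000
    max_soft_clip: int = 3


def _mm_cap(length: int, frac: float) -> int:
    return int(frac * length)


@dataclass(frozen=True)
class AlignmentSegment:
    """A gapless aligned block; read and reference intervals have equal length."""

    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.read_end - self.read_start != self.ref_end - self.ref_start:
            raise ValueError("segment read and reference intervals differ in length")

    def __len__(self) -> int:
        return self.read_end - self.read_start


@dataclass(frozen=True)
class SplitAlignment:
    """A read placement: one contiguous segment or two segments chained over a gap."""

    read_id: str
    reference_id: str
    strand: str
    segments: tuple[AlignmentSegment, ...]
    score: int

    def __post_init__(self) -> None:
        if len(self.segments) not in (1, 2):
            raise ValueError("a placement has one or two segments")

    @property
    def ref_gap(self) -> int:
        if len(self.segments) == 1:
            return 0
        return self.segments[1].ref_start - self.segments[0].ref_end

    @property
    def n_mismatches(self) -> int:
        return sum(s.mismatches for s in self.segments)

    def sort_key(self):
        return (
            self.segments[0].ref_start,
            0 if self.strand == "+" else 1,
            len(self.segments),
            self.segments[0].ref_end,
            self.segments[-1].ref_start,
        )


class ReferenceIndex:
    """Exact k-mer index over one reference sequence."""

    def __init__(self, reference: SequenceRecord | str, k: int = 15, name: str = "ref"):
        if isinstance(reference, SequenceRecord):
            self.name = reference.id
            self.seq = reference.seq
        else:
            self.name = name
            self.seq = reference.upper()
        self.k = k
        self.arr = np.frombuffer(self.seq.encode(), dtype=np.uint8)
        index: dict[str, list[int]] = {}
        for i in range(len(self.seq) - k + 1):
            index.setdefault(self.seq[i : i + k], []).append(i)
        self.index = index

    def __len__(self) -> int:
        return len(self.seq)

    def seed_diagonals(self, seq: str, max_len: int) -> list[int]:
        """Diagonals (ref_pos - read_pos) of all exact k-mer hits of ``seq``."""
        k = self.k
        diags: set[int] = set()
        upper = len(self.seq) - max_len
        for i in range(len(seq) - k + 1):
            for p in self.index.get(seq[i : i + k], ()):
                d = p - i
                if 0 <= d <= upper:
                    diags.add(d)
        return sorted(diags)


def _match_array(seq_arr: np.ndarray, ref_arr: np.ndarray, d: int) -> np.ndarray:
    return seq_arr == ref_arr[d : d + len(seq_arr)]


def _best_contiguous(match: np.ndarray, d: int, params: MapParams):
    """Best (score, clipL, clipR, mm) for a full-read placement on diagonal d."""
    length = len(match)
    cum = np.concatenate(([0], np.cumsum(match)))
    best = None
    for cl in range(params.max_soft_clip + 1):
        for cr in range(params.max_soft_clip + 1):
            seg_len = length - cl - cr
            if seg_len < params.min_anchor:
                continue
            matches = int(cum[length - cr] - cum[cl])
            mm = seg_len - matches
            if mm > _mm_cap(seg_len, params.max_mismatch_frac):
                continue
            score = matches - mm
            if best is None or score > best[0]:
                best = (score, cl, cr, mm)
    return best


def _best_split(m1: np.ndarray, m2: np.ndarray, params: MapParams):
    """Best (score, s, mm1, mm2) splitting the read at s between diagonals d1, d2.

    Split placements cover the whole read (no soft clips); ties on score are
    resolved to the leftmost split point.
    """
    length = len(m1)
    p1 = np.concatenate(([0], np.cumsum(m1)))
    p2 = np.concatenate(([0], np.cumsum(m2)))
    a = params.min_anchor
    if length < 2 * a:
        return None
    s = np.arange(a, length - a + 1)
    left_len = s
    right_len = length - s
    left_matches = p1[s]
    right_matches = p2[length] - p2[s]
    left_mm = left_len - left_matches
    right_mm = right_len - right_matches
    frac = params.max_mismatch_frac
    valid = (left_mm <= np.floor(frac * left_len)) & (right_mm <= np.floor(frac * right_len))
    if not valid.any():
        return None
    score = (left_matches - left_mm) + (right_matches - right_mm)
    score = np.where(valid, score, np.iinfo(np.int64).min)
    i = int(np.argmax(score))  # argmax returns the first (leftmost) maximum
    return int(score[i]), int(s[i]), int(left_mm[i]), int(right_mm[i])


def _candidates_for_diagonals(
    read_id: str,
    seq: str,
    strand: str,
    index: ReferenceIndex,
    diagonals: Iterable[int],
    params: MapParams,
) -> list[SplitAlignment]:
    """All canonical placements of the oriented read over the given diagonals.

    Shared by the seeded mapper (diagonals from k-mer hits) and by the
    synthetic-truth labeller (diagonals from known source coordinates), so both
    score placements identically.
    """
    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    length = len(seq)
    diags = sorted(set(d for d in diagonals if 0 <= d <= len(index) - length))
    matches = {d: _match_array(seq_arr, index.arr, d) for d in diags}
    out: list[SplitAlignment] = []
    for d in diags:
        best = _best_contiguous(matches[d], d, params)
        if best is None:
            continue
        score, cl, cr, mm = best
        seg = AlignmentSegment(cl, length - cr, d + cl, d + length - cr, mm)
        out.append(SplitAlignment(read_id, index.name, strand, (seg,), score))
    for i, d1 in enumerate(diags):
        for d2 in diags[i + 1 :]:
            gap = d2 - d1
            if not (params.min_intron_gap <= gap <= params.max_intron_gap):
                continue
            best = _best_split(matches[d1], matches[d2], params)
            if best is None:
                continue
            score, s, mm1, mm2 = best
            seg1 = AlignmentSegment(0, s, d1, d1 + s, mm1)
            seg2 = AlignmentSegment(s, length, d2 + s, d2 + length, mm2)
            out.append(SplitAlignment(read_id, index.name, strand, (seg1, seg2), score))
    return out


def map_read(
    read: str,
    reference: ReferenceIndex,
    params: MapParams = MapParams(),
    read_id: str = "read",
) -> list[SplitAlignment]:
    """All maximal-score placements of ``read`` on the reference (both orientations).

    A read shorter than k is unmappable and yields an empty list.
    """
    if len(read) < reference.k:
        return []
    candidates: list[SplitAlignment] = []
    for strand, seq in (("+", read.upper()), ("-", revcomp(read.upper()))):
        if len(seq) > len(reference):
            continue
        diags = reference.seed_diagonals(seq, len(seq))
        if diags:
            candidates.extend(
                _candidates_for_diagonals(read_id, seq, strand, reference, diags, params)
            )
    if not candidates:
        return []
    best = max(a.score for a in candidates)
    top = [a for a in candidates if a.score == best]
    top.sort(key=SplitAlignment.sort_key)
    return top


# ---------------------------------------------------------------------------
# Exhaustive oracle (tests only)
# ---------------------------------------------------------------------------


def map_read_bruteforce(
    read: str,
    reference: SequenceRecord | str,
    params: MapParams = MapParams(),
    read_id: str = "read",
) -> SplitAlignment | None:
    """Exhaustive enumeration of every placement; returns the best one.

    Enumerates all contiguous positions x clip combinations and all
    (position pair x split point) two-segment configurations, in both
    orientations, with no seeding heuristics.  Refuses references over 5 kb or
    reads over 100 nt; intended purely as an independent test oracle for
    :func:`map_read`.
    """
    ref_seq = reference.seq if isinstance(reference, SequenceRecord) else reference.upper()
    if len(ref_seq) > 5000 or len(read) > 100:
        raise ValueError("brute-force oracle limited to references <= 5 kb, reads <= 100 nt")
    if len(read) > len(ref_seq):
        return None
    ref_arr = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
    length = len(read)
    frac = params.max_mismatch_frac
    best: SplitAlignment | None = None

    def consider(aln: SplitAlignment):
        nonlocal best
        if best is None or aln.score > best.score or (
            aln.score == best.score and aln.sort_key() < best.sort_key()
        ):
            best = aln

    for strand, seq in (("+", read.upper()), ("-", revcomp(read.upper()))):
        seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        n_pos = len(ref_seq) - length + 1
        if n_pos <= 0:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(ref_arr, length)
        match = windows == seq_arr  # (n_pos, L)
        prefix = np.concatenate(
            [np.zeros((n_pos, 1), dtype=np.int64), np.cumsum(match, axis=1)], axis=1
        )
        # contiguous placements, every position and clip combination
        for cl in range(params.max_soft_clip + 1):
            for cr in range(params.max_soft_clip + 1):
                seg_len = length - cl - cr
                if seg_len < params.min_anchor:
                    continue
                m = prefix[:, length - cr] - prefix[:, cl]
                mm = seg_len - m
                score = m - mm
                ok = mm <= _mm_cap(seg_len, frac)
                for d in np.nonzero(ok)[0]:
                    seg = AlignmentSegment(
                        cl, length - cr, int(d) + cl, int(d) + length - cr, int(mm[d])
                    )
                    consider(
                        SplitAlignment(read_id, "ref", strand, (seg,), int(score[d]))
                    )
        # two-segment placements: every split point and diagonal pair
        a = params.min_anchor
        for s in range(a, length - a + 1):
            left_len, right_len = s, length - s
            lm = prefix[:, s]
            rm = prefix[:, length] - prefix[:, s]
            l_mm = left_len - lm
            r_mm = right_len - rm
            l_ok = l_mm <= np.floor(frac * left_len)
            r_ok = r_mm <= np.floor(frac * right_len)
            l_idx = np.nonzero(l_ok)[0]
            r_idx = np.nonzero(r_ok)[0]
            if len(l_idx) == 0 or len(r_idx) == 0:
                continue
            for d1 in l_idx:
                lo = d1 + params.min_intron_gap
                hi = d1 + params.max_intron_gap
                for d2 in r_idx[(r_idx >= lo) & (r_idx <= hi)]:
                    score = int(lm[d1] - l_mm[d1] + rm[d2] - r_mm[d2])
                    seg1 = AlignmentSegment(0, s, int(d1), int(d1) + s, int(l_mm[d1]))
                    seg2 = AlignmentSegment(
                        s, length, int(d2) + s, int(d2) + length, int(r_mm[d2])
                    )
                    consider(SplitAlignment(read_id, "ref", strand, (seg1, seg2), score))
    return best


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def write_alignments_tsv(alignments: Iterable[SplitAlignment], path) -> None:
    """Tab-separated dump: one row per alignment, segments as start-end pairs."""
    with open(path, "w") as fh:
        fh.write(
            "read_id\treference\tstrand\tscore\tn_segments\tref_gap\t"
            "segments_read\tsegments_ref\tmismatches\n"
        )
        for aln in alignments:
            seg_read = ",".join(f"{s.read_start}-{s.read_end}" for s in aln.segments)
            seg_ref = ",".join(f"{s.ref_start}-{s.ref_end}" for s in aln.segments)
            mism = ",".join(str(s.mismatches) for s in aln.segments)
            fh.write(
                f"{aln.read_id}\t{aln.reference_id}\t{aln.strand}\t{aln.score}\t"
                f"{len(aln.segments)}\t{aln.ref_gap}\t{seg_read}\t{seg_ref}\t{mism}\n"
            )


def _cigar(aln: SplitAlignment, read_len: int) -> str:
    segs = aln.segments
    parts = []
    lead = segs[0].read_start
    if lead:
        parts.append(f"{lead}S")
    parts.append(f"{len(segs[0])}M")
    if len(segs) == 2:
        parts.append(f"{aln.ref_gap}N")
        parts.append(f"{len(segs[1])}M")
    trail = read_len - segs[-1].read_end
    if trail:
        parts.append(f"{trail}S")
    return "".join(parts)


def write_sam(
    alignments: Iterable[tuple[SplitAlignment, str]],
    references: dict[str, int],
    path,
) -> None:
    """Export (alignment, original read sequence) pairs in SAM, spliced gaps as N.

    Reverse-strand placements are stored reverse-complemented with flag 16,
    per SAM convention.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, ln in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{ln}\n")
        for aln, read_seq in alignments:
            oriented = read_seq if aln.strand == "+" else revcomp(read_seq)
            flag = 0 if aln.strand == "+" else 16
            fh.write(
                "\t".join(
                    [
                        aln.read_id,
                        str(flag),
                        aln.reference_id,
                        str(aln.segments[0].ref_start + 1),
                        "60",
                        _cigar(aln, len(oriented)),
                        "*",
                        "0",
                        "0",
                        oriented,
                        "*",
                        f"NM:i:{aln.n_mismatches}",
                    ]
                )
                + "\n"
            )
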