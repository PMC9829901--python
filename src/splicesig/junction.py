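"""Targeted splice-junction quantification against an unspliced reference transcript.

The IRE1a endoribonuclease excises a short fragment (26 nt in human *XBP1*)
from the unspliced mRNA.  In RNA-seq data the spliced isoform (*XBP1s*) is
therefore visible as reads that align to the unspliced transcript with a
single deletion of exactly the excision length at the known junction.  This
module aligns reads to the unspliced transcript with de-penalised long gaps,
classifies each read as spliced / unspliced / uninformative, and summarises a
sample as a splicing percentage:

    spliced_percent = 100 * spliced / (spliced + unspliced)

over junction-informative reads only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "SpliceTarget",
    "AlignmentParams",
    "DetectionThresholds",
    "ReadAlignment",
    "JunctionCounts",
    "align_to_target",
    "classify_read",
    "quantify_sample",
    "count_from_alignments",
    "write_alignments_sam",
]

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_NEG = -1e18
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SpliceTarget:
    """An unspliced reference transcript with the known excision event.

    ``junction_start`` is the 0-based index of the first excised base; the
    excised interval is ``[junction_start, junction_start + excision_length)``.
    """

    transcript_id: str
    sequence: str
    junction_start: int
    excision_length: int = 26
    label: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(f"target sequence contains non-ACGTN characters: {sorted(bad)}")
        if self.excision_length < 1:
            raise ValueError("excision_length must be >= 1")
        if not (0 <= self.junction_start and self.junction_start + self.excision_length <= len(seq)):
            raise ValueError("junction interval falls outside the target sequence")

    @property
    def spliced_sequence(self) -> str:
        """The transcript with the excised interval removed."""
        js, ex = self.junction_start, self.excision_length
        return self.sequence[:js] + self.sequence[js + ex:]


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap scoring.  A gap of length L costs ``gap_open + gap_extend*L``.

    Defaults de-penalise long gaps (open=extend=1) so a 26-nt deletion is
    cheap relative to the matches it buys back — the same intent as running a
    short-read aligner with minimal read/reference gap penalties.  Because
    gaps are nearly free, an unrestricted DP would happily stitch a short
    read tail across several small chance-matched gaps instead of taking the
    one long deletion; ``gap_bar`` forbids gaps whose flanks hold fewer than
    that many read bases (the short-read-aligner gap barrier), which restores
    the intended single-deletion alignments.  Set ``gap_bar=0`` to disable.
    """

    match_score: int = 2
    mismatch_penalty: int = 3
    gap_open: int = 1
    gap_extend: int = 1
    gap_bar: int = 10  # no gaps within this many bases of either read end
    band_width: int | None = None  # max reference-gap length tracked; None = unbounded
    min_score_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if min(self.mismatch_penalty, self.gap_open, self.gap_extend, self.gap_bar) < 0:
            raise ValueError("penalties must be nonnegative")
        if self.band_width is not None and self.band_width < 1:
            raise ValueError("band_width must be a positive integer or None")
        if not 0.0 <= self.min_score_fraction <= 1.0:
            raise ValueError("min_score_fraction must be in [0, 1]")


@dataclass(frozen=True)
class DetectionThresholds:
    """Event-calling thresholds.

    ``min_supporting_reads``, ``max_depth`` and ``min_event_fraction`` mirror
    pileup-style indel calling (at least three supporting reads, depth cap
    50000, minimum event fraction 2e-4); ``min_base_quality`` is the Phred
    cutoff applied to the junction-flanking read bases (Q13).  ``min_anchor``
    and ``position_tolerance`` govern how a deletion is matched to the
    annotated junction.
    """

    min_supporting_reads: int = 3
    min_base_quality: int = 13
    min_event_fraction: float = 0.0002
    max_depth: int = 50000
    min_anchor: int = 6
    position_tolerance: int = 1

    def __post_init__(self) -> None:
        for name in ("min_supporting_reads", "min_base_quality", "max_depth",
                     "min_anchor", "position_tolerance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.max_depth < 1:
            raise ValueError("max_depth must be positive")
        if not 0.0 <= self.min_event_fraction <= 1.0:
            raise ValueError("min_event_fraction must be in [0, 1]")


@dataclass
class ReadAlignment:
    """A gapped alignment of a full read against a reference substring.

    ``ops`` is a run-length list of (op, length) with op in
    {match, mismatch, insertion, deletion}; insertion consumes read only,
    deletion consumes reference only.  ``seq``/``qual`` hold the read in the
    aligned orientation (reverse-complemented when ``strand`` is '-').
    """

    read_id: str
    ref_start: int
    ops: list[tuple[str, int]]
    score: float
    mapped: bool
    strand: str = "+"
    seq: str = ""
    qual: str | None = None

    def read_length_consumed(self) -> int:
        return sum(n for op, n in self.ops if op in ("match", "mismatch", "insertion"))


@dataclass
class JunctionCounts:
    """Per-sample junction read counts and the derived splicing percentage."""

    spliced_count: int = 0
    unspliced_count: int = 0
    uninformative_count: int = 0
    spliced_percent: float | None = None
    pass_threshold: bool = False
    sample_id: str = ""

    @classmethod
    def from_counts(cls, spliced: int, unspliced: int, uninformative: int,
                    thresholds: DetectionThresholds, sample_id: str = "") -> "JunctionCounts":
        denom = spliced + unspliced
        percent = 100.0 * spliced / denom if denom > 0 else None
        passed = (
            spliced >= thresholds.min_supporting_reads
            and denom > 0
            and spliced / denom >= thresholds.min_event_fraction
        )
        return cls(spliced, unspliced, uninformative, percent, passed, sample_id)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _substitution_scores(read: str, ref: str, params: AlignmentParams) -> np.ndarray:
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    t = np.frombuffer(ref.encode(), dtype=np.uint8)
    eq = r[:, None] == t[None, :]
    # N never matches anything (including N) — ambiguous bases score as mismatch
    has_n = (r[:, None] == ord("N")) | (t[None, :] == ord("N"))
    return np.where(eq & ~has_n, float(params.match_score), -float(params.mismatch_penalty))


def _glocal_dp(read: str, ref: str, params: AlignmentParams):
    """Affine-gap DP, global in the read, local (free ends) in the reference.

    Returns the three state matrices plus the substitution matrix.  Row i /
    column j means i read bases and j reference bases consumed.  ``D`` (a gap
    in the read consuming reference) is computed with a running-maximum trick
    so each row is vectorised; with a finite band_width the reference gap
    length is capped via a sliding-window maximum.
    """
    n, m = len(read), len(ref)
    go, ge = float(params.gap_open), float(params.gap_extend)
    sub = _substitution_scores(read, ref, params)

    M = np.full((n + 1, m + 1), _NEG)
    I = np.full((n + 1, m + 1), _NEG)
    D = np.full((n + 1, m + 1), _NEG)
    M[0, :] = 0.0  # alignment may start at any reference position

    gb = params.gap_bar
    j_idx = np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], I[i - 1]), D[i - 1])
        M[i, 1:] = best_prev[:-1] + sub[i - 1]
        # gap barrier: an inserted read base i needs >= gb read bases strictly
        # before and after it; a reference gap after i read bases needs >= gb
        # read bases on each side
        if i - 1 >= gb and n - i >= gb:
            I[i] = np.maximum(best_prev - go, I[i - 1]) - ge
        if i >= gb and n - i >= gb:
            mi = np.maximum(M[i], I[i])
            x = mi + ge * j_idx
            if params.band_width is None:
                run = np.maximum.accumulate(x)
            else:
                b = min(params.band_width, m + 1)
                pad = np.full(b - 1, _NEG)
                xp = np.concatenate([pad, x])
                run = np.lib.stride_tricks.sliding_window_view(xp, b).max(axis=1)
            D[i, 1:] = run[:-1] - go - ge * j_idx[1:]
    return M, I, D, sub


def _traceback(read: str, ref: str, params: AlignmentParams, M, I, D, sub):
    """Deterministic traceback: at ties prefer match state, then extending a
    deletion (pushing reference gaps left-most), then insertion."""
    n = len(read)
    end_scores = np.maximum(M[n], I[n])
    j = int(np.argmax(end_scores))  # first occurrence -> smallest end position
    score = float(end_scores[j])
    state = "M" if M[n, j] >= I[n, j] else "I"
    go, ge = float(params.gap_open), float(params.gap_extend)

    ops_rev: list[str] = []
    i = n
    while i > 0:
        if state == "M":
            s = sub[i - 1, j - 1]
            ops_rev.append("match" if s > 0 else "mismatch")
            want = M[i, j] - s
            i, j = i - 1, j - 1
            if i == 0:
                break
            if M[i, j] == want:
                state = "M"
            elif D[i, j] == want:
                state = "D"
            else:
                state = "I"
        elif state == "I":
            ops_rev.append("insertion")
            if I[i, j] == I[i - 1, j] - ge:
                i, state = i - 1, "I"
            else:
                want = I[i, j] + ge + go
                i = i - 1
                if i == 0:
                    break
                state = "M" if M[i, j] == want else ("D" if D[i, j] == want else "I")
        else:  # D: reference gap
            ops_rev.append("deletion")
            if D[i, j] == D[i, j - 1] - ge:
                j, state = j - 1, "D"
            else:
                want = D[i, j] + ge + go
                j = j - 1
                state = "M" if M[i, j] == want else "I"

    ops: list[tuple[str, int]] = []
    for op in reversed(ops_rev):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return score, j, ops


def align_to_target(read: str, qual: str | None, target: SpliceTarget,
                    params: AlignmentParams | None = None,
                    read_id: str = "read") -> ReadAlignment:
    """Optimal affine-gap alignment of a full read against the target.

    Both orientations are tried and the better-scoring one kept (forward wins
    ties).  ``mapped`` is False when the best score falls below
    ``min_score_fraction * read_length * match_score``.
    """
    params = params or AlignmentParams()
    read = read.upper()
    if not read:
        raise ValueError("read must be nonempty")
    bad = set(read) - _VALID_BASES
    if bad:
        raise ValueError(f"read contains non-ACGTN characters: {sorted(bad)}")
    if len(read) > len(target.sequence):
        raise ValueError(
            f"read length {len(read)} exceeds target length {len(target.sequence)}")
    if qual is not None and len(qual) != len(read):
        raise ValueError("quality string length does not match read length")

    best = None
    for strand, oriented, oqual in (
        ("+", read, qual),
        ("-", reverse_complement(read), qual[::-1] if qual is not None else None),
    ):
        M, I, D, sub = _glocal_dp(oriented, target.sequence, params)
        score, ref_start, ops = _traceback(oriented, target.sequence, params, M, I, D, sub)
        if best is None or score > best[0]:
            best = (score, ref_start, ops, strand, oriented, oqual)

    score, ref_start, ops, strand, oriented, oqual = best
    mapped = score >= params.min_score_fraction * len(read) * params.match_score
    return ReadAlignment(read_id=read_id, ref_start=ref_start, ops=ops if mapped else ops,
                         score=score, mapped=mapped, strand=strand, seq=oriented, qual=oqual)


# ---------------------------------------------------------------------------
# classification and counting
# ---------------------------------------------------------------------------

def left_align_deletion(seq: str, start: int, length: int) -> int:
    """Leftmost score-equivalent start of a deletion of ``length`` at ``start``.

    A deletion of ``[p, p+L)`` can shift one base left whenever
    ``seq[p-1] == seq[p+L-1]``; repeated shifting yields the canonical
    left-aligned representation (the convention pileup/VCF tools use).
    """
    while start > 0 and seq[start - 1] == seq[start + length - 1]:
        start -= 1
    return start


def right_align_deletion(seq: str, start: int, length: int) -> int:
    """Rightmost score-equivalent start of the same deletion."""
    while start + length < len(seq) and seq[start] == seq[start + length]:
        start += 1
    return start


def _phred(qual: str | None, pos: int) -> int | None:
    if qual is None or pos < 0 or pos >= len(qual):
        return None
    return ord(qual[pos]) - 33


def classify_read(aln: ReadAlignment, target: SpliceTarget,
                  thresholds: DetectionThresholds | None = None) -> str:
    """Label an aligned read as ``spliced``, ``unspliced`` or ``uninformative``.

    Spliced: the alignment carries a deletion *cluster* (deletions separated
    by fewer than ``min_anchor`` aligned bases — with near-free gap penalties
    the aligner may split the excision around chance-matched bases inside the
    excised region) whose total deleted length equals the excision length and
    whose reference span overlaps the annotated excision interval by at least
    ``excision_length - position_tolerance`` under indel-normalisation
    equivalence (a deletion flanked by repeats can slide), with at least
    ``min_anchor`` aligned read bases on each side of the cluster.
    Unspliced: no such cluster and an uninterrupted aligned run covering
    ``[junction_start - min_anchor, junction_start + min_anchor)``.  Reads
    failing the Phred cutoff at the junction-flanking bases, unmapped reads
    and reads not reaching the junction are uninformative.
    """
    th = thresholds or DetectionThresholds()
    if not aln.mapped:
        return "uninformative"
    js, ex = target.junction_start, target.excision_length
    a, tol, minq = th.min_anchor, th.position_tolerance, th.min_base_quality

    read_pos, ref_pos = 0, aln.ref_start
    segments: list[tuple[int, int, int]] = []  # (ref_start, length, read_start) aligned runs
    deletions: list[tuple[int, int, int]] = []  # (ref_start, length, read_pos_at)
    aligned_before: list[int] = []  # aligned read bases preceding each deletion
    mismatch_refs: list[tuple[int, int]] = []  # (ref_start, length) of mismatch runs
    n_aligned = 0
    run: tuple[int, int, int] | None = None  # mismatches do not break an aligned run
    for op, length in aln.ops:
        if op == "mismatch":
            mismatch_refs.append((ref_pos, length))
        if op in ("match", "mismatch"):
            if run is not None and run[0] + run[1] == ref_pos:
                run = (run[0], run[1] + length, run[2])
            else:
                if run is not None:
                    segments.append(run)
                run = (ref_pos, length, read_pos)
            read_pos += length
            ref_pos += length
            n_aligned += length
        elif op == "insertion":
            if run is not None:  # an inserted base interrupts the anchor run
                segments.append(run)
                run = None
            read_pos += length
        elif op == "deletion":
            if run is not None:
                segments.append(run)
                run = None
            deletions.append((ref_pos, length, read_pos))
            aligned_before.append(n_aligned)
            ref_pos += length
        else:  # pragma: no cover - guarded by construction
            raise ValueError(f"unknown alignment op {op!r}")
    if run is not None:
        segments.append(run)
    total_aligned = n_aligned

    # group deletions separated by fewer than min_anchor aligned bases into
    # clusters: the de-penalised DP may split one excision around a few
    # chance-matched bases inside the excised region
    clusters: list[list[int]] = []
    for idx, (dstart, dlen, dread) in enumerate(deletions):
        if clusters:
            prev_idx = clusters[-1][-1]
            between = aligned_before[idx] - aligned_before[prev_idx]
            if between < a:
                clusters[-1].append(idx)
                continue
        clusters.append([idx])

    # all score-equivalent placements of the excision interval
    js_lo = left_align_deletion(target.sequence, js, ex)
    js_hi = right_align_deletion(target.sequence, js, ex)
    for cluster in clusters:
        total_del = sum(deletions[i][1] for i in cluster)
        if total_del != ex:
            continue
        span_start = deletions[cluster[0]][0]
        span_end = deletions[cluster[-1]][0] + deletions[cluster[-1]][1]
        overlap = max(
            min(span_end, p + ex) - max(span_start, p)
            for p in range(js_lo, js_hi + 1))
        if overlap < ex - tol:
            continue
        before = aligned_before[cluster[0]]
        after = total_aligned - aligned_before[cluster[-1]]
        if before >= a and after >= a:
            ql = _phred(aln.qual, deletions[cluster[0]][2] - 1)
            qr = _phred(aln.qual, deletions[cluster[-1]][2])
            if (ql is not None and ql < minq) or (qr is not None and qr < minq):
                return "uninformative"
            return "spliced"

    # unspliced: the anchor window around the junction must be covered by a
    # single aligned run (reference-contiguous, no gap crossing it), and the
    # window bases must agree with the reference — a mismatch there is more
    # likely a misaligned junction read than genuine unspliced coverage
    lo, hi = js - a, js + a
    for seg_ref, seg_len, seg_read in segments:
        if seg_ref <= lo and seg_ref + seg_len >= hi:
            if any(ms < hi and ms + ml > lo for ms, ml in mismatch_refs):
                return "uninformative"
            ql = _phred(aln.qual, seg_read + (js - 1 - seg_ref))
            qr = _phred(aln.qual, seg_read + (js - seg_ref))
            if (ql is not None and ql < minq) or (qr is not None and qr < minq):
                return "uninformative"
            return "unspliced"
    return "uninformative"


def quantify_sample(reads: Iterable[tuple[str, str, str | None]],
                    target: SpliceTarget,
                    params: AlignmentParams | None = None,
                    thresholds: DetectionThresholds | None = None,
                    sample_id: str = "sample") -> JunctionCounts:
    """Align and classify a stream of reads, returning junction counts.

    ``reads`` yields (read_id, sequence, quality-or-None) tuples (see
    :func:`splicesig.io.read_fastq`).  Junction-informative reads beyond
    ``max_depth`` are dropped (first-come truncation).
    """
    params = params or AlignmentParams()
    th = thresholds or DetectionThresholds()
    spliced = unspliced = uninformative = 0
    for read_id, seq, qual in reads:
        aln = align_to_target(seq, qual, target, params, read_id=read_id)
        label = classify_read(aln, target, th)
        if label == "uninformative":
            uninformative += 1
        elif spliced + unspliced >= th.max_depth:
            continue  # depth cap reached: further informative reads are skipped
        elif label == "spliced":
            spliced += 1
        else:
            unspliced += 1
    return JunctionCounts.from_counts(spliced, unspliced, uninformative, th, sample_id)


def _cigar_to_ops(cigartuples, seq: str, qual: str | None,
                  ref_seq: str, ref_start: int):
    """Convert pysam CIGAR tuples to internal ops, trimming soft clips.

    Returns (ops, trimmed_seq, trimmed_qual).  M runs are split into
    match/mismatch against the reference so both counting entry points see
    the same evidence; =/X map directly.
    """
    start_clip = end_clip = 0
    body = list(cigartuples)
    if body and body[0][0] == 4:
        start_clip = body[0][1]
        body = body[1:]
    if body and body[-1][0] == 4:
        end_clip = body[-1][1]
        body = body[:-1]
    end = len(seq) - end_clip if seq else None
    tseq = seq[start_clip:end] if seq else ""
    tqual = qual[start_clip:end] if qual is not None else None

    ops: list[tuple[str, int]] = []

    def emit(op: str, length: int) -> None:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))

    read_pos, ref_pos = 0, ref_start
    for code, length in body:
        if code == 0:  # M: split by comparing to the reference
            if not tseq:
                emit("match", length)
            else:
                for k in range(length):
                    r = tseq[read_pos + k]
                    t = ref_seq[ref_pos + k] if ref_pos + k < len(ref_seq) else "N"
                    same = r == t and r != "N" and t != "N"
                    emit("match" if same else "mismatch", 1)
            read_pos += length
            ref_pos += length
        elif code == 7:  # =
            emit("match", length)
            read_pos += length
            ref_pos += length
        elif code == 8:  # X
            emit("mismatch", length)
            read_pos += length
            ref_pos += length
        elif code == 1:
            emit("insertion", length)
            read_pos += length
        elif code in (2, 3):  # D, N: a skipped region is a deletion here
            emit("deletion", length)
            ref_pos += length
        elif code == 5:  # hard clip
            continue
        else:
            raise ValueError(f"unsupported CIGAR op code {code}")
    return ops, tseq, tqual


def count_from_alignments(alignments, target: SpliceTarget,
                          thresholds: DetectionThresholds | None = None,
                          sample_id: str = "sample") -> JunctionCounts:
    """Count junction reads from existing SAM/BAM alignments.

    ``alignments`` is a path or an open ``pysam.AlignmentFile``.  Records
    aligned to a reference other than ``target.transcript_id`` are an input
    error; records without a CIGAR are skipped with a warning.
    """
    import pysam

    th = thresholds or DetectionThresholds()
    own = False
    if not hasattr(alignments, "fetch"):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own = True
    spliced = unspliced = uninformative = 0
    try:
        for rec in alignments.fetch(until_eof=True):
            if rec.is_unmapped:
                uninformative += 1
                continue
            if rec.reference_name != target.transcript_id:
                raise ValueError(
                    f"alignment reference {rec.reference_name!r} does not match "
                    f"target transcript {target.transcript_id!r}")
            if rec.cigartuples is None:
                logger.warning("record %s has no CIGAR; skipped", rec.query_name)
                continue
            seq = rec.query_sequence or ""
            qual = (
                "".join(chr(q + 33) for q in rec.query_qualities)
                if rec.query_qualities is not None else None
            )
            ops, tseq, tqual = _cigar_to_ops(rec.cigartuples, seq, qual,
                                             target.sequence,
                                             rec.reference_start)
            aln = ReadAlignment(read_id=rec.query_name, ref_start=rec.reference_start,
                                ops=ops, score=0.0, mapped=True,
                                strand="-" if rec.is_reverse else "+",
                                seq=tseq, qual=tqual)
            label = classify_read(aln, target, th)
            if label == "uninformative":
                uninformative += 1
            elif spliced + unspliced >= th.max_depth:
                continue
            elif label == "spliced":
                spliced += 1
            else:
                unspliced += 1
    finally:
        if own:
            alignments.close()
    return JunctionCounts.from_counts(spliced, unspliced, uninformative, th, sample_id)


def write_alignments_sam(alignments: Iterable[ReadAlignment], target: SpliceTarget,
                         path: str) -> int:
    """Serialise in-memory alignments to a SAM file (match+mismatch become M)."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": target.transcript_id, "LN": len(target.sequence)}]}
    n = 0
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.query_sequence = aln.seq
            if aln.qual is not None:
                rec.query_qualities = pysam.qualitystring_to_array(aln.qual)
            if not aln.mapped:
                rec.is_unmapped = True
                out.write(rec)
                n += 1
                continue
            rec.reference_id = 0
            rec.reference_start = aln.ref_start
            rec.mapping_quality = 60
            rec.is_reverse = aln.strand == "-"
            cig = []
            for op, length in aln.ops:
                code = {"match": 0, "mismatch": 0, "insertion": 1, "deletion": 2}[op]
                if cig and cig[-1][0] == code:
                    cig[-1] = (code, cig[-1][1] + length)
                else:
                    cig.append((code, length))
            rec.cigartuples = cig
            out.write(rec)
            n += 1
    return n
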