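"""Desk-scale seed-and-chain long-read alignment and two-phase read triage.

The internal aligner exists so the test suite needs no external binary; it
follows the familiar minimizer / colinear-chain / extend recipe at small
scale.  Externally produced PAF/SAM (``seqio.read_alignments``) can enter the
pipeline at :func:`triage_reads` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
from Bio import Align as _bioalign

from lvis._util import revcomp
from lvis.seqio import AlignmentSpan, LongRead, read_fasta

_UINT64_MAX = np.uint64(0xFFFFFFFFFFFFFFFF)

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer; decorrelates k-mer rank from sequence content."""
    z = x + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def _kmer_hashes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Hashes of canonical k-mers at every position, and the strand of the
    canonical form (0 = forward, 1 = reverse).  Positions containing N get
    the sentinel max hash."""
    codes = _encode(seq).astype(np.uint64)
    n = len(seq)
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.uint8)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | (codes[j : j + m] & np.uint64(3))
        rev |= ((np.uint64(3) - (codes[j : j + m] & np.uint64(3))) & np.uint64(3)) << np.uint64(2 * j)
    strand = (fwd > rev).astype(np.uint8)
    canon = np.where(strand == 0, fwd, rev)
    hashes = _mix64(canon)
    is_n = (codes == 4).astype(np.int32)
    bad = np.convolve(is_n, np.ones(k, dtype=np.int32), mode="valid") > 0
    hashes[bad] = _UINT64_MAX
    return hashes, strand


def _minimizers(seq: str, k: int, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(positions, hashes, strands) of (w,k)-minimizers; leftmost tie wins."""
    hashes, strand = _kmer_hashes(seq, k)
    m = hashes.size
    if m == 0:
        e = np.empty(0, dtype=np.int64)
        return e, np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.uint8)
    win = min(w, m)
    view = np.lib.stride_tricks.sliding_window_view(hashes, win)
    pos = np.unique(view.argmin(axis=1) + np.arange(view.shape[0]))
    keep = hashes[pos] != _UINT64_MAX
    pos = pos[keep]
    return pos, hashes[pos], strand[pos]


@dataclass
class MinimizerIndex:
    """Canonical-minimizer index over a set of target sequences."""

    k: int
    w: int
    names: list[str]
    sequences: dict[str, str]
    table: dict[int, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.sequences.items()}


def build_index(reference: Union[dict, str], k: int = 15, w: int = 10) -> MinimizerIndex:
    """Index every sequence of ``reference`` (dict name->seq, or FASTA path)."""
    if not isinstance(reference, dict):
        reference = read_fasta(reference)
    if not reference:
        raise ValueError("empty reference")
    names = list(reference)
    seqs = {n: s.upper() for n, s in reference.items()}
    for n, s in seqs.items():
        if k > len(s):
            raise ValueError(f"k={k} exceeds length of sequence {n!r} ({len(s)})")
    all_h: list[np.ndarray] = []
    all_rows: list[np.ndarray] = []
    for tid, name in enumerate(names):
        pos, h, strand = _minimizers(seqs[name], k, w)
        rows = np.empty((pos.size, 3), dtype=np.int64)
        rows[:, 0] = tid
        rows[:, 1] = pos
        rows[:, 2] = strand
        all_h.append(h)
        all_rows.append(rows)
    hcat = np.concatenate(all_h) if all_h else np.empty(0, dtype=np.uint64)
    rcat = np.concatenate(all_rows) if all_rows else np.empty((0, 3), dtype=np.int64)
    order = np.argsort(hcat, kind="stable")
    hcat, rcat = hcat[order], rcat[order]
    table: dict[int, np.ndarray] = {}
    if hcat.size:
        uniq, starts = np.unique(hcat, return_index=True)
        bounds = list(starts) + [hcat.size]
        for i, key in enumerate(uniq):
            table[int(key)] = rcat[bounds[i] : bounds[i + 1]]
    return MinimizerIndex(k=k, w=w, names=names, sequences=seqs, table=table)


# ---------------------------------------------------------------------------
# Chaining + extension
# ---------------------------------------------------------------------------

_aligner = _bioalign.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 2
_aligner.mismatch_score = -3
_aligner.open_gap_score = -5
_aligner.extend_gap_score = -2


def _fill_gap(qseq: str, tseq: str) -> tuple[int, int]:
    """(matches, aligned columns) for one inter-anchor gap."""
    if not qseq and not tseq:
        return 0, 0
    if not qseq or not tseq:
        return 0, max(len(qseq), len(tseq))
    if qseq == tseq:
        return len(qseq), len(qseq)
    if len(qseq) > 2000 or len(tseq) > 2000:
        # unbridgeable gap: count as one long unaligned block
        return 0, max(len(qseq), len(tseq))
    aln = _aligner.align(qseq, tseq)[0]
    counts = aln.counts()
    return counts.identities, aln.length


_ext_aligner = _bioalign.PairwiseAligner()
_ext_aligner.mode = "global"
_ext_aligner.match_score = 2
_ext_aligner.mismatch_score = -3
_ext_aligner.open_gap_score = -5
_ext_aligner.extend_gap_score = -2
# free distal end gaps: the aligner stops extending where the score peaks,
# leaving unrelated tail sequence (e.g. host beyond a junction) unaligned
try:
    _ext_aligner.open_right_deletion_score = 0
    _ext_aligner.extend_right_deletion_score = 0
    _ext_aligner.open_right_insertion_score = 0
    _ext_aligner.extend_right_insertion_score = 0
except AttributeError:  # Biopython < 1.86 naming
    _ext_aligner.query_right_open_gap_score = 0
    _ext_aligner.query_right_extend_gap_score = 0
    _ext_aligner.target_right_open_gap_score = 0
    _ext_aligner.target_right_extend_gap_score = 0


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    if n == 0:
        return 0
    aa = np.frombuffer(a[:n].encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b[:n].encode("ascii"), dtype=np.uint8)
    neq = np.nonzero(aa != bb)[0]
    return int(neq[0]) if neq.size else n


def _extend_right(qtail: str, ttail: str, max_ext: int = 1500) -> tuple[int, int, int, int]:
    """Extend an alignment rightward from position 0 of both tails.

    Returns (query_advance, target_advance, matches, columns).  Exact runs
    are taken directly; the remainder goes through a free-right-end-gap
    alignment so extension survives indels instead of stopping at them.
    """
    p = _common_prefix_len(qtail, ttail)
    if p == min(len(qtail), len(ttail)):
        return p, p, p, p
    qrest = qtail[p : p + max_ext]
    trest = ttail[p : p + max_ext]
    if not qrest or not trest:
        return p, p, p, p
    aln = _ext_aligner.align(qrest, trest)[0]
    qblocks, tblocks = aln.aligned
    # x-drop semantics: keep only the maximum-scoring *prefix* of the path,
    # otherwise the free-end-gap optimum can swallow unrelated flank sequence
    # (e.g. host beyond a junction) on scattered chance matches
    best = (0, 0, 0, 0)
    best_score = 0.0
    score = 0.0
    matches = 0
    cols = 0
    prev_q = prev_t = 0
    for (q0, q1), (t0, t1) in zip(qblocks, tblocks):
        gap = (q0 - prev_q) + (t0 - prev_t)
        if gap:
            score += -5.0 - 2.0 * (gap - 1)
            cols += gap
        eq = np.frombuffer(qrest[q0:q1].encode(), np.uint8) == np.frombuffer(
            trest[t0:t1].encode(), np.uint8
        )
        if eq.size:
            cum = np.cumsum(np.where(eq, 2.0, -3.0))
            i_best = int(np.argmax(cum))
            if score + cum[i_best] > best_score:
                best_score = score + float(cum[i_best])
                best = (
                    q0 + i_best + 1,
                    t0 + i_best + 1,
                    matches + int(eq[: i_best + 1].sum()),
                    cols + i_best + 1,
                )
            score += float(cum[-1])
            matches += int(eq.sum())
            cols += eq.size
        prev_q, prev_t = q1, t1
    q_adv, t_adv, m, c = best
    return p + q_adv, p + t_adv, p + m, p + c


def _chain_anchors(anchors: list[tuple[int, int]], max_gap: int = 2000,
                   band: int = 200) -> list[list[tuple[int, int]]]:
    """Greedy colinear chaining of (q, t) anchors sorted by q."""
    chains: list[list[tuple[int, int]]] = []
    tails: list[tuple[int, int]] = []
    for q, t in anchors:
        best_i, best_gap = -1, None
        for i, (lq, lt) in enumerate(tails):
            dq, dt = q - lq, t - lt
            if dq <= 0 or dt <= 0 or dq > max_gap or dt > max_gap:
                continue
            if abs(dq - dt) > band:
                continue
            gap = max(dq, dt)
            if best_gap is None or gap < best_gap:
                best_i, best_gap = i, gap
        if best_i >= 0:
            chains[best_i].append((q, t))
            tails[best_i] = (q, t)
        else:
            chains.append([(q, t)])
            tails.append((q, t))
    return chains


def _chain_to_span(chain: list[tuple[int, int]], qseq: str, tseq: str, k: int
                   ) -> Optional[tuple[int, int, int, int, int, int]]:
    """Turn an anchor chain into (qs, qe, ts, te, matches, block) on the
    oriented query frame; gap segments are realigned, ends greedily extended."""
    # coalesce same-diagonal overlapping anchors into exact runs
    runs: list[list[int]] = []  # [qs, qe, ts, te]
    for q, t in chain:
        if runs and runs[-1][1] - runs[-1][3] == q - t and q <= runs[-1][1]:
            runs[-1][1] = q + k
            runs[-1][3] = t + k
        else:
            runs.append([q, q + k, t, t + k])
    # trim overlaps between off-diagonal neighbouring runs
    cleaned: list[list[int]] = []
    for run in runs:
        if cleaned:
            prev = cleaned[-1]
            shift = max(prev[1] - run[0], prev[3] - run[2], 0)
            run = [run[0] + shift, run[1], run[2] + shift, run[3]]
            if run[1] - run[0] < 1:
                continue
        cleaned.append(run)
    if not cleaned:
        return None
    matches = block = 0
    for qs_, qe_, ts_, te_ in cleaned:
        matches += qe_ - qs_
        block += qe_ - qs_
    for a, b in zip(cleaned, cleaned[1:]):
        m, c = _fill_gap(qseq[a[1] : b[0]], tseq[a[3] : b[2]])
        matches += m
        block += c
    qs, qe = cleaned[0][0], cleaned[-1][1]
    ts, te = cleaned[0][2], cleaned[-1][3]
    q_adv, t_adv, m, c = _extend_right(qseq[:qs][::-1], tseq[:ts][::-1])
    qs, ts = qs - q_adv, ts - t_adv
    matches += m
    block += c
    q_adv, t_adv, m, c = _extend_right(qseq[qe:], tseq[te:])
    qe, te = qe + q_adv, te + t_adv
    matches += m
    block += c
    return qs, qe, ts, te, matches, block


def align_read(
    read: Union[LongRead, str],
    index: MinimizerIndex,
    min_chain_anchors: int = 4,
    min_identity: float = 0.8,
    max_occ: int = 200,
    query_id: str = "query",
) -> list[AlignmentSpan]:
    """Align one read against the index; spans returned best-first.

    Unalignable reads yield an empty list.  Ties are broken by lowest target
    start coordinate, then target name, so output is deterministic.
    """
    if isinstance(read, LongRead):
        seq, query_id = read.sequence, read.id
    else:
        seq = read.upper()
    L = len(seq)
    if L < index.k:
        return []
    pos, hashes, strands = _minimizers(seq, index.k, index.w)
    k = index.k
    groups: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for p, h, s in zip(pos, hashes, strands):
        entry = index.table.get(int(h))
        if entry is None or entry.shape[0] > max_occ:
            continue
        for tid, tpos, tstrand in entry:
            rel = int(s) ^ int(tstrand)  # 0: read fwd matches target fwd
            q = int(p) if rel == 0 else L - k - int(p)
            groups.setdefault((int(tid), rel), []).append((q, int(tpos)))
    spans: list[AlignmentSpan] = []
    rc_cache: Optional[str] = None
    for (tid, rel), anchors in groups.items():
        anchors.sort()
        tname = index.names[tid]
        tseq = index.sequences[tname]
        if rel == 0:
            qseq = seq
        else:
            if rc_cache is None:
                rc_cache = revcomp(seq)
            qseq = rc_cache
        for chain in _chain_anchors(anchors):
            if len(chain) < min_chain_anchors:
                continue
            res = _chain_to_span(chain, qseq, tseq, k)
            if res is None:
                continue
            qs, qe, ts, te, matches, block = res
            if qe - qs < k or block <= 0:
                continue
            identity = matches / block
            if identity < min_identity:
                continue
            if rel == 1:
                qs, qe = L - qe, L - qs
            spans.append(
                AlignmentSpan(
                    query_id=query_id,
                    query_start=qs,
                    query_end=qe,
                    target_name=tname,
                    target_start=ts,
                    target_end=te,
                    strand="+" if rel == 0 else "-",
                    matches=matches,
                    block_length=block,
                    score=float(matches),
                    is_primary=False,
                )
            )
    spans.sort(key=lambda s: (-s.score, s.target_start, s.target_name))
    if spans:
        spans[0].is_primary = True
    return spans


# ---------------------------------------------------------------------------
# Two-phase triage
# ---------------------------------------------------------------------------

Classification = Literal[
    "junction_candidate", "vector_only", "host_only", "unmapped", "ambiguous"
]


@dataclass
class TriageParams:
    uniqueness_ratio: float = 1.2
    min_host_anchor: int = 200
    min_identity: float = 0.8
    min_chain_anchors: int = 4
    #: bp of query re-exposed on each side of the LV span before host mapping,
    #: sized to tsd_max (7) plus a little alignment raggedness
    mask_cushion: int = 8
    min_flank: int = 50


@dataclass
class TriageResult:
    """Per-read outcome of the vector-first, host-second alignment gate."""

    read_id: str
    read_length: int
    lv_span: Optional[AlignmentSpan]
    host_span: Optional[AlignmentSpan]
    unique_host: bool
    classification: Classification
    lv_spans: list[AlignmentSpan] = field(default_factory=list)
    host_spans: list[AlignmentSpan] = field(default_factory=list)
    flank_lv_spans: list[AlignmentSpan] = field(default_factory=list)
    read_sequence: Optional[str] = field(default=None, repr=False)


def _align_flank(seq: str, offset: int, query_id: str, index: MinimizerIndex,
                 params: TriageParams) -> list[AlignmentSpan]:
    spans = align_read(
        seq,
        index,
        min_chain_anchors=params.min_chain_anchors,
        min_identity=params.min_identity,
        query_id=query_id,
    )
    for s in spans:
        s.query_start += offset
        s.query_end += offset
    return spans


def triage_read(
    read: LongRead,
    construct_index: MinimizerIndex,
    host_index: MinimizerIndex,
    params: Optional[TriageParams] = None,
) -> TriageResult:
    """Vector-first gate: only reads with an LV span have their non-LV query
    portion mapped to host; host uniqueness uses a best/second-best score
    ratio so repeat-resident anchors surface as ``ambiguous``."""
    params = params or TriageParams()
    lv_spans = align_read(
        read, construct_index,
        min_chain_anchors=params.min_chain_anchors,
        min_identity=params.min_identity,
    )
    L = len(read)
    if not lv_spans:
        # no LV anchor: do not host-align; cheap minimizer screen only
        pos, hashes, _ = _minimizers(read.sequence, host_index.k, host_index.w)
        hits = sum(1 for h in hashes if int(h) in host_index.table)
        cls: Classification = "host_only" if hits >= params.min_chain_anchors else "unmapped"
        return TriageResult(read.id, L, None, None, False, cls,
                            read_sequence=read.sequence)
    lv = lv_spans[0]
    host_spans: list[AlignmentSpan] = []
    flank_lv: list[AlignmentSpan] = []
    left_end = lv.query_start + params.mask_cushion
    right_start = lv.query_end - params.mask_cushion
    flanks = []
    if left_end >= params.min_flank:
        flanks.append((read.sequence[:left_end], 0))
    if L - right_start >= params.min_flank:
        flanks.append((read.sequence[right_start:], right_start))
    for fseq, off in flanks:
        host_spans.extend(_align_flank(fseq, off, read.id, host_index, params))
        flank_lv.extend(_align_flank(fseq, off, read.id, construct_index, params))
    host_spans.sort(key=lambda s: (-s.score, s.target_start, s.target_name))
    flank_lv.sort(key=lambda s: (-s.score, s.target_start, s.target_name))
    if not host_spans:
        return TriageResult(
            read.id, L, lv, None, False, "vector_only",
            lv_spans=lv_spans, flank_lv_spans=flank_lv,
            read_sequence=read.sequence,
        )
    best = host_spans[0]
    unique = True
    if len(host_spans) > 1:
        unique = best.score >= params.uniqueness_ratio * host_spans[1].score
    anchored = best.query_span >= params.min_host_anchor
    unique_host = unique and anchored
    if unique_host:
        cls = "junction_candidate"
    elif not unique:
        cls = "ambiguous"
    else:
        cls = "vector_only"  # host hit too short to count as an anchor
    return TriageResult(
        read.id, L, lv, best, unique_host, cls,
        lv_spans=lv_spans, host_spans=host_spans, flank_lv_spans=flank_lv,
        read_sequence=read.sequence,
    )


def triage_reads(
    reads: Sequence[LongRead],
    construct_index: MinimizerIndex,
    host_index: MinimizerIndex,
    params: Optional[TriageParams] = None,
) -> list[TriageResult]:
    params = params or TriageParams()
    return [triage_read(r, construct_index, host_index, params) for r in reads]


def triage_from_alignments(
    reads: Sequence[LongRead],
    spans: Sequence[AlignmentSpan],
    construct_name: str,
    params: Optional[TriageParams] = None,
) -> list[TriageResult]:
    """Build triage results from externally produced alignments (PAF/SAM).

    Spans targeting ``construct_name`` are LV evidence; all others are host.
    The same LV-first gate, uniqueness ratio and anchor-length rules apply,
    so an external long-read aligner can replace the internal one wholesale.
    """
    params = params or TriageParams()
    by_read: dict[str, list[AlignmentSpan]] = {}
    for s in spans:
        by_read.setdefault(s.query_id, []).append(s)
    results: list[TriageResult] = []
    for read in reads:
        rs = by_read.get(read.id, [])
        lv_spans = sorted(
            (s for s in rs if s.target_name == construct_name),
            key=lambda s: (-s.score, s.target_start, s.target_name),
        )
        host_spans = sorted(
            (s for s in rs if s.target_name != construct_name),
            key=lambda s: (-s.score, s.target_start, s.target_name),
        )
        L = len(read)
        if not lv_spans:
            cls: Classification = "host_only" if host_spans else "unmapped"
            results.append(TriageResult(read.id, L, None, None, False, cls,
                                        read_sequence=read.sequence))
            continue
        lv = lv_spans[0]
        # honour the LV-first gate: host evidence must come from the non-LV
        # portion of the read
        usable = [
            s
            for s in host_spans
            if min(s.query_end, lv.query_end) - max(s.query_start, lv.query_start)
            <= params.mask_cushion
        ]
        flank_lv = [s for s in lv_spans[1:]]
        if not usable:
            results.append(
                TriageResult(
                    read.id, L, lv, None, False, "vector_only",
                    lv_spans=lv_spans, flank_lv_spans=flank_lv,
                    read_sequence=read.sequence,
                )
            )
            continue
        best = usable[0]
        unique = True
        if len(usable) > 1:
            unique = best.score >= params.uniqueness_ratio * usable[1].score
        anchored = best.query_span >= params.min_host_anchor
        unique_host = unique and anchored
        if unique_host:
            cls = "junction_candidate"
        elif not unique:
            cls = "ambiguous"
        else:
            cls = "vector_only"
        results.append(
            TriageResult(
                read.id, L, lv, best, unique_host, cls,
                lv_spans=lv_spans, host_spans=usable, flank_lv_spans=flank_lv,
                read_sequence=read.sequence,
            )
        )
    return results
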