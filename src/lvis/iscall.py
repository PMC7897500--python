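"""Read filtering, junction calling, episome elimination and clustering.

Junction geometry convention: every call carries the host-side *boundary*
coordinate where the host alignment meets the vector.  When the host segment
lies downstream of the vector (host span on the read maps to the plus
strand) the boundary is the first base of the duplicated motif; when it lies
upstream (minus strand) the boundary is motif start + TSD.  Bidirectional
clusters therefore estimate the TSD as upstream minus downstream boundary,
and the site position is the downstream boundary (the 5'-most copy of the
duplicated motif).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Literal, Optional, Sequence

from lvis._util import revcomp
from lvis.align import (
    MinimizerIndex,
    TriageParams,
    TriageResult,
    build_index,
    triage_reads,
)
from lvis.model import ArmSpec, ProvirusConstruct, arm_specs
from lvis.seqio import LongRead

Bucket = Literal[
    "dropped_quality", "dropped_size", "episome", "no_structure", "ambiguous", "member"
]


@dataclass
class JunctionCall:
    """Per-read integration evidence."""

    read_id: str
    chromosome: str
    position: int  # host boundary coordinate, 0-based (see module docstring)
    host_strand: Literal["+", "-"]
    vector_end: Literal["left_terminus", "right_terminus"]
    vector_strand_in_host: Literal["+", "-"]
    cut_site_used: str
    boundary: Literal["downstream", "upstream"] = "downstream"

    def __post_init__(self) -> None:
        self.boundary = "downstream" if self.host_strand == "+" else "upstream"


@dataclass
class IntegrationSite:
    """One clustered unique integration site."""

    is_id: str
    chromosome: str
    position: int
    strand: Literal["+", "-"]
    support: int
    bidirectional: bool
    tsd_estimate: Optional[int]
    reads: list[str] = field(default_factory=list)
    calls: list[JunctionCall] = field(default_factory=list, repr=False)
    # annotation slots filled by lvis.annotate
    category: Optional[str] = None
    gene: Optional[str] = None
    nearest_gene: Optional[str] = None
    nearest_distance: Optional[int] = None


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _materialize(reads: Iterable[LongRead]) -> list[LongRead]:
    return list(reads)


def quality_filter(
    reads: Iterable[LongRead], min_mean_q: float = 9.0
) -> tuple[list[LongRead], int]:
    """Keep reads whose mean Phred quality is strictly greater than the cutoff
    (a read averaging exactly the cutoff is dropped)."""
    reads = _materialize(reads)
    kept = [r for r in reads if r.mean_quality > min_mean_q]
    return kept, len(reads) - len(kept)


def size_select(
    reads: Iterable[LongRead],
    specs: Sequence[ArmSpec],
    min_host_anchor: int = 200,
) -> tuple[list[LongRead], int]:
    """Pre-alignment size filter: a useful read must span at least the
    shortest cut-to-terminus arm plus a mappable chunk of host genome."""
    if not specs:
        raise ValueError("empty arm specs")
    threshold = min(s.arm_length for s in specs) + min_host_anchor
    reads = _materialize(reads)
    kept = [r for r in reads if len(r) >= threshold]
    return kept, len(reads) - len(kept)


# ---------------------------------------------------------------------------
# Junction calling
# ---------------------------------------------------------------------------

def _refine_boundary(
    read_seq: str,
    q_term: int,
    host_strand: str,
    ref: str,
    b0: int,
    window: int = 30,
    radius: int = 15,
) -> int:
    """Sharpen the junction coordinate by sliding the read's first
    post-terminus bases along the host reference near the span-derived
    estimate ``b0``.  Exact on error-free reads; falls back to ``b0`` when no
    convincing placement exists."""
    probe = read_seq[q_term : q_term + window]
    if len(probe) < 10:
        return b0
    best_pos, best_m = b0, -1
    if host_strand == "+":
        lo = max(0, b0 - radius)
        hi = min(len(ref) - len(probe), b0 + radius)
        for t in range(lo, hi + 1):
            seg = ref[t : t + len(probe)]
            m = sum(a == b for a, b in zip(probe, seg))
            if m > best_m or (m == best_m and abs(t - b0) < abs(best_pos - b0)):
                best_m, best_pos = m, t
    else:
        rp = revcomp(probe)
        lo = max(len(rp), b0 - radius)
        hi = min(len(ref), b0 + radius)
        for t in range(lo, hi + 1):
            seg = ref[t - len(rp) : t]
            m = sum(a == b for a, b in zip(rp, seg))
            if m > best_m or (m == best_m and abs(t - b0) < abs(best_pos - b0)):
                best_m, best_pos = m, t
    if best_m >= 0.6 * len(probe):
        return best_pos
    return b0


def call_junction_ex(
    tr: TriageResult,
    construct: ProvirusConstruct,
    specs: Sequence[ArmSpec],
    end_slack: int = 50,
    cut_slack: int = 50,
    max_gap: int = 20,
    max_overlap: int = 12,
    host_sequences: Optional[dict[str, str]] = None,
) -> tuple[Optional[JunctionCall], Optional[str]]:
    """Junction call plus a failure reason when the read lacks the required
    cut-site -> terminus -> host structure.

    The reported coordinate is refined to the read position where the vector
    terminus lands (``lv.query_end``): the construct sequence ends at its
    terminus, so that query coordinate cannot creep into host, whereas the
    host-span edge can absorb a few coincidentally matching vector bases.
    The host target coordinate is shifted by the query-side offset between
    the two spans, which makes junctions exact on error-free reads.
    """
    if tr.classification != "junction_candidate":
        return None, tr.classification
    lv, host = tr.lv_span, tr.host_span
    if lv.query_start > cut_slack:
        return None, "no_cut_at_read_start"
    gap = host.query_start - lv.query_end
    if gap > max_gap or -gap > max_overlap:
        return None, "junction_gap"
    cut_coord = lv.target_start if lv.strand == "+" else lv.target_end
    far_coord = lv.target_end if lv.strand == "+" else lv.target_start
    guide = min(construct.guides, key=lambda g: abs(g.cut_position - cut_coord))
    if abs(guide.cut_position - cut_coord) > cut_slack:
        return None, "no_cut_site"
    if guide.arm == "left":
        if far_coord > end_slack:
            return None, "short_arm"
        vector_end = "left_terminus"
    else:
        if far_coord < construct.length - end_slack:
            return None, "short_arm"
        vector_end = "right_terminus"
    host_strand = host.strand
    offset = host.query_start - lv.query_end
    if host_strand == "+":
        position = host.target_start - offset
    else:
        position = host.target_end + offset
    if host_sequences is not None and tr.read_sequence is not None:
        ref = host_sequences.get(host.target_name)
        if ref is not None:
            position = _refine_boundary(
                tr.read_sequence, lv.query_end, host_strand, ref, position
            )
    return (
        JunctionCall(
            read_id=tr.read_id,
            chromosome=host.target_name,
            position=position,
            host_strand=host_strand,
            vector_end=vector_end,
            vector_strand_in_host="+" if lv.strand == host_strand else "-",
            cut_site_used=guide.name,
        ),
        None,
    )


def call_junction(tr, construct, specs, **kwargs) -> Optional[JunctionCall]:
    return call_junction_ex(tr, construct, specs, **kwargs)[0]


def classify_episome(
    tr: TriageResult,
    construct: ProvirusConstruct,
    end_slack: int = 50,
    min_host_anchor: int = 200,
) -> Optional[str]:
    """Reason string when the read looks episomal (LTR circle / no host),
    otherwise None.  Conservative: vector-only reads that reach a terminus
    are excluded even when too short to prove a circle junction."""
    lv = tr.lv_span
    if lv is None or tr.classification == "junction_candidate":
        return None
    if tr.classification == "ambiguous":
        return None
    L = tr.read_length
    reaches_left = lv.target_start <= end_slack
    reaches_right = lv.target_end >= construct.length - end_slack
    if not (reaches_left or reaches_right):
        return None
    # query flank lying beyond the terminus on the read
    if lv.strand == "+":
        flank = (L - lv.query_end) if reaches_right else lv.query_start
        flank_lo = lv.query_end if reaches_right else 0
        flank_hi = L if reaches_right else lv.query_start
    else:
        flank = (L - lv.query_end) if reaches_left else lv.query_start
        flank_lo = lv.query_end if reaches_left else 0
        flank_hi = L if reaches_left else lv.query_start
    for s in tr.flank_lv_spans:
        if s.query_start >= flank_lo and s.query_end <= flank_hi + 1:
            return "circle_junction"
    if flank >= min_host_anchor:
        return "no_host_anchor"
    return "too_short_to_judge"


def detect_episome(tr: TriageResult, construct: ProvirusConstruct, **kwargs) -> bool:
    return classify_episome(tr, construct, **kwargs) is not None


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def estimate_tsd(site: IntegrationSite, tsd_max: int = 7) -> Optional[int]:
    """Target-site duplication length from the bidirectional junction overlap:
    median upstream boundary minus median downstream boundary, clipped to
    [0, tsd_max].  Absent for unidirectional sites."""
    if not site.bidirectional:
        return None
    down = [c.position for c in site.calls if c.boundary == "downstream"]
    up = [c.position for c in site.calls if c.boundary == "upstream"]
    if not down or not up:
        return None
    est = round(median(up) - median(down))
    return max(0, min(tsd_max, int(est)))


def cluster_calls(
    calls: Sequence[JunctionCall],
    merge_window: int = 10,
    tsd_max: int = 7,
) -> list[IntegrationSite]:
    """Single-linkage clustering of junction calls into unique sites.

    Same-boundary calls merge within ``merge_window``; opposite-boundary
    calls merge when upstream - downstream is consistent with a duplication
    of 0..tsd_max bp (plus merge_window slack for ragged junctions).
    """
    by_chrom: dict[str, list[JunctionCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chromosome, []).append(c)
    clusters: list[list[JunctionCall]] = []
    reach = tsd_max + merge_window
    for chrom in sorted(by_chrom):
        cs = sorted(by_chrom[chrom], key=lambda c: (c.position, c.read_id))
        parent = list(range(len(cs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i: int, j: int) -> None:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

        for i, a in enumerate(cs):
            for j in range(i + 1, len(cs)):
                b = cs[j]
                if b.position - a.position > reach:
                    break
                if a.boundary == b.boundary:
                    if b.position - a.position <= merge_window:
                        union(i, j)
                else:
                    d, u = (a, b) if a.boundary == "downstream" else (b, a)
                    if -merge_window <= u.position - d.position <= reach:
                        union(i, j)
        groups: dict[int, list[JunctionCall]] = {}
        for i in range(len(cs)):
            groups.setdefault(find(i), []).append(cs[i])
        clusters.extend(groups[g] for g in sorted(groups))

    sites: list[IntegrationSite] = []
    for members in clusters:
        down = [c.position for c in members if c.boundary == "downstream"]
        up = [c.position for c in members if c.boundary == "upstream"]
        position = int(median(down)) if down else int(median(up))
        ends = {c.vector_end for c in members}
        strands = [c.vector_strand_in_host for c in members]
        strand = "+" if strands.count("+") >= strands.count("-") else "-"
        site = IntegrationSite(
            is_id="",
            chromosome=members[0].chromosome,
            position=position,
            strand=strand,
            support=len(members),
            bidirectional=len(ends) == 2,
            tsd_estimate=None,
            reads=[c.read_id for c in members],
            calls=list(members),
        )
        site.tsd_estimate = estimate_tsd(site, tsd_max=tsd_max)
        sites.append(site)
    sites.sort(key=lambda s: (s.chromosome, s.position))
    for i, s in enumerate(sites, start=1):
        s.is_id = f"IS_{i}"
    return sites


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineParams:
    min_mean_q: float = 9.0
    min_host_anchor: int = 200
    merge_window: int = 10
    tsd_max: int = 7
    end_slack: int = 50
    cut_slack: int = 50
    triage: TriageParams = field(default_factory=TriageParams)

    def __post_init__(self) -> None:
        self.triage.min_host_anchor = self.min_host_anchor


@dataclass
class PipelineResult:
    sites: list[IntegrationSite]
    calls: list[JunctionCall]
    triage: list[TriageResult]
    decisions: dict[str, tuple[Bucket, str]]  # read id -> (bucket, reason)
    counts: dict[str, int]
    n_input: int
    n_lv_mapped: int  # reads with any alignment to the LV genome

    def conserved(self) -> bool:
        return sum(self.counts.values()) == self.n_input


def run_pipeline(
    reads: Sequence[LongRead],
    construct: ProvirusConstruct,
    host_index: MinimizerIndex,
    construct_index: Optional[MinimizerIndex] = None,
    params: Optional[PipelineParams] = None,
) -> PipelineResult:
    """Filter -> triage -> junction call -> episome gate -> cluster.

    Every input read lands in exactly one bucket: dropped_quality,
    dropped_size, episome, no_structure, ambiguous or member(-of-site).
    """
    params = params or PipelineParams()
    specs = arm_specs(construct)
    if construct_index is None:
        construct_index = build_index({construct.name: construct.sequence})
    decisions: dict[str, tuple[Bucket, str]] = {}
    counts = {
        "dropped_quality": 0,
        "dropped_size": 0,
        "episome": 0,
        "no_structure": 0,
        "ambiguous": 0,
        "member": 0,
    }
    passq, _ = quality_filter(reads, params.min_mean_q)
    passq_ids = {r.id for r in passq}
    for r in reads:
        if r.id not in passq_ids:
            decisions[r.id] = ("dropped_quality", f"mean Q <= {params.min_mean_q}")
            counts["dropped_quality"] += 1
    passs, _ = size_select(passq, specs, params.min_host_anchor)
    passs_ids = {r.id for r in passs}
    for r in passq:
        if r.id not in passs_ids:
            decisions[r.id] = ("dropped_size", "below arm+anchor size threshold")
            counts["dropped_size"] += 1
    triaged = triage_reads(passs, construct_index, host_index, params.triage)
    calls: list[JunctionCall] = []
    n_lv = 0
    for tr in triaged:
        if tr.lv_span is not None:
            n_lv += 1
        if tr.classification == "junction_candidate":
            call, reason = call_junction_ex(
                tr, construct, specs,
                end_slack=params.end_slack, cut_slack=params.cut_slack,
                host_sequences=host_index.sequences,
            )
            if call is not None:
                calls.append(call)
                decisions[tr.read_id] = ("member", "junction call")
                counts["member"] += 1
                continue
            decisions[tr.read_id] = ("no_structure", reason or "structure")
            counts["no_structure"] += 1
        elif tr.classification == "ambiguous":
            decisions[tr.read_id] = ("ambiguous", "multi-mapping host anchor")
            counts["ambiguous"] += 1
        elif tr.classification == "vector_only":
            reason = classify_episome(
                tr, construct,
                end_slack=params.end_slack,
                min_host_anchor=params.min_host_anchor,
            )
            if reason is not None:
                decisions[tr.read_id] = ("episome", reason)
                counts["episome"] += 1
            else:
                decisions[tr.read_id] = ("no_structure", "vector-only (inward/truncated)")
                counts["no_structure"] += 1
        else:  # host_only / unmapped
            decisions[tr.read_id] = ("no_structure", tr.classification)
            counts["no_structure"] += 1
    sites = cluster_calls(calls, params.merge_window, params.tsd_max)
    return PipelineResult(
        sites=sites,
        calls=calls,
        triage=triaged,
        decisions=decisions,
        counts=counts,
        n_input=len(reads),
        n_lv_mapped=n_lv,
    )


def write_decisions(result: PipelineResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tbucket\treason\n")
        for rid, (bucket, reason) in result.decisions.items():
            fh.write(f"{rid}\t{bucket}\t{reason}\n")
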