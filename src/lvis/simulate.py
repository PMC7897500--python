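"""Synthetic data: host genome with gene model, planted integrations with
target-site duplications, and Cas9-cut directional long reads.

Every read is tracked in a provenance table and every planted site in a
truth table, so the whole pipeline can be validated end to end without
external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from lvis._util import revcomp
from lvis.model import ProvirusConstruct, design_guides
from lvis.seqio import Gene, LongRead

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimParams:
    """Knobs for the simulator; see field comments for defaults' provenance."""

    n_chromosomes: int = 3
    chrom_length: int = 1_000_000
    n_genes: int = 30
    exons_per_gene: int = 3
    n_integrations: int = 10
    vcn: float = 5.0  # copies/cell, enrichment bookkeeping only
    tsd_length: Union[int, tuple[int, int]] = (5, 6)
    read_length_mean: int = 12_000
    read_length_sd: int = 1_500
    outward_bias: float = 0.9
    error_rate: float = 0.0
    background_fraction: float = 0.0
    circle_fraction: float = 0.0
    n_reads: int = 100
    reads_per_end: Optional[int] = None  # overrides n_reads for junction reads
    gene_density_slope: float = 0.0  # 0 = uniform genes across chromosomes
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("outward_bias", "error_rate", "background_fraction", "circle_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.background_fraction + self.circle_fraction > 1.0:
            raise ValueError("background_fraction + circle_fraction exceeds 1")
        tsd = self.tsd_length
        if isinstance(tsd, int):
            if tsd < 0:
                raise ValueError("tsd_length must be >= 0")
        else:
            lo, hi = tsd
            if not (0 <= lo <= hi):
                raise ValueError(f"bad tsd_length range {tsd}")


@dataclass
class TruthRecord:
    """Ground truth for one planted integration.  ``position`` is the host
    coordinate of the first base of the duplicated motif."""

    is_id: str
    chromosome: str
    position: int
    strand: str
    tsd: int


@dataclass
class Placement:
    """Where a provirus landed in the *modified* genome coordinate frame."""

    is_id: str
    chromosome: str
    mod_start: int  # start of the inserted vector block in the modified chrom
    strand: str
    tsd: int
    host_position: int


@dataclass
class HostGenome:
    chromosomes: dict[str, str]
    genes: list[Gene]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.chromosomes.items()}


@dataclass
class ModifiedGenome:
    chromosomes: dict[str, str]
    host: HostGenome
    placements: list[Placement]
    construct_name: str


@dataclass
class Provenance:
    category: str  # junction_left | junction_right | background | circle
    is_id: Optional[str] = None


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=n, dtype=np.uint8)].tobytes().decode()


def make_host(params: SimParams, rng: Optional[np.random.Generator] = None) -> HostGenome:
    """Random host genome plus a non-overlapping gene model.

    Gene counts per chromosome follow weights ``1 + slope * chrom_index`` so a
    density gradient can be requested; placement is slot-based so genes never
    overlap.  Deterministic for a fixed seed.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    chroms = {
        f"chr{i + 1}": _random_dna(params.chrom_length, rng)
        for i in range(params.n_chromosomes)
    }
    weights = np.array(
        [1.0 + params.gene_density_slope * i for i in range(params.n_chromosomes)]
    )
    weights /= weights.sum()
    counts = rng.multinomial(params.n_genes, weights)
    genes: list[Gene] = []
    gi = 0
    for ci, (chrom, n_here) in enumerate(zip(chroms, counts)):
        if n_here == 0:
            continue
        slot = params.chrom_length // n_here
        max_gene = min(10_000, slot - 2)
        if max_gene < 200 * params.exons_per_gene:
            raise ValueError(
                f"cannot pack {n_here} genes of >= {200 * params.exons_per_gene} bp "
                f"into {chrom} ({params.chrom_length} bp)"
            )
        for s in range(n_here):
            glen = int(rng.integers(max(2_000, 200 * params.exons_per_gene), max_gene + 1))
            start = int(rng.integers(s * slot, (s + 1) * slot - glen))
            end = start + glen
            # exons: equally spaced slots inside the gene, one exon per slot
            exons = []
            if params.exons_per_gene > 0:
                eslot = glen // params.exons_per_gene
                for e in range(params.exons_per_gene):
                    elen = int(rng.integers(100, max(101, eslot // 2)))
                    es = start + e * eslot + int(rng.integers(0, max(1, eslot - elen)))
                    exons.append((es, es + elen))
            gi += 1
            genes.append(
                Gene(
                    name=f"gene{gi}",
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=exons,
                )
            )
    return HostGenome(chromosomes=chroms, genes=genes)


def random_construct(
    length: int = 5_000,
    seed: int = 0,
    n_per_arm: int = 2,
    name: str = "vector",
) -> ProvirusConstruct:
    """Random provirus construct with an auto-designed rule-compliant panel."""
    rng = np.random.default_rng(seed)
    for _ in range(20):
        seq = _random_dna(length, rng)
        try:
            guides = design_guides(seq, n_per_arm=n_per_arm)
        except ValueError:
            continue
        return ProvirusConstruct(name=name, sequence=seq, guides=guides)
    raise RuntimeError("failed to design a compliant guide panel on random sequence")


def _draw_tsd(params: SimParams, rng: np.random.Generator) -> int:
    if isinstance(params.tsd_length, int):
        return params.tsd_length
    lo, hi = params.tsd_length
    return int(rng.integers(lo, hi + 1))


def plant_integrations(
    host: HostGenome,
    construct: ProvirusConstruct,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ModifiedGenome, list[TruthRecord]]:
    """Insert the provirus at random host positions with TSD duplication.

    At each site the ``tsd`` bp host motif starting at the sampled position is
    duplicated so it flanks the inserted (randomly stranded) provirus.  Sites
    keep a minimum separation of twice the mean read length so no read spans
    two events, and stay clear of chromosome ends by the mean read length.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    margin = params.read_length_mean
    min_sep = 2 * params.read_length_mean
    names = list(host.chromosomes)
    lengths = np.array([len(host.chromosomes[n]) for n in names], dtype=float)
    usable = lengths - 2 * margin
    if (usable <= 0).any():
        raise ValueError("chromosomes shorter than twice the read-length margin")
    capacity = int((usable // min_sep).sum())
    if params.n_integrations > capacity:
        raise ValueError(
            f"{params.n_integrations} integrations exceed genome capacity "
            f"(~{capacity} at {min_sep} bp separation)"
        )
    chosen: dict[str, list[int]] = {n: [] for n in names}
    probs = usable / usable.sum()
    for _ in range(params.n_integrations):
        for _attempt in range(1000):
            chrom = names[int(rng.choice(len(names), p=probs))]
            pos = int(rng.integers(margin, len(host.chromosomes[chrom]) - margin))
            if all(abs(pos - p) >= min_sep for p in chosen[chrom]):
                chosen[chrom].append(pos)
                break
        else:
            raise ValueError("could not place integrations with required separation")

    truth: list[TruthRecord] = []
    placements: list[Placement] = []
    modified: dict[str, str] = {}
    idx = 0
    site_meta = []
    for chrom in names:
        for pos in sorted(chosen[chrom]):
            idx += 1
            site_meta.append((chrom, pos, f"IS_{idx}"))
    for chrom in names:
        seq = host.chromosomes[chrom]
        pieces: list[str] = []
        prev = 0
        total = 0
        for c, pos, is_id in site_meta:
            if c != chrom:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            tsd = _draw_tsd(params, rng)
            vec = construct.sequence if strand == "+" else revcomp(construct.sequence)
            upstream = seq[prev : pos + tsd]
            pieces.append(upstream)
            total += len(upstream)
            placements.append(
                Placement(
                    is_id=is_id,
                    chromosome=chrom,
                    mod_start=total,
                    strand=strand,
                    tsd=tsd,
                    host_position=pos,
                )
            )
            truth.append(TruthRecord(is_id, chrom, pos, strand, tsd))
            pieces.append(vec)
            total += len(vec)
            prev = pos
        pieces.append(seq[prev:])
        modified[chrom] = "".join(pieces)
    return (
        ModifiedGenome(
            chromosomes=modified,
            host=host,
            placements=placements,
            construct_name=construct.name,
        ),
        truth,
    )


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitutions (60%), insertions (20%) and deletions (20%) at ``rate``."""
    if rate <= 0.0 or not seq:
        return seq
    n = len(seq)
    r = rng.random(n)
    p_sub, p_ins = 0.6 * rate, 0.2 * rate
    err_idx = np.nonzero(r < rate)[0]
    if err_idx.size == 0:
        return seq
    out: list[str] = []
    prev = 0
    for i in err_idx:
        out.append(seq[prev:i])
        ri = r[i]
        if ri < p_sub:  # substitution
            shift = int(rng.integers(1, 4))
            base = "ACGT"[("ACGT".index(seq[i]) + shift) % 4] if seq[i] in "ACGT" else "A"
            out.append(base)
        elif ri < p_sub + p_ins:  # insertion before the base
            out.append("ACGT"[int(rng.integers(0, 4))])
            out.append(seq[i])
        # else: deletion -- emit nothing
        prev = i + 1
    out.append(seq[prev:])
    return "".join(out)


def _phred_for(rate: float) -> int:
    if rate <= 0:
        return 40
    return max(2, min(40, round(-10.0 * math.log10(rate))))


def _make_read(rid: str, seq: str, params: SimParams, rng: np.random.Generator) -> LongRead:
    seq = _apply_errors(seq, params.error_rate, rng)
    q = _phred_for(params.error_rate)
    return LongRead(id=rid, sequence=seq, qualities=[q] * len(seq))


def _draw_length(params: SimParams, rng: np.random.Generator) -> int:
    ln = rng.normal(params.read_length_mean, params.read_length_sd)
    return max(200, int(ln))


def _junction_read_seq(
    mod: ModifiedGenome,
    construct: ProvirusConstruct,
    placement: Placement,
    arm: str,
    outward: bool,
    length: int,
    rng: np.random.Generator,
) -> str:
    """Sequence of one read starting at a cut of ``arm`` and running outward
    (through the served terminus into host) or inward (staying in-vector)."""
    guides = [g for g in construct.guides if g.arm == arm]
    g = guides[int(rng.integers(0, len(guides)))]
    Lv = construct.length
    chrom_seq = mod.chromosomes[placement.chromosome]
    if placement.strand == "+":
        cut_m = placement.mod_start + g.cut_position
    else:
        cut_m = placement.mod_start + (Lv - g.cut_position)
    rightward_out = (arm == "left") == (placement.strand == "-")
    rightward = rightward_out if outward else not rightward_out
    if not outward:
        # wrong-direction read: truncate inside the vector
        to_far = Lv - g.cut_position if arm == "left" else g.cut_position
        length = min(length, to_far)
    if rightward:
        return chrom_seq[cut_m : cut_m + length]
    return revcomp(chrom_seq[max(0, cut_m - length) : cut_m])


def _circle_read_seq(
    construct: ProvirusConstruct, length: int, rng: np.random.Generator
) -> str:
    """Read from a 2-LTR episomal circle: runs outward from a cut, across the
    terminus-terminus junction, and back into the construct."""
    g = construct.guides[int(rng.integers(0, len(construct.guides)))]
    Lv = construct.length
    length = min(length, Lv)
    circ = construct.sequence + construct.sequence
    if g.arm == "left":
        start = Lv + g.cut_position
        return revcomp(circ[start - length : start])
    return circ[g.cut_position : g.cut_position + length]


def emit_reads(
    mod: ModifiedGenome,
    construct: ProvirusConstruct,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[LongRead], dict[str, Provenance]]:
    """Emit junction, background and episome-circle reads with provenance.

    With ``reads_per_end`` set, every site gets exactly that many junction
    reads per vector end and background/circle counts are derived from the
    requested fractions; otherwise ``n_reads`` is split multinomially.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 2)
    bf, cf = params.background_fraction, params.circle_fraction
    jf = 1.0 - bf - cf
    placements = mod.placements
    jobs: list[tuple[str, Optional[Placement], Optional[str]]] = []
    if params.reads_per_end is not None:
        if jf <= 0 and placements:
            raise ValueError("reads_per_end requires background+circle fractions < 1")
        n_junction = len(placements) * 2 * params.reads_per_end
        total = n_junction / jf if jf > 0 else 0
        n_bg = int(round(total * bf))
        n_circ = int(round(total * cf))
        for p in placements:
            for end in ("left", "right"):
                for _ in range(params.reads_per_end):
                    jobs.append(("junction", p, end))
    else:
        n_bg, n_circ, n_junction = rng.multinomial(params.n_reads, [bf, cf, max(jf, 0.0)])
        if n_junction and not placements:
            raise ValueError("junction reads requested but no integrations planted")
        for _ in range(n_junction):
            p = placements[int(rng.integers(0, len(placements)))]
            end = "left" if rng.random() < 0.5 else "right"
            jobs.append(("junction", p, end))
    reads: list[LongRead] = []
    provenance: dict[str, Provenance] = {}
    host_names = list(mod.host.chromosomes)
    host_lens = np.array([len(mod.host.chromosomes[n]) for n in host_names], dtype=float)
    host_probs = host_lens / host_lens.sum()
    ji = 0
    for kind, p, end in jobs:
        ji += 1
        outward = rng.random() < params.outward_bias
        length = _draw_length(params, rng)
        seq = _junction_read_seq(mod, construct, p, end, outward, length, rng)
        rid = f"junc{ji}_{p.is_id}_{end}{'_in' if not outward else ''}"
        reads.append(_make_read(rid, seq, params, rng))
        provenance[rid] = Provenance(category=f"junction_{end}", is_id=p.is_id)
    for i in range(n_bg):
        chrom = host_names[int(rng.choice(len(host_names), p=host_probs))]
        seq_full = mod.host.chromosomes[chrom]
        length = min(_draw_length(params, rng), len(seq_full))
        start = int(rng.integers(0, len(seq_full) - length + 1))
        sub = seq_full[start : start + length]
        if rng.random() < 0.5:
            sub = revcomp(sub)
        rid = f"bg{i + 1}"
        reads.append(_make_read(rid, sub, params, rng))
        provenance[rid] = Provenance(category="background")
    for i in range(n_circ):
        rid = f"circ{i + 1}"
        seq = _circle_read_seq(construct, _draw_length(params, rng), rng)
        reads.append(_make_read(rid, seq, params, rng))
        provenance[rid] = Provenance(category="circle")
    return reads, provenance


@dataclass
class SimBundle:
    params: SimParams
    construct: ProvirusConstruct
    host: HostGenome
    modified: ModifiedGenome
    truth: list[TruthRecord]
    reads: list[LongRead]
    provenance: dict[str, Provenance]


def simulate_run(
    params: SimParams, construct: Optional[ProvirusConstruct] = None
) -> SimBundle:
    """One-call simulation: host, integrations, reads, truth, provenance."""
    rng = np.random.default_rng(params.seed)
    if construct is None:
        construct = random_construct(seed=params.seed)
    host = make_host(params, rng)
    mod, truth = plant_integrations(host, construct, params, rng)
    reads, provenance = emit_reads(mod, construct, params, rng)
    return SimBundle(params, construct, host, mod, truth, reads, provenance)


def write_truth(truth: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("is_id\tchromosome\tposition\tstrand\ttsd\n")
        for t in truth:
            fh.write(f"{t.is_id}\t{t.chromosome}\t{t.position}\t{t.strand}\t{t.tsd}\n")


def write_provenance(provenance: dict[str, Provenance], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcategory\tis_id\n")
        for rid, p in provenance.items():
            fh.write(f"{rid}\t{p.category}\t{p.is_id or ''}\n")
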