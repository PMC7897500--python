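"""Readers and writers for the standard formats the pipeline touches.

Internals use 0-based half-open coordinates everywhere.  SAM support is a
deliberate subset: primary/secondary/supplementary records with plain CIGARs;
anything outside that subset raises rather than being skipped silently.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Optional, Sequence

import pysam
from Bio import SeqIO

__all__ = [
    "LongRead",
    "AlignmentSpan",
    "Gene",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_alignments",
    "write_paf",
    "write_sites",
    "read_sites",
    "write_gff3",
    "read_gff3",
    "write_bed12",
    "read_bed12",
]


@dataclass
class LongRead:
    """A basecalled read: id, sequence and per-base Phred qualities."""

    id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        if not self.qualities:
            return 0.0
        return sum(self.qualities) / len(self.qualities)


@dataclass
class AlignmentSpan:
    """One aligned block; the common currency of the internal aligner and of
    PAF/SAM import."""

    query_id: str
    query_start: int
    query_end: int
    target_name: str
    target_start: int
    target_end: int
    strand: Literal["+", "-"]
    matches: int
    block_length: int
    score: float
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.query_end <= self.query_start:
            raise ValueError("query_end must exceed query_start")
        if self.target_end <= self.target_start:
            raise ValueError("target_end must exceed target_start")
        if self.matches > self.block_length:
            raise ValueError("matches cannot exceed block_length")

    @property
    def identity(self) -> float:
        return self.matches / self.block_length if self.block_length else 0.0

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass
class Gene:
    """One gene-model feature: body interval plus exon sub-intervals."""

    name: str
    chromosome: str
    start: int
    end: int
    strand: Literal["+", "-"]
    exons: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def read_fastq(path) -> Iterator[LongRead]:
    """Lazily yield reads from a FASTQ file (Phred+33)."""
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield LongRead(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ {path}: {exc}") from exc


def write_fastq(reads: Sequence[LongRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def read_fasta(path) -> dict[str, str]:
    """Load a (small) FASTA into an ordered name -> sequence dict."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments (PAF + SAM subset)
# ---------------------------------------------------------------------------

_ALLOWED_SAM_FLAGS = 0x10 | 0x100 | 0x800
_QUERY_OPS = {0, 1, 7, 8}  # M I = X
_TARGET_OPS = {0, 2, 7, 8}  # M D = X
_CLIP_OPS = {4, 5}  # S H


def read_alignments(path, dialect: Literal["paf", "sam"] = "paf") -> list[AlignmentSpan]:
    """Parse alignments into normalized spans.

    PAF coordinates map directly.  For SAM, query coordinates are recovered
    from the CIGAR (clips included, so split/hard-clipped supplementary
    records land in original-read coordinates, matching PAF).
    """
    if dialect == "paf":
        return _read_paf(path)
    if dialect == "sam":
        return _read_sam(path)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def _read_paf(path) -> list[AlignmentSpan]:
    spans: list[AlignmentSpan] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: PAF line has {len(cols)} columns")
            try:
                tags = dict(
                    (c.split(":", 2)[0], c.split(":", 2)[1:]) for c in cols[12:]
                )
                matches = int(cols[9])
                block = int(cols[10])
                score = float(tags["AS"][1]) if "AS" in tags else float(matches)
                is_primary = tags.get("tp", [None, "P"])[1] == "P"
                spans.append(
                    AlignmentSpan(
                        query_id=cols[0],
                        query_start=int(cols[2]),
                        query_end=int(cols[3]),
                        strand=cols[4],
                        target_name=cols[5],
                        target_start=int(cols[7]),
                        target_end=int(cols[8]),
                        matches=matches,
                        block_length=block,
                        score=score,
                        is_primary=is_primary,
                    )
                )
            except (ValueError, IndexError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable PAF line: {exc}") from exc
    return spans


def _read_sam(path) -> list[AlignmentSpan]:
    spans: list[AlignmentSpan] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.flag & ~(_ALLOWED_SAM_FLAGS):
                raise ValueError(
                    f"unsupported SAM flag {rec.flag} for read {rec.query_name!r}; "
                    "only plain mapped/reverse/secondary/supplementary records "
                    "are handled"
                )
            cig = rec.cigartuples or []
            if any(op not in _QUERY_OPS | _TARGET_OPS | _CLIP_OPS for op, _ in cig):
                bad = [op for op, _ in cig if op not in _QUERY_OPS | _TARGET_OPS | _CLIP_OPS]
                raise ValueError(
                    f"unsupported CIGAR op(s) {bad} for read {rec.query_name!r}"
                )
            lead = 0
            for op, n in cig:
                if op in _CLIP_OPS:
                    lead += n
                else:
                    break
            qlen = sum(n for op, n in cig if op in _QUERY_OPS)
            total = sum(n for op, n in cig if op in _QUERY_OPS | _CLIP_OPS)
            if rec.is_reverse:
                qstart, qend = total - (lead + qlen), total - lead
            else:
                qstart, qend = lead, lead + qlen
            m_cols = sum(n for op, n in cig if op in (0, 7, 8))
            indel = sum(n for op, n in cig if op in (1, 2))
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            subs = max(0, int(nm) - indel)
            matches = m_cols - subs
            block = m_cols + indel
            score = float(rec.get_tag("AS")) if rec.has_tag("AS") else float(matches)
            spans.append(
                AlignmentSpan(
                    query_id=rec.query_name,
                    query_start=qstart,
                    query_end=qend,
                    strand="-" if rec.is_reverse else "+",
                    target_name=rec.reference_name,
                    target_start=rec.reference_start,
                    target_end=rec.reference_start
                    + sum(n for op, n in cig if op in _TARGET_OPS),
                    matches=matches,
                    block_length=block,
                    score=score,
                    is_primary=not (rec.is_secondary or rec.is_supplementary),
                )
            )
    return spans


def write_paf(spans: Sequence[AlignmentSpan], path, query_lengths=None, target_lengths=None) -> None:
    """Emit spans as minimal 12-column PAF (+AS/tp tags)."""
    query_lengths = query_lengths or {}
    target_lengths = target_lengths or {}
    with open(path, "w") as fh:
        for s in spans:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        s.query_id,
                        query_lengths.get(s.query_id, s.query_end),
                        s.query_start,
                        s.query_end,
                        s.strand,
                        s.target_name,
                        target_lengths.get(s.target_name, s.target_end),
                        s.target_start,
                        s.target_end,
                        s.matches,
                        s.block_length,
                        255,
                        f"AS:i:{int(s.score)}",
                        f"tp:A:{'P' if s.is_primary else 'S'}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Integration-site tables
# ---------------------------------------------------------------------------

SITE_TSV_COLUMNS = [
    "is_id",
    "chromosome",
    "position",
    "strand",
    "support",
    "bidirectional",
    "tsd",
    "category",
    "gene",
    "nearest_gene",
    "nearest_distance",
    "reads",
]


def write_sites(sites, path, fmt: Literal["bed", "tsv"] = "tsv") -> None:
    """Write clustered integration sites as BED6 (1-bp junction features) or
    as a full TSV report."""
    if fmt == "bed":
        with open(path, "w") as fh:
            for s in sites:
                fh.write(
                    f"{s.chromosome}\t{s.position}\t{s.position + 1}\t"
                    f"{s.is_id}\t{s.support}\t{s.strand}\n"
                )
        return
    if fmt != "tsv":
        raise ValueError(f"unknown site format {fmt!r}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SITE_TSV_COLUMNS)
        for s in sites:
            writer.writerow(
                [
                    s.is_id,
                    s.chromosome,
                    s.position,
                    s.strand,
                    s.support,
                    int(s.bidirectional),
                    "" if s.tsd_estimate is None else s.tsd_estimate,
                    getattr(s, "category", "") or "",
                    getattr(s, "gene", "") or "",
                    getattr(s, "nearest_gene", "") or "",
                    "" if getattr(s, "nearest_distance", None) is None
                    else getattr(s, "nearest_distance"),
                    ",".join(s.reads),
                ]
            )


def read_sites(path) -> list:
    """Read back a site TSV written by :func:`write_sites` (fmt='tsv')."""
    from lvis.iscall import IntegrationSite

    sites = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            site = IntegrationSite(
                is_id=row["is_id"],
                chromosome=row["chromosome"],
                position=int(row["position"]),
                strand=row["strand"],
                support=int(row["support"]),
                bidirectional=bool(int(row["bidirectional"])),
                tsd_estimate=int(row["tsd"]) if row["tsd"] != "" else None,
                reads=row["reads"].split(",") if row["reads"] else [],
            )
            site.category = row["category"] or None
            site.gene = row["gene"] or None
            site.nearest_gene = row["nearest_gene"] or None
            site.nearest_distance = (
                int(row["nearest_distance"]) if row["nearest_distance"] != "" else None
            )
            sites.append(site)
    return sites


# ---------------------------------------------------------------------------
# Gene models (GFF3 + BED12)
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[Gene], chrom_lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\tlvis\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.name}\n"
            )
            for i, (es, ee) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chromosome}\tlvis\texon\t{es + 1}\t{ee}\t.\t"
                    f"{g.strand}\t.\tID={g.name}.exon{i};Parent={g.name}\n"
                )


def read_gff3(path) -> tuple[list[Gene], dict[str, int]]:
    """Parse gene/exon features and ##sequence-region lengths from GFF3."""
    import gffutils

    chrom_lengths: dict[str, int] = {}
    has_features = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, chrom, start, end = line.split()[:4]
                chrom_lengths[chrom] = int(end)
            elif line.strip() and not line.startswith("#"):
                has_features = True
    if not has_features:
        return [], chrom_lengths
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[Gene] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(feat, featuretype="exon", order_by="start")
        ]
        genes.append(
            Gene(
                name=feat.id,
                chromosome=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                exons=exons,
            )
        )
    return genes, chrom_lengths


def write_bed12(genes: Sequence[Gene], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons or [(g.start, g.end)]
            sizes = ",".join(str(ee - es) for es, ee in exons) + ","
            starts = ",".join(str(es - g.start) for es, ee in exons) + ","
            fh.write(
                f"{g.chromosome}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


def read_bed12(path) -> list[Gene]:
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns")
            start = int(cols[1])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(
                Gene(
                    name=cols[3],
                    chromosome=cols[0],
                    start=start,
                    end=int(cols[2]),
                    strand=cols[5] if cols[5] in "+-" else "+",
                    exons=exons,
                )
            )
    return genes
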