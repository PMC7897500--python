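"""Enrichment statistic and run summary."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional

from lvis.iscall import PipelineResult

BUCKETS = [
    "dropped_quality",
    "dropped_size",
    "episome",
    "no_structure",
    "ambiguous",
    "member",
]


@dataclass
class EnrichmentInputs:
    """Inputs to the fold-enrichment ratio.

    a: number of input genomes; b: vector copy number (copies/genome);
    c: total number of sequenced reads; d: average read size (bases);
    e: total input bases based on input genomes; observed: number of reads
    mapped onto the integrated LV genome.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    observed: int

    def __post_init__(self) -> None:
        for name in "abcde":
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"enrichment input {name!r} must be > 0, got {v}")
        if self.observed < 0:
            raise ValueError("observed read count must be >= 0")
        if self.e < self.a:
            raise ValueError("total input bases (e) must be at least one per genome (a)")

    @property
    def expected(self) -> float:
        """Expected LV-genome reads at this depth without enrichment."""
        return (self.a * self.b) * (self.c * self.d) / self.e


def total_input_bases(n_genomes: float, genome_size: float) -> float:
    """Convenience: e = a * G for a host of ``genome_size`` bases."""
    return n_genomes * genome_size


def fold_enrichment(inputs: EnrichmentInputs) -> float:
    """Observed over expected LV-genome reads; dimensionless ratio."""
    expected = inputs.expected
    if expected <= 0:
        raise ValueError("expected read count must be positive")
    return inputs.observed / expected


@dataclass
class RunSummary:
    sample: str
    input_reads: int
    bucket_counts: dict[str, int]
    lv_mapped_reads: int
    junction_calls: int
    unique_sites: int
    episome_reads: int
    vcn: Optional[float]
    fold_enrichment: Optional[float]

    def conserved(self) -> bool:
        return sum(self.bucket_counts.values()) == self.input_reads


def summarize_run(
    result: PipelineResult,
    enrichment: Optional[EnrichmentInputs] = None,
    vcn: Optional[float] = None,
    sample: str = "sample",
) -> RunSummary:
    """Table-1-style one-row summary of a pipeline run."""
    if result is None:
        raise ValueError("missing stage artifact: pipeline result")
    if result.sites is None or result.decisions is None:
        raise ValueError("missing stage artifact: clustering/decision log")
    fold: Optional[float] = None
    if enrichment is not None and result.n_input > 0:
        fold = fold_enrichment(enrichment)
    return RunSummary(
        sample=sample,
        input_reads=result.n_input,
        bucket_counts={b: result.counts.get(b, 0) for b in BUCKETS},
        lv_mapped_reads=result.n_lv_mapped,
        junction_calls=len(result.calls),
        unique_sites=len(result.sites),
        episome_reads=result.counts.get("episome", 0),
        vcn=vcn,
        fold_enrichment=fold,
    )


_SUMMARY_COLUMNS = (
    ["sample", "input_reads"]
    + BUCKETS
    + ["lv_mapped_reads", "junction_calls", "unique_sites", "vcn", "fold_enrichment"]
)


def write_summary(summaries, path) -> None:
    rows = summaries if isinstance(summaries, list) else [summaries]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_SUMMARY_COLUMNS)
        for s in rows:
            writer.writerow(
                [s.sample, s.input_reads]
                + [s.bucket_counts[b] for b in BUCKETS]
                + [
                    s.lv_mapped_reads,
                    s.junction_calls,
                    s.unique_sites,
                    "" if s.vcn is None else s.vcn,
                    "" if s.fold_enrichment is None else repr(s.fold_enrichment),
                ]
            )


def read_summary(path) -> list[RunSummary]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                RunSummary(
                    sample=row["sample"],
                    input_reads=int(row["input_reads"]),
                    bucket_counts={b: int(row[b]) for b in BUCKETS},
                    lv_mapped_reads=int(row["lv_mapped_reads"]),
                    junction_calls=int(row["junction_calls"]),
                    unique_sites=int(row["unique_sites"]),
                    episome_reads=int(row["episome"]),
                    vcn=float(row["vcn"]) if row["vcn"] != "" else None,
                    fold_enrichment=(
                        float(row["fold_enrichment"])
                        if row["fold_enrichment"] != ""
                        else None
                    ),
                )
            )
    return out
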