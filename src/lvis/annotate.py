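"""Positional annotation of integration sites against a gene model."""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from lvis.iscall import IntegrationSite
from lvis.seqio import Gene, read_bed12, read_gff3


@dataclass
class GeneModel:
    """Gene bodies + exons with fast point-containment lookup."""

    genes: list[Gene]
    chrom_lengths: dict[str, int]
    _by_chrom: dict[str, list[Gene]] = field(init=False, repr=False)
    _starts: dict[str, list[int]] = field(init=False, repr=False)
    _maxend: dict[str, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_chrom = {}
        for g in sorted(self.genes, key=lambda g: (g.chromosome, g.start, g.name)):
            self._by_chrom.setdefault(g.chromosome, []).append(g)
        self._starts = {c: [g.start for g in gs] for c, gs in self._by_chrom.items()}
        self._maxend = {}
        for c, gs in self._by_chrom.items():
            running = []
            m = 0
            for g in gs:
                m = max(m, g.end)
                running.append(m)
            self._maxend[c] = running

    @classmethod
    def from_gff3(cls, path, chrom_lengths: Optional[dict[str, int]] = None) -> "GeneModel":
        genes, lengths = read_gff3(path)
        return cls(genes=genes, chrom_lengths=chrom_lengths or lengths)

    @classmethod
    def from_bed12(cls, path, chrom_lengths: dict[str, int]) -> "GeneModel":
        return cls(genes=read_bed12(path), chrom_lengths=chrom_lengths)

    def genes_at(self, chromosome: str, position: int) -> list[Gene]:
        gs = self._by_chrom.get(chromosome, [])
        if not gs:
            return []
        starts = self._starts[chromosome]
        maxend = self._maxend[chromosome]
        idx = bisect_right(starts, position)
        hits = []
        i = idx - 1
        while i >= 0 and maxend[i] > position:
            g = gs[i]
            if g.start <= position < g.end:
                hits.append(g)
            i -= 1
        hits.reverse()
        return hits


def classify_site(site: IntegrationSite, model: GeneModel) -> IntegrationSite:
    """Assign exon / intron / intergenic (exon precedence) and gene membership.

    A site inside several overlapping gene bodies is classified once but
    attributed to all of them (``site.genes``) for gene-level analyses.
    """
    if site.chromosome not in model.chrom_lengths:
        raise ValueError(f"unknown chromosome {site.chromosome!r}")
    hits = model.genes_at(site.chromosome, site.position)
    in_exon = any(
        es <= site.position < ee for g in hits for (es, ee) in g.exons
    )
    if hits:
        site.category = "exon" if in_exon else "intron"
        site.genes = [g.name for g in hits]
        site.gene = site.genes[0]
    else:
        site.category = "intergenic"
        site.genes = []
        site.gene = None
    ng = nearest_gene(site, model)
    site.nearest_gene = ng[0].name if ng[0] is not None else None
    site.nearest_distance = ng[1]
    return site


def annotate_sites(sites: Iterable[IntegrationSite], model: GeneModel) -> list[IntegrationSite]:
    return [classify_site(s, model) for s in sites]


def nearest_gene(site: IntegrationSite, model: GeneModel) -> tuple[Optional[Gene], Optional[int]]:
    """Closest gene and signed distance: 0 inside the body, positive when the
    site lies rightward of the gene end, negative when leftward of the start.
    Ties break toward the smaller gene start, then name."""
    gs = model._by_chrom.get(site.chromosome, [])
    if not gs:
        return None, None
    best: Optional[Gene] = None
    best_dist: Optional[int] = None
    for g in gs:
        if g.start <= site.position < g.end:
            d = 0
        elif site.position < g.start:
            d = site.position - g.start  # negative
        else:
            d = site.position - g.end + 1  # positive, rightward of gene end
        if (
            best_dist is None
            or abs(d) < abs(best_dist)
            or (abs(d) == abs(best_dist) and (g.start, g.name) < (best.start, best.name))
        ):
            best, best_dist = g, d
    return best, best_dist


def classification_fractions(sites: Sequence[IntegrationSite]) -> dict[str, float]:
    """Fraction of sites per category; sums to 1 over any non-empty site set."""
    n = len(sites)
    if n == 0:
        return {"exon": 0.0, "intron": 0.0, "intergenic": 0.0}
    out = {}
    for cat in ("exon", "intron", "intergenic"):
        out[cat] = sum(1 for s in sites if s.category == cat) / n
    return out


def find_mis(sites: Sequence[IntegrationSite]) -> list[tuple[str, int, list[int]]]:
    """Genes hit by two or more distinct integration sites (any separation),
    sorted by count descending then name."""
    per_gene: dict[str, list[IntegrationSite]] = {}
    for s in sites:
        for gname in getattr(s, "genes", None) or ([s.gene] if s.gene else []):
            per_gene.setdefault(gname, []).append(s)
    out = []
    for gname, ss in per_gene.items():
        distinct = {s.is_id: s.position for s in ss}
        if len(distinct) >= 2:
            out.append((gname, len(distinct), sorted(distinct.values())))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


@dataclass
class OverlapResult:
    shared: set[str]
    fraction: float
    a_only: set[str]
    b_only: set[str]


def gene_overlap(
    sample_a_genes: Iterable[str],
    sample_b_genes: Iterable[str],
    convention: str = "jaccard",
) -> OverlapResult:
    """Shared gene-body hits between two samples.

    ``fraction`` is Jaccard (|A∩B| / |A∪B|) by default; pass
    ``convention="min"`` for |A∩B| / min(|A|, |B|).
    """
    a, b = set(sample_a_genes), set(sample_b_genes)
    shared = a & b
    union = a | b
    if not union:
        warnings.warn("both gene sets are empty; overlap fraction reported as 0")
        frac = 0.0
    elif convention == "jaccard":
        frac = len(shared) / len(union)
    elif convention == "min":
        denom = min(len(a), len(b))
        frac = len(shared) / denom if denom else 0.0
    else:
        raise ValueError(f"unknown overlap convention {convention!r}")
    return OverlapResult(shared=shared, fraction=frac, a_only=a - shared, b_only=b - shared)


@dataclass
class ChromDistribution:
    table: pd.DataFrame  # chromosome, n_sites, n_genes, site_density, gene_density
    slope: Optional[float]
    intercept: Optional[float]
    r_squared: Optional[float]


def chrom_distribution(
    sites: Sequence[IntegrationSite],
    model: GeneModel,
    exclude: Iterable[str] = (),
) -> ChromDistribution:
    """Per-chromosome site and gene densities plus an OLS fit of site density
    on gene density.  Degenerate inputs report R² as absent rather than NaN."""
    exclude = set(exclude)
    chroms = [c for c in model.chrom_lengths if c not in exclude]
    if len(chroms) < 2:
        raise ValueError("need at least 2 chromosomes for a density fit")
    site_counts = {c: 0 for c in chroms}
    for s in sites:
        if s.chromosome in site_counts:
            site_counts[s.chromosome] += 1
    gene_counts = {c: 0 for c in chroms}
    for g in model.genes:
        if g.chromosome in gene_counts:
            gene_counts[g.chromosome] += 1
    rows = []
    for c in chroms:
        L = model.chrom_lengths[c]
        rows.append(
            {
                "chromosome": c,
                "n_sites": site_counts[c],
                "n_genes": gene_counts[c],
                "site_density": site_counts[c] / L,
                "gene_density": gene_counts[c] / L,
            }
        )
    table = pd.DataFrame(rows)
    x = table["gene_density"].to_numpy()
    y = table["site_density"].to_numpy()
    if len(set(x)) < 2:
        return ChromDistribution(table, None, None, None)
    fit = stats.linregress(x, y)
    return ChromDistribution(table, fit.slope, fit.intercept, fit.rvalue**2)


def bin_windows(
    sites: Sequence[IntegrationSite],
    chrom_lengths: dict[str, int],
    window: int = 50_000,
) -> pd.DataFrame:
    """Count sites per half-open genomic window; ideogram-ready table with
    columns Chr, Start, End, Value covering every window of every chromosome."""
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    counts: dict[tuple[str, int], int] = {}
    for s in sites:
        counts[(s.chromosome, s.position // window)] = (
            counts.get((s.chromosome, s.position // window), 0) + 1
        )
    for chrom, length in chrom_lengths.items():
        n_windows = (length + window - 1) // window
        for i in range(n_windows):
            rows.append(
                {
                    "Chr": chrom,
                    "Start": i * window,
                    "End": min((i + 1) * window, length),
                    "Value": counts.get((chrom, i), 0),
                }
            )
    return pd.DataFrame(rows, columns=["Chr", "Start", "End", "Value"])
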