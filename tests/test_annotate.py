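"""Gene-model classification, MIS, overlap, density fit, window binning."""

import numpy as np
import pytest

from lvis.annotate import (
    GeneModel,
    bin_windows,
    chrom_distribution,
    classification_fractions,
    classify_site,
    find_mis,
    gene_overlap,
    nearest_gene,
)
from lvis.iscall import IntegrationSite
from lvis.seqio import Gene


def _site(pos, chrom="chr1", is_id="IS_1"):
    return IntegrationSite(
        is_id=is_id, chromosome=chrom, position=pos, strand="+",
        support=1, bidirectional=False, tsd_estimate=None, reads=["r"],
    )


THREE_GENES = GeneModel(
    genes=[
        Gene("gA", "chr1", 1000, 5000, "+", [(1000, 1500), (4000, 5000)]),
        Gene("gB", "chr1", 8000, 9000, "-", [(8100, 8300)]),
        Gene("gC", "chr2", 0, 2000, "+", [(0, 500)]),
    ],
    chrom_lengths={"chr1": 20_000, "chr2": 10_000},
)


class TestClassifySite:
    def test_exon_hit(self):
        s = classify_site(_site(1200), THREE_GENES)
        assert s.category == "exon" and s.gene == "gA"

    def test_intron_hit(self):
        s = classify_site(_site(2000), THREE_GENES)
        assert s.category == "intron" and s.gene == "gA"

    def test_intergenic(self):
        s = classify_site(_site(6000), THREE_GENES)
        assert s.category == "intergenic" and s.gene is None

    def test_zero_gene_model(self):
        model = GeneModel(genes=[], chrom_lengths={"chr1": 1000})
        s = classify_site(_site(10), model)
        assert s.category == "intergenic"
        assert s.nearest_gene is None and s.nearest_distance is None

    def test_unknown_chromosome_errors(self):
        with pytest.raises(ValueError, match="chrX"):
            classify_site(_site(5, chrom="chrX"), THREE_GENES)

    def test_twenty_sites_match_containment_oracle(self):
        rng = np.random.default_rng(3)
        positions = rng.integers(0, 20_000, 20)
        for i, pos in enumerate(positions):
            s = classify_site(_site(int(pos), is_id=f"IS_{i}"), THREE_GENES)
            # brute-force interval containment
            want = "intergenic"
            for g in THREE_GENES.genes:
                if g.chromosome != "chr1":
                    continue
                if any(es <= pos < ee for es, ee in g.exons):
                    want = "exon"
                    break
                if g.start <= pos < g.end:
                    want = "intron"
            assert s.category == want, pos

    def test_overlapping_genes_attributed_to_both(self):
        model = GeneModel(
            genes=[
                Gene("outer", "chr1", 0, 10_000, "+", [(0, 100)]),
                Gene("inner", "chr1", 4000, 6000, "+", [(4000, 4100)]),
            ],
            chrom_lengths={"chr1": 20_000},
        )
        s = classify_site(_site(5000), model)
        assert s.category == "intron"
        assert set(s.genes) == {"outer", "inner"}

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        sites = [
            classify_site(_site(int(p), is_id=f"IS_{i}"), THREE_GENES)
            for i, p in enumerate(rng.integers(0, 20_000, 50))
        ]
        fracs = classification_fractions(sites)
        assert abs(sum(fracs.values()) - 1.0) < 1e-12


class TestNearestGene:
    def test_inside_gene_distance_zero(self):
        g, d = nearest_gene(_site(2000), THREE_GENES)
        assert g.name == "gA" and d == 0

    def test_tie_broken_by_smaller_start(self):
        model = GeneModel(
            genes=[
                Gene("left", "chr1", 0, 1000, "+", []),
                Gene("right", "chr1", 1201, 2000, "+", []),
            ],
            chrom_lengths={"chr1": 5000},
        )
        # position 1100 is 101 from the last base of 'left' and 101 before
        # the start of 'right': a true tie, resolved toward the smaller start
        g, d = nearest_gene(_site(1100), model)
        assert abs(d) == 101 and g.name == "left"

    def test_signed_distance_rightward(self):
        model = GeneModel(
            genes=[Gene("only", "chr1", 0, 1000, "+", [])],
            chrom_lengths={"chr1": 5000},
        )
        g, d = nearest_gene(_site(1499), model)
        assert g.name == "only" and d == 500

    def test_empty_chromosome_absent(self):
        model = GeneModel(genes=[], chrom_lengths={"chr1": 100})
        assert nearest_gene(_site(5), model) == (None, None)


class TestFindMis:
    def _annotated(self, assignments):
        sites = []
        for i, (gene, pos) in enumerate(assignments):
            s = _site(pos, is_id=f"IS_{i + 1}")
            s.gene = gene
            s.genes = [gene] if gene else []
            sites.append(s)
        return sites

    def test_all_genes_hit_once(self):
        sites = self._annotated([("g1", 10), ("g2", 20), ("g3", 30)])
        assert find_mis(sites) == []

    def test_two_hits_sixty_kb_apart_reported(self):
        sites = self._annotated([("g1", 10_000), ("g1", 72_000)])
        (hit,) = find_mis(sites)
        assert hit[0] == "g1" and hit[1] == 2
        assert hit[2] == [10_000, 72_000]

    def test_counts_match_brute_force_group_by(self):
        assignments = [("g1", 1), ("g2", 2), ("g1", 3), ("g3", 4), ("g1", 5),
                       ("g2", 6), (None, 7)]
        sites = self._annotated(assignments)
        got = {(g, n) for g, n, _ in find_mis(sites)}
        counts = {}
        for g, _ in assignments:
            if g:
                counts[g] = counts.get(g, 0) + 1
        want = {(g, n) for g, n in counts.items() if n >= 2}
        assert got == want

    def test_sorted_by_count_desc(self):
        sites = self._annotated([("a", 1), ("b", 2), ("b", 3), ("b", 4),
                                 ("a", 5)])
        assert [g for g, _, _ in find_mis(sites)] == ["b", "a"]


class TestGeneOverlap:
    def test_identical_sets(self):
        r = gene_overlap({"a", "b"}, {"a", "b"})
        assert r.fraction == 1.0 and r.shared == {"a", "b"}

    def test_spec_example_jaccard(self):
        r = gene_overlap({"A", "B", "C"}, {"C", "D"})
        assert r.shared == {"C"}
        assert r.fraction == 0.25
        assert r.a_only == {"A", "B"} and r.b_only == {"D"}

    def test_disjoint_sets(self):
        assert gene_overlap({"a"}, {"b"}).fraction == 0.0

    def test_both_empty_warns_zero(self):
        with pytest.warns(UserWarning):
            assert gene_overlap(set(), set()).fraction == 0.0

    def test_min_convention(self):
        r = gene_overlap({"A", "B", "C"}, {"C", "D"}, convention="min")
        assert r.fraction == 0.5


class TestChromDistribution:
    def _model(self, gene_counts, lengths):
        genes = []
        for i, (c, n) in enumerate(zip(lengths, gene_counts)):
            for j in range(n):
                genes.append(Gene(f"g{i}_{j}", c, j * 100, j * 100 + 50, "+", []))
        return GeneModel(genes=genes, chrom_lengths=lengths)

    def test_proportional_counts_r2_one(self):
        lengths = {"chr1": 100_000, "chr2": 100_000, "chr3": 100_000}
        model = self._model([2, 4, 8], lengths)
        sites = []
        for c, n in zip(lengths, [4, 8, 16]):  # sites = 2 x genes
            sites.extend(_site(50_000, chrom=c, is_id=f"{c}_{i}") for i in range(n))
        dist = chrom_distribution(sites, model)
        assert dist.r_squared == pytest.approx(1.0)

    def test_hand_built_table_matches_pearson(self):
        lengths = {"c1": 1000, "c2": 1000, "c3": 1000, "c4": 1000}
        gene_counts = [1, 2, 3, 4]
        site_counts = [2, 3, 7, 8]
        model = self._model(gene_counts, lengths)
        sites = []
        for c, n in zip(lengths, site_counts):
            sites.extend(_site(10, chrom=c, is_id=f"{c}_{i}") for i in range(n))
        dist = chrom_distribution(sites, model)
        x = np.array(gene_counts) / 1000
        y = np.array(site_counts) / 1000
        r = np.corrcoef(x, y)[0, 1]
        assert dist.r_squared == pytest.approx(r**2)
        assert 0.0 <= dist.r_squared <= 1.0

    def test_degenerate_gene_density_reports_absent(self):
        lengths = {"c1": 1000, "c2": 1000, "c3": 1000}
        model = GeneModel(genes=[], chrom_lengths=lengths)
        sites = [_site(10, chrom=c, is_id=c) for c in lengths]
        dist = chrom_distribution(sites, model)
        assert dist.r_squared is None

    def test_single_chromosome_errors(self):
        model = GeneModel(genes=[], chrom_lengths={"c1": 1000})
        with pytest.raises(ValueError, match="chromosome"):
            chrom_distribution([], model)

    def test_exclusion_list_respected(self):
        lengths = {"c1": 1000, "c2": 1000, "chrY": 1000}
        model = GeneModel(genes=[], chrom_lengths=lengths)
        dist = chrom_distribution([], model, exclude={"chrY"})
        assert list(dist.table["chromosome"]) == ["c1", "c2"]


class TestBinWindows:
    LENGTHS = {"chr1": 150_000}

    def test_half_open_boundary(self):
        sites = [_site(49_999, is_id="a"), _site(50_000, is_id="b")]
        table = bin_windows(sites, self.LENGTHS, window=50_000)
        assert list(table["Value"]) == [1, 1, 0]

    def test_single_site_one_nonzero_window(self):
        table = bin_windows([_site(120_000)], self.LENGTHS, window=50_000)
        assert (table["Value"] > 0).sum() == 1
        assert table.loc[table["Value"] > 0, "Start"].item() == 100_000

    def test_conservation_of_counts(self):
        rng = np.random.default_rng(11)
        sites = [_site(int(p), is_id=f"IS_{i}")
                 for i, p in enumerate(rng.integers(0, 150_000, 1000))]
        for w in (7, 1000, 50_000, 10**6):
            table = bin_windows(sites, self.LENGTHS, window=w)
            assert table["Value"].sum() == 1000

    def test_window_bounds_clip_to_chromosome(self):
        table = bin_windows([], self.LENGTHS, window=50_000)
        assert table["End"].iloc[-1] == 150_000

    def test_nonpositive_window_errors(self):
        with pytest.raises(ValueError):
            bin_windows([], self.LENGTHS, window=0)
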