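# lvis

Detection, clustering and annotation of lentiviral vector integration sites
(IS) from Cas9-enriched, amplification-free long reads.

The protocol this tool analyzes cuts the integrated provirus at guide sites
placed near both vector ends, ligates sequencing adapters at the cuts, and
sequences outward through the vector terminus into the host genome. The
pipeline:

1. **filters** basecalled reads (mean Phred > 9; length ≥ shortest
   cut-to-terminus arm + a mappable host anchor),
2. **triages** reads vector-first: only reads with an alignment to the
   provirus have their non-vector portion mapped to the host genome, with a
   best/second-best score ratio guarding against repeat multi-mapping,
3. **calls junctions** requiring the cut-site → terminus → host read
   structure, eliminating episomal (LTR-circle) reads by their lack of a
   host anchor beyond the terminus,
4. **clusters** calls into unique IS; bidirectional sites (evidence from both
   vector ends) yield a target-site duplication (TSD) estimate from the
   junction overlap,
5. **annotates** sites against a gene model (exon/intron/intergenic, nearest
   gene, multiple-integration genes, cross-sample gene overlap,
   chromosome-density correlation, 50 kb window binning), and
6. **reports** a run summary including the fold-enrichment statistic
   `observed / ((a·b)·(c·d)/e)` (a: input genomes, b: vector copy number,
   c: total reads, d: average read size, e: total input bases).

A self-contained simulator (host genome + gene model, planted integrations
with TSDs, directional Cas9-cut reads, background and LTR-circle reads)
makes every stage testable without external data.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(error-free and noisy round trips, aligner-vs-substring-search oracle,
formula checks, filter boundaries).

## CLI

```sh
# synthetic dataset with ground truth
lvis simulate --seed 1 --out-dir sim --n-integrations 20 --reads-per-end 3

# check an enrichment panel against the design rules
lvis validate-guides --construct sim/construct.fasta --guides sim/guides.tsv

# filter -> triage -> junction-call -> cluster
lvis call --reads sim/reads.fastq --construct sim/construct.fasta \
    --guides sim/guides.tsv --host sim/host.fasta --out-dir out

# externally produced alignments (PAF) can replace the internal aligner
lvis call ... --alignments external.paf

# classify sites against the gene model
lvis annotate --sites out/sites.tsv --genes sim/genes.gff3 --out-dir ann

# Table-style run summary + fold enrichment
lvis report --decisions out/decisions.tsv --sites out/sites.tsv \
    --vcn 20.55 --input-genomes 3030303 --total-reads 199032 \
    --avg-read-size 12000 --total-input-bases 2e16 --out summary.tsv
```

File formats: FASTQ/FASTA in and out, GFF3 or BED12 gene models, PAF or a
SAM subset for imported alignments, BED6/TSV site tables.

## Conventions

- Coordinates are 0-based, half-open throughout; a site's position is the
  first base of the duplicated host motif (the 5′-most copy).
- A guide's cut position is the first base of the right-hand fragment; the
  blunt SpCas9 cut is modelled 3 bp on the protospacer side of the PAM.
- The sequenced (A-tailable) fragment of a cut is the PAM-side fragment;
  panel validation enforces that it contains the served vector terminus.
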