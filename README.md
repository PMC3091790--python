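# usskit

Genome-screening toolkit for Pasteurellaceae comparative genomics: uptake
signal sequence (USS) scanning and flanking-composition profiling, tiered
homology-based product naming, ribosome-binding-site detection,
virulence-factor panel screening, and two-genome ortholog pairing — with a
synthetic-data generator so every step is testable without downloading a
genome.

## The science

Pasteurellaceae (the family containing *Haemophilus influenzae*,
*Actinobacillus succinogenes* and relatives) accumulate hundreds to
thousands of copies of a 9-bp **uptake signal sequence core** — `AAGTGCGGT`
(USS1) in most species, `ACAAGCGGT` (USS2) in a minority — that marks DNA
for preferential uptake during natural transformation. Each genome strongly
favors one core. Comparative USS tables report, per genome: counts of both
cores on both strands, the dominant core, the **USS density**
(dominant-core count per kb), and the percentage of sites whose core is
immediately followed by a C ("C at nt 12" under the extended-USS numbering,
where the core occupies nt 3–11). The core is typically preceded by an A
and followed by an AT-rich tail; `usskit` computes the full per-position
nucleotide-frequency profile of these flanks.

Around the scanner sit the screening procedures used in manual genome
annotation:

- **Tiered product naming** from homology evidence: ≥75% identity over
  ≥75% of the product length (or equivalog-family membership) inherits the
  product name; 60–75%/65% gives "putative", 40–64%/40% "probable",
  25–39%/25% "possible"; ≥60% identity to a protein of unknown function
  gives "conserved hypothetical protein"; anything weaker is
  "hypothetical protein". Implemented as a lower-bound cascade so the rule
  is total and monotone.
- **RBS detection**: at least 3 consecutive bases of the Shine–Dalgarno
  consensus `AAGGAGG`, 5–10 nt upstream of the start codon.
- **Panel screening**: each query protein's top Smith–Waterman hit in a
  target proteome, validity banded by identity (60–75 putative, 40–59
  probable, 25–39 possible; NA when the alignment covers <25% of the query).
- **Ortholog pairing** between two genomes: reciprocal best hits at ≥25%
  protein identity, with gene-order (synteny) rescue of one-directional
  candidates, plus shared-ORF percentage accounting.

The local aligner is a BLOSUM62 / affine-gap (open 11, extend 1)
Smith–Waterman (via Biopython's `PairwiseAligner`), reporting percent
identity and similarity over alignment columns including gaps.

## Worked example

```python
>>> import usskit
>>> genome = usskit.GenomeSequence("toy", "TTAAGTGCGGTC" + "AT" * 10)
>>> s = usskit.summarize_uss(genome)
>>> (s.uss1_count, s.uss2_count, s.dominant, s.c_at_12_pct, s.density_uss_per_kb)
(1, 0, 'USS1', 100, 31.25)
```

The toy genome carries one USS1 core followed by a C, so the dominant core
is USS1, 100% of sites have C at nt 12, and the density is 1 site over
0.032 kb = 31.25 USS/kb. The same arithmetic applied to the published
comparative table reproduces its printed densities — for example 1,690
USS1 sites in a 2,319,663-bp genome:

```python
>>> usskit.uss_density(1690, 2319663)
0.73
```

From the shell, simulate a genome with planted cores and summarize it:

```bash
usskit simulate --length 100000 --n-forward 50 --n-reverse 50 --seed 1 \
    --out-prefix sim
usskit uss-summary sim.fasta --out summary.tsv
```

Other subcommands: `uss-scan`, `uss-profile`, `annotate-tiers`,
`annotate-rbs`, `screen`, `orthologs` (see `usskit --help`).

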