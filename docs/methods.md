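# Methods

This note records the models, conventions and design choices behind
`usskit`, including the points where the published procedures left the
design genuinely open.

## USS scanning and summaries

The scanner reports every exact match of a 9-mer core (`AAGTGCGGT` for
USS1, `ACAAGCGGT` for USS2) on both strands of a linear genome. Matches may
overlap and each is counted; the two canonical cores have no nontrivial
self-overlap, so overlap handling is moot for them but kept correct for
arbitrary 9-mers. `N` never matches any core position. Genomes are treated
as linear: no origin-spanning matches on circular chromosomes (a
2.3-Mb genome could lose at most one site to this, well below reporting
precision).

Coordinates are 1-based and inclusive. A minus-strand occurrence's `start`
is the forward-strand position of the core's 5'-most base *as read on the
minus strand* — i.e. the rightmost base of the reverse-complement match —
so that windows and flank positions are always expressed in the core's own
orientation.

Summary-row arithmetic mirrors how comparative USS tables are printed:

- **Dominant core** = argmax of the two counts (USS1 on the tie, which does
  not occur in practice: genomes favor one core by an order of magnitude).
- **Density** = dominant-core count / (genome size in kb), rounded half-up
  to 2 decimals.
- **C at nt 12** = percent of dominant-core occurrences whose first base 3'
  of the core (position +1 in our numbering; nt 12 of the extended USS,
  whose core spans nt 3–11) is C, rounded half-up to an integer.
  Occurrences whose +1 base falls off the sequence end are excluded from
  the denominator. Restricting to dominant-core occurrences is an
  interpretation — the published table does not state whether minor-core
  sites contribute — chosen because the table reports a single value per
  genome; `c_at_12_percent` accepts any occurrence list, so the all-cores
  reading is one call away.

Rounding is decimal half-up (not banker's), matching printed-table values
such as 1690/2319.663 kb → 0.73.

## Flanking profiles

`flanking_profile` computes per-position nucleotide frequencies at
positions −U…−1 (upstream), 1…9 (core) and +1…+D (downstream), oriented
5'→3' along the core's strand. Defaults U=10, D=30: downstream must reach
at least ~26 to cover the motif structure reported around USS2 (a
`GCAAA(A/T)` element ~20 nt downstream of the core). Edge-truncated windows
are excluded *position-wise*: each position's denominator counts only
occurrences whose window covers it, and the denominator is reported
(`n_obs`). Positions with zero observations carry NaN frequencies rather
than fabricated zeros. Bases that are `N` are omitted from that position's
denominator.

## Local alignment

`local_align` is Smith–Waterman with BLOSUM62 and affine gaps, open 11 /
extend 1 (a gap of length k costs 11 + k) — the conventional protein-search
defaults; matrix and gap costs are configurable arguments. The engine is
Biopython's `PairwiseAligner`; the test suite checks its scores against an
independently written Gotoh three-matrix DP, exhaustively over all sequence
pairs of lengths 1–3 on a 4-letter alphabet and on seeded random pairs up
to length 12 (exhaustive enumeration at length 12 is combinatorially
impossible, ~10^14 pairs).

Percent identity and percent similarity (columns with a positive
substitution score) both use the full alignment length *including gap
columns* as denominator, matching how alignment length is reported
alongside identity in homology screen tables. A query–subject pair with no
positive-scoring local alignment is reported as "no hit" (None), not as a
zero-length alignment. Ranking in `best_hits` is by raw score, ties broken
by identity then lexicographic subject id for determinism. No E-value model
is attached: score calibration is out of scope, and E-values from external
hit tables are carried through for reporting only.

## Annotation tiers

The published tier bands overlap at 60–64% identity and leave combinations
such as 70% identity / 50% coverage between bands. The classifier resolves
this as a lower-bound cascade: try the best tier first (equivalog
membership or ≥75/≥75), fall through to putative (≥60/≥65), probable
(≥40/≥40), possible (≥25/≥25), with unknown-function subjects short-cut to
"conserved hypothetical" at ≥60% identity. All thresholds are inclusive
lower bounds ("at least 75%"). This preserves every printed band's members
and makes the rule total and monotone in both identity and coverage, which
the test suite verifies over the full 0–100 × 0–100 grid.

Coverage for annotation uses the **subject** (product) length as
denominator, from the "aligned region is less than 25% of the product
length" convention; the panel screen deliberately uses the **query** length
instead (its NA rule is stated against the query). Both denominators are
exposed via configuration.

## RBS rule

At least 3 consecutive bases of `AAGGAGG`, located 5–10 nt upstream of the
start codon. "5–10 nt upstream" is read as constraining the whole match to
lie within the 6-base window (bases 10 through 5 upstream); an alternative
reading constraining only the match's 3' end is available as
`mode="three-prime-end"`. The longest in-window substring wins; ties go to
the match nearer the start codon. Upstream sequences shorter than 10 nt are
evaluated on the available window and flagged truncated.

## Panel screen

One row per panel query, carrying its top hit's statistics. Validity is
banded purely by identity — 60–75 putative, 40–59 probable, 25–39
possible — with NA when there is no hit, identity < 25%, or the alignment
covers < 25% of the query length. Identity above 75% is reported as
"strong" rather than being silently folded into "putative", so the bands
partition [25, 75] exactly as published while never capping a better hit.

## Ortholog pairing

Reciprocal best hits (RBH) between the two proteomes are accepted when the
alignment shows ≥ 25% identity **and** spans ≥ 25% of the shorter protein.
The span requirement operationalizes "identity at the protein level":
unrelated proteins routinely exceed 25% identity over a few dozen local
alignment columns, so a bare identity floor on local alignments would admit
chance pairs; true orthologs in the 40–90% identity range align essentially
full-length. A candidate that is a best hit in only one direction is
rescued when an adjacent gene pair with the same relative orientation is
already accepted — adjacency-based synteny support standing in for the
manual inspection of gene order, orientation and intergenic features that
the original compilation used and did not operationalize. Output is
one-to-one, and each pair reports its synteny support (0–2 paired
neighbors).

Shared-ORF percentages take the union denominator as an explicit input,
because how a published total (e.g. 2,223 for two re-annotated proteomes
with 1,735 shared ORFs → 78%) was derived from the two proteomes is a
reporting convention, not a computable quantity.

## Synthetic data

The genome simulator plants n exact cores per strand at uniform
non-overlapping positions (via the spare-length gap construction) on an
i.i.d. background of chosen GC content, dressing each core with flanks from
a parameterized model: A at −1 with probability 0.65 ("usually preceded by
an A"; the exact fraction is not printed, 0.65 is a realistic reading of
the published frequency profile), C at +1 with probability 0.71 (the
printed fraction), and an A/T base (equal split) at +2…+20 with probability
0.70 (an AT-rich tail). Non-planted positions keep the background
distribution, so background core hits arise by chance at their closed-form
rate 2·(L−8)·p(core), and truth tables list planted sites only; tests
account for background hits with a brute-force scan.

The proteome-pair simulator draws ortholog identities uniformly from a
range (default 40–90%), realizes them by point substitutions at uniformly
chosen positions (within 1 percentage point of target; no indels — the
pairing criteria are identity- and order-based, so indel realism buys
nothing for these tests), permutes genome B's gene order in contiguous
blocks (some inverted, flipping strand), and adds unrelated random proteins
on each side. Default scenario: 100 orthologs, 20 unique genes per side, 3
rearrangement blocks, protein lengths 120–260 aa. Random proteins use
uniform residue frequencies; amino-acid composition realism is not needed
for rule tests.

What the simulations do **not** emulate: codon structure, repeat families,
local GC heterogeneity, indel evolution, gene gain/loss, and paralogous
families. Passing tests therefore demonstrate correctness of the scanning,
classification and pairing *rules* under controlled truth, not performance
on the full complexity of real genomes; the full-genome reproduction of the
published USS table row requires the user-supplied chromosome FASTA
(GenBank CP000746) and is exercised automatically when it is present.

## Problem sizes and determinism

All generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`. Default test problem sizes — 100-kb genomes
with 100 planted sites for scanner oracles, 120-kb genomes with 2,000
sites for flank-frequency recovery (3-binomial-SE band), 120-protein
proteomes for pairing — are chosen so the statistical checks have power
while the full suite stays fast enough to run habitually. Stochastic
assertions use fixed seeds or derandomized property testing throughout.
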