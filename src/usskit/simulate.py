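"""Synthetic genomes and proteome pairs with machine-readable ground truth.

Every generator is a pure function of its parameters and an integer seed, and
emits a truth table alongside the data, so the scanner, annotation rules and
ortholog pairing are testable without downloading any real genome.

The genome generator plants exact 9-mer cores on both strands of an i.i.d.
background of chosen GC content, dressing each core with flanks drawn from a
parameterized model of the composition seen around real uptake-signal cores:
a preceding A with probability ``p_a_minus1``, a C immediately following the
core with probability ``p_c_plus1`` (0.71 by default, the fraction observed
in *A. succinogenes*), and an AT-rich tail further downstream. Background
matches of the core can and do arise by chance; truth tables list only the
planted sites, and oracle-based tests account for background hits
separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import GeneRecord, GenomeSequence, ProteinRecord, reverse_complement
from .uss import CORE_LEN, USS_CORES

PROTEIN_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

#: Planted flank block: 1 base upstream (-1), the 9-base core, and a
#: downstream stretch +1..+FLANK_TAIL_SPAN covered by the flank model.
FLANK_UP_SPAN = 1
FLANK_TAIL_SPAN = 20


@dataclass(frozen=True)
class FlankModel:
    """Composition model for the bases planted around a core.

    Defaults emulate the flanking structure of real uptake-signal repeats:
    a usually-preceding A, a C at +1 in 71% of sites, and an AT-rich tail
    out to +20.
    """

    p_a_minus1: float = 0.65
    p_c_plus1: float = 0.71
    p_at_tail: float = 0.70

    def __post_init__(self) -> None:
        for name in ("p_a_minus1", "p_c_plus1", "p_at_tail"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth emitted beside a simulated dataset."""

    seed: int
    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.table.to_csv(f"{prefix}.truth.tsv", sep="\t", index=False)
        with open(f"{prefix}.manifest.json", "w") as fh:
            json.dump(
                {"seed": self.seed, "params": self.params}, fh, indent=2,
                default=str,
            )
            fh.write("\n")


def background_probs(gc: float) -> np.ndarray:
    """Per-base probabilities (A, C, G, T) for i.i.d. background at a GC
    fraction."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


def expected_background_core_hits(length_bp: int, gc: float) -> float:
    """Closed-form expected chance hits of a 9-mer core on both strands of
    an i.i.d. background (the two canonical cores have identical
    composition: 3 A/T and 6 G/C bases)."""
    at = (1.0 - gc) / 2.0
    p = at**3 * (gc / 2.0) ** 6
    return 2.0 * max(0, length_bp - CORE_LEN + 1) * p


def _draw_flanked_block(
    core9: str, flanks: FlankModel, rng: np.random.Generator, probs: np.ndarray
) -> str:
    bases = np.array(list("ACGT"))
    out = []
    # -1: A with p_a_minus1, else background renormalized over C/G/T.
    if rng.random() < flanks.p_a_minus1:
        out.append("A")
    else:
        rest = probs[1:] / probs[1:].sum()
        out.append(str(rng.choice(bases[1:], p=rest)))
    out.append(core9)
    # +1: C with p_c_plus1, else background renormalized over A/G/T.
    if rng.random() < flanks.p_c_plus1:
        out.append("C")
    else:
        idx = [0, 2, 3]
        rest = probs[idx] / probs[idx].sum()
        out.append(str(rng.choice(bases[idx], p=rest)))
    # +2..+tail: A/T (equal split) with p_at_tail, else G/C (equal split).
    for _ in range(FLANK_TAIL_SPAN - 1):
        if rng.random() < flanks.p_at_tail:
            out.append("A" if rng.random() < 0.5 else "T")
        else:
            out.append("G" if rng.random() < 0.5 else "C")
    return "".join(out)


def simulate_genome(
    length_bp: int,
    gc: float,
    n_forward: int,
    n_reverse: int,
    core: str = "USS1",
    flanks: FlankModel | None = None,
    seed: int = 0,
    genome_id: str = "sim",
) -> tuple[GenomeSequence, SimTruth]:
    """Background genome with planted, flank-dressed cores on both strands.

    Planted blocks (1 upstream base + core + 20 downstream bases) are placed
    at uniform non-overlapping positions. The truth table reports each
    planted core's scanner-convention coordinates: ``start`` is the 1-based
    forward position of the core's 5'-most base in core orientation, and
    ``left`` the leftmost forward position of the core.
    """
    flanks = flanks or FlankModel()
    core9 = USS_CORES[core] if core in USS_CORES else core
    n_sites = n_forward + n_reverse
    block = FLANK_UP_SPAN + CORE_LEN + FLANK_TAIL_SPAN
    if n_sites * block > length_bp:
        raise ValueError(
            f"cannot pack {n_sites} sites of {block} bp into {length_bp} bp"
        )

    rng = np.random.default_rng(seed)
    probs = background_probs(gc)
    seq = rng.choice(np.array(list("ACGT")), size=length_bp, p=probs)

    # Non-overlapping uniform placement via the gap construction: distribute
    # the spare length as random gaps between ordered blocks.
    spare = length_bp - n_sites * block
    cuts = np.sort(rng.integers(0, spare + 1, size=n_sites))
    starts = cuts + block * np.arange(n_sites)  # 0-based block starts

    strands = np.array(["+"] * n_forward + ["-"] * n_reverse)
    rng.shuffle(strands)

    rows = []
    for b0, strand in zip(starts, strands):
        block_seq = _draw_flanked_block(core9, flanks, rng, probs)
        if strand == "-":
            block_seq = reverse_complement(block_seq)
            core_left = b0 + FLANK_TAIL_SPAN  # tail lies left of the core
            start = core_left + CORE_LEN  # 5'-most core base, minus strand
        else:
            core_left = b0 + FLANK_UP_SPAN
            start = core_left + 1
        seq[b0 : b0 + block] = list(block_seq)
        rows.append(
            {
                "start": int(start),
                "left": int(core_left + 1),
                "strand": str(strand),
                "core": core,
            }
        )

    truth = pd.DataFrame(
        rows, columns=["start", "left", "strand", "core"]
    ).sort_values("left", ignore_index=True)
    genome = GenomeSequence(id=genome_id, residues="".join(seq))
    params = {
        "length_bp": length_bp, "gc": gc, "n_forward": n_forward,
        "n_reverse": n_reverse, "core": core,
        "flanks": vars(flanks) if hasattr(flanks, "__dict__") else {
            "p_a_minus1": flanks.p_a_minus1,
            "p_c_plus1": flanks.p_c_plus1,
            "p_at_tail": flanks.p_at_tail,
        },
    }
    return genome, SimTruth(seed=seed, table=truth, params=params)


def random_protein(
    length_aa: int, rng: np.random.Generator, pid: str = "prot",
    function_known: bool = False, product: str = "",
) -> ProteinRecord:
    """Random protein with uniform residue frequencies."""
    letters = rng.choice(np.array(list(PROTEIN_LETTERS)), size=length_aa)
    return ProteinRecord(
        id=pid, residues="".join(letters),
        function_known=function_known, product=product,
    )


def mutate_protein(
    parent: ProteinRecord, target_identity: float, seed: int = 0,
    child_id: str | None = None,
) -> ProteinRecord:
    """Point-substituted copy at a controlled ungapped percent identity.

    Substitutions hit uniformly chosen distinct positions, each replaced by
    a uniformly chosen non-identical residue, until the realized identity is
    within 1 percentage point of the target.
    """
    if not 0.0 < target_identity <= 100.0:
        raise ValueError("target_identity must be in (0, 100]")
    L = parent.length_aa
    n_sub = int(round(L * (1.0 - target_identity / 100.0)))
    realized = 100.0 * (L - n_sub) / L
    if abs(realized - target_identity) > 1.0:
        raise ValueError(
            f"length {L} cannot realize identity within 1 point of "
            f"{target_identity}"
        )
    rng = np.random.default_rng(seed)
    residues = list(parent.residues)
    for pos in rng.choice(L, size=n_sub, replace=False):
        alternatives = [c for c in PROTEIN_LETTERS if c != residues[pos]]
        residues[pos] = alternatives[rng.integers(len(alternatives))]
    return ProteinRecord(
        id=child_id or f"{parent.id}_mut",
        residues="".join(residues),
        function_known=parent.function_known,
        product=parent.product,
    )


def simulate_genome_pair(
    n_orthologs: int = 100,
    identity_range: tuple[float, float] = (40.0, 90.0),
    n_unique_each: int = 20,
    n_blocks: int = 3,
    seed: int = 0,
    protein_len_range: tuple[int, int] = (120, 260),
) -> tuple[
    tuple[list[GeneRecord], list[ProteinRecord]],
    tuple[list[GeneRecord], list[ProteinRecord]],
    SimTruth,
]:
    """Two annotated genomes with known orthology, rearrangement and uniques.

    Genome A carries ``n_orthologs`` ortholog genes in order plus
    ``n_unique_each`` unrelated genes at random positions; genome B carries
    mutated copies of the orthologs (identities drawn uniformly from
    ``identity_range``) with the ortholog order permuted in ``n_blocks``
    contiguous blocks, some inverted (flipping strand), plus its own unique
    genes. The truth table lists the true ortholog pairs with their target
    identities and block assignment.
    """
    if n_blocks > max(1, n_orthologs):
        raise ValueError("n_blocks must be <= n_orthologs")
    lo, hi = identity_range
    if not 0 < lo <= hi <= 100:
        raise ValueError("identity_range must satisfy 0 < lo <= hi <= 100")
    rng = np.random.default_rng(seed)

    lengths = rng.integers(
        protein_len_range[0], protein_len_range[1] + 1, size=n_orthologs
    )
    prots_a_orth = [
        random_protein(int(L), rng, pid=f"A_{i:04d}")
        for i, L in enumerate(lengths)
    ]
    identities = rng.uniform(lo, hi, size=n_orthologs)
    prots_b_orth = [
        mutate_protein(
            p, float(t), seed=int(rng.integers(2**31)), child_id=f"B_{i:04d}"
        )
        for i, (p, t) in enumerate(zip(prots_a_orth, identities))
    ]

    # Block permutation of B's ortholog order, some blocks inverted.
    if n_orthologs:
        bounds = np.sort(
            rng.choice(np.arange(1, n_orthologs), size=n_blocks - 1,
                       replace=False)
        ) if n_blocks > 1 else np.array([], dtype=int)
        blocks = np.split(np.arange(n_orthologs), bounds)
        order = rng.permutation(len(blocks))
        inverted = rng.random(len(blocks)) < 0.5
    else:
        blocks, order, inverted = [], np.array([], dtype=int), np.array([])

    block_of = np.zeros(n_orthologs, dtype=int)
    for bi, idxs in enumerate(blocks):
        block_of[idxs] = bi
    b_order: list[tuple[int, bool]] = []  # (ortholog index, inverted?)
    for bi in order:
        idxs = blocks[bi]
        if inverted[bi]:
            b_order.extend((int(i), True) for i in idxs[::-1])
        else:
            b_order.extend((int(i), False) for i in idxs)

    def _unique_prots(side: str) -> list[ProteinRecord]:
        ls = rng.integers(
            protein_len_range[0], protein_len_range[1] + 1, size=n_unique_each
        )
        return [
            random_protein(int(L), rng, pid=f"{side}_uniq_{i:03d}")
            for i, L in enumerate(ls)
        ]

    uniq_a = _unique_prots("A")
    uniq_b = _unique_prots("B")

    def _assemble(
        ordered: list[tuple[ProteinRecord, str]], prefix: str
    ) -> tuple[list[GeneRecord], list[ProteinRecord]]:
        genes, prots, cursor = [], [], 1
        for k, (prot, strand) in enumerate(ordered):
            span = 3 * prot.length_aa + 3
            genes.append(
                GeneRecord(
                    locus=f"{prefix}_{k:04d}",
                    start=cursor,
                    end=cursor + span - 1,
                    strand=strand,
                    protein_id=prot.id,
                )
            )
            prots.append(prot)
            cursor += span + 50  # fixed intergenic spacer
        return genes, prots

    strands_a = ["+" if rng.random() < 0.5 else "-" for _ in range(n_orthologs)]

    ordered_a: list[tuple[ProteinRecord, str]] = [
        (p, s) for p, s in zip(prots_a_orth, strands_a)
    ]
    for p in uniq_a:
        ordered_a.insert(int(rng.integers(len(ordered_a) + 1)),
                         (p, "+" if rng.random() < 0.5 else "-"))

    ordered_b: list[tuple[ProteinRecord, str]] = []
    for i, inv in b_order:
        strand = strands_a[i]
        if inv:
            strand = "-" if strand == "+" else "+"
        ordered_b.append((prots_b_orth[i], strand))
    for p in uniq_b:
        ordered_b.insert(int(rng.integers(len(ordered_b) + 1)),
                         (p, "+" if rng.random() < 0.5 else "-"))

    genes_a, all_prots_a = _assemble(ordered_a, "GA")
    genes_b, all_prots_b = _assemble(ordered_b, "GB")

    locus_of_prot_a = {g.protein_id: g.locus for g in genes_a}
    locus_of_prot_b = {g.protein_id: g.locus for g in genes_b}
    truth = pd.DataFrame(
        {
            "locus_a": [locus_of_prot_a[p.id] for p in prots_a_orth],
            "locus_b": [locus_of_prot_b[p.id] for p in prots_b_orth],
            "target_identity": identities,
            "block": block_of,
            "inverted": [bool(inverted[b]) for b in block_of],
        }
    )
    params = {
        "n_orthologs": n_orthologs, "identity_range": list(identity_range),
        "n_unique_each": n_unique_each, "n_blocks": n_blocks,
        "protein_len_range": list(protein_len_range),
    }
    return (genes_a, all_prots_a), (genes_b, all_prots_b), SimTruth(
        seed=seed, table=truth, params=params
    )
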