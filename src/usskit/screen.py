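"""Comparative procedures: virulence-panel screening and ortholog pairing.

The panel screen takes a set of query proteins (e.g. known Pasteurellaceae
virulence factors or competence proteins) with metadata, finds each query's
top hit in a target proteome, and bands the hit's validity by amino-acid
identity: 60-75% putative, 40-59% probable, 25-39% possible, with NA when
there is no hit, identity is below 25%, or the aligned region covers less
than 25% of the *query* length. Identity above 75% is labelled "strong"
rather than silently capped at "putative". Note the coverage denominator
here is the query, deliberately different from the annotation tiers' subject
denominator.

Ortholog pairing between two genomes automates a manual gene-order-aware
compilation: reciprocal best hits at >= 25% protein identity are accepted
outright, and a non-reciprocal best-hit candidate is rescued only when an
adjacent gene pair with the same relative orientation is already paired
(adjacency-based synteny support standing in for manual inspection of gene
order and intergenic features). Output is one-to-one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .align import AlignmentResult, best_hits
from .seqio import GeneRecord, HomologyHit, ProteinRecord
from .uss import round_half_up

ORTHOLOG_IDENTITY_FLOOR = 25.0
#: An ortholog candidate's alignment must span at least this percent of the
#: shorter protein: "identity at the protein level" implies more than a
#: short local block, and unrelated proteins routinely reach 25% identity
#: over a few dozen aligned columns.
ORTHOLOG_COVERAGE_FLOOR = 25.0
SCREEN_COVERAGE_FLOOR = 25.0

#: Identity bands (inclusive bounds) for screen validity.
VALIDITY_BANDS = (
    ("strong", 75.0, math.inf),     # above the published bands; open-ended
    ("putative", 60.0, 75.0),
    ("probable", 40.0, 60.0),
    ("possible", 25.0, 40.0),
)


@dataclass(frozen=True)
class ScreenRow:
    """One panel query's top-hit report row."""

    query_name: str
    query_id: str
    organism: str
    function: str
    query_len: int
    subject_id: str | None
    subject_len: int | None
    evalue: float
    aln_len: int | None
    pct_identity: float | None
    pct_similarity: float | None
    aln_pct_of_query: float | None
    validity: str


@dataclass(frozen=True)
class OrthologPair:
    locus_a: str
    locus_b: str
    pct_identity: float
    reciprocal_best: bool
    synteny_support: int

    def __post_init__(self) -> None:
        if self.pct_identity < ORTHOLOG_IDENTITY_FLOOR:
            raise ValueError(
                f"pair {self.locus_a}/{self.locus_b}: identity "
                f"{self.pct_identity:.1f} below the 25% floor"
            )


def validity_band(
    pct_identity: float | None, coverage_vs_query: float | None
) -> str:
    """Band a hit's validity by identity, NA below the coverage floor.

    Bands partition [25, 75]: 25-39 possible, 40-59 probable, 60-75
    putative; identity > 75 is "strong". NA when there is no hit, identity
    < 25, or coverage-vs-query < 25%.
    """
    if pct_identity is None or coverage_vs_query is None:
        return "NA"
    if coverage_vs_query < SCREEN_COVERAGE_FLOOR:
        return "NA"
    if pct_identity > 75.0:
        return "strong"
    for name, lo, hi in VALIDITY_BANDS[1:]:
        if lo <= pct_identity <= hi:
            return name
    return "NA"


def screen_panel(
    panel: Sequence[ProteinRecord],
    panel_meta: Mapping[str, Mapping],
    target_proteome: Sequence[ProteinRecord],
    hits: Mapping[str, Sequence[AlignmentResult]] | None = None,
) -> list[ScreenRow]:
    """Top-hit screen of a query panel against a target proteome.

    ``panel_meta`` maps query id -> dict with keys among ``name``,
    ``organism``, ``function``, ``length`` (length is required). ``hits``
    may supply precomputed ranked hits (e.g. from an external aligner via
    the tabular hit format); when None the built-in aligner is used.
    """
    for rec in panel:
        meta = panel_meta.get(rec.id, {})
        if "length" not in meta or not meta["length"]:
            raise ValueError(f"panel entry {rec.id!r} is missing its length")
    if hits is None:
        hits = best_hits(list(panel), list(target_proteome))
    target_lens = {p.id: p.length_aa for p in target_proteome}

    rows: list[ScreenRow] = []
    for rec in panel:
        meta = panel_meta[rec.id]
        qlen = int(meta["length"])
        ranked = hits.get(rec.id, [])
        if not ranked:
            rows.append(
                ScreenRow(
                    query_name=str(meta.get("name", rec.id)),
                    query_id=rec.id,
                    organism=str(meta.get("organism", "")),
                    function=str(meta.get("function", "")),
                    query_len=qlen,
                    subject_id=None,
                    subject_len=None,
                    evalue=math.nan,
                    aln_len=None,
                    pct_identity=None,
                    pct_similarity=None,
                    aln_pct_of_query=None,
                    validity="NA",
                )
            )
            continue
        top = ranked[0]
        cov = 100.0 * top.aln_len / qlen
        rows.append(
            ScreenRow(
                query_name=str(meta.get("name", rec.id)),
                query_id=rec.id,
                organism=str(meta.get("organism", "")),
                function=str(meta.get("function", "")),
                query_len=qlen,
                subject_id=top.subject_id,
                subject_len=target_lens.get(top.subject_id),
                evalue=math.nan,
                aln_len=top.aln_len,
                pct_identity=top.pct_identity,
                pct_similarity=top.pct_similarity,
                aln_pct_of_query=cov,
                validity=validity_band(top.pct_identity, cov),
            )
        )
    return rows


def screen_rows_to_frame(rows: Sequence[ScreenRow]) -> pd.DataFrame:
    def fmt(x, nd=1):
        return "NA" if x is None else f"{x:.{nd}f}"

    return pd.DataFrame(
        {
            "name": [r.query_name for r in rows],
            "query": [r.query_id for r in rows],
            "organism": [r.organism for r in rows],
            "function": [r.function for r in rows],
            "query_len": [r.query_len for r in rows],
            "subject": [r.subject_id or "NA" for r in rows],
            "subject_len": [
                "NA" if r.subject_len is None else r.subject_len for r in rows
            ],
            "aln_len": [
                "NA" if r.aln_len is None else r.aln_len for r in rows
            ],
            "pct_identity": [fmt(r.pct_identity) for r in rows],
            "pct_similarity": [fmt(r.pct_similarity) for r in rows],
            "aln_pct_of_query": [fmt(r.aln_pct_of_query) for r in rows],
            "validity": [r.validity for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# Ortholog pairing


def _check_unique_loci(genes: Sequence[GeneRecord], label: str) -> None:
    seen = {g.locus for g in genes}
    if len(seen) != len(genes):
        raise ValueError(f"duplicate locus tags in genome {label}")


def _gene_order(genes: Sequence[GeneRecord]) -> list[GeneRecord]:
    return sorted(genes, key=lambda g: (g.start, g.locus))


def pair_orthologs(
    genes_a: Sequence[GeneRecord],
    proteins_a: Sequence[ProteinRecord],
    genes_b: Sequence[GeneRecord],
    proteins_b: Sequence[ProteinRecord],
) -> list[OrthologPair]:
    """One-to-one ortholog pairs between two annotated genomes.

    Reciprocal best hits with >= 25% identity are accepted; a candidate
    that is a best hit in only one direction is accepted when at least one
    adjacent, same-relative-orientation gene pair is already accepted
    (synteny support). ``synteny_support`` on each returned pair counts its
    paired neighbors (0-2). Output is sorted by ``locus_a``.
    """
    _check_unique_loci(genes_a, "A")
    _check_unique_loci(genes_b, "B")
    if not genes_a or not genes_b:
        return []

    prot_a = {p.id: p for p in proteins_a}
    prot_b = {p.id: p for p in proteins_b}
    for g in genes_a:
        if (g.protein_id or g.locus) not in prot_a:
            raise ValueError(f"genome A gene {g.locus} has no protein")
    for g in genes_b:
        if (g.protein_id or g.locus) not in prot_b:
            raise ValueError(f"genome B gene {g.locus} has no protein")

    order_a = _gene_order(genes_a)
    order_b = _gene_order(genes_b)
    locus_by_prot_a = {(g.protein_id or g.locus): g.locus for g in genes_a}
    locus_by_prot_b = {(g.protein_id or g.locus): g.locus for g in genes_b}
    gene_a = {g.locus: g for g in genes_a}
    gene_b = {g.locus: g for g in genes_b}
    pos_a = {g.locus: i for i, g in enumerate(order_a)}
    pos_b = {g.locus: i for i, g in enumerate(order_b)}

    # Score every A-protein against every B-protein once; symmetric score
    # and identity let one matrix serve both directions.
    hits_ab = best_hits(
        [prot_a[g.protein_id or g.locus] for g in order_a],
        [prot_b[g.protein_id or g.locus] for g in order_b],
    )

    def _admissible(res: AlignmentResult) -> bool:
        """Identity floor plus protein-level span: the alignment must cover
        >= 25% of the shorter protein."""
        shorter = min(
            prot_a[res.query_id].length_aa, prot_b[res.subject_id].length_aa
        )
        return (
            res.pct_identity >= ORTHOLOG_IDENTITY_FLOOR
            and 100.0 * res.aln_len / shorter >= ORTHOLOG_COVERAGE_FLOOR
        )

    def top(pid_a: str) -> AlignmentResult | None:
        ranked = hits_ab.get(pid_a, [])
        return ranked[0] if ranked else None

    # Best hit B->A from the same matrix: for each B protein, the A protein
    # giving the highest score (ties: identity, then A locus).
    best_for_b: dict[str, tuple[float, float, str]] = {}
    ident: dict[tuple[str, str], float] = {}
    res_by: dict[tuple[str, str], AlignmentResult] = {}
    for pid_a, ranked in hits_ab.items():
        la = locus_by_prot_a[pid_a]
        for res in ranked:
            lb = locus_by_prot_b[res.subject_id]
            ident[(la, lb)] = res.pct_identity
            res_by[(la, lb)] = res
            key = (-res.score, -res.pct_identity, la)
            if res.subject_id not in best_for_b or key < best_for_b[
                res.subject_id
            ][0:3]:
                best_for_b[res.subject_id] = key

    paired_a: dict[str, str] = {}
    paired_b: dict[str, str] = {}
    reciprocal: set[tuple[str, str]] = set()

    # Pass 1: reciprocal best hits above the identity floor.
    for g in order_a:
        pid_a = g.protein_id or g.locus
        res = top(pid_a)
        if res is None or not _admissible(res):
            continue
        lb = locus_by_prot_b[res.subject_id]
        back = best_for_b.get(res.subject_id)
        if back is not None and back[2] == g.locus and lb not in paired_b:
            paired_a[g.locus] = lb
            paired_b[lb] = g.locus
            reciprocal.add((g.locus, lb))

    def _same_relative_orientation(la1, lb1, la2, lb2) -> bool:
        s = lambda g: 1 if g.strand == "+" else -1
        return (s(gene_a[la1]) * s(gene_b[lb1])) == (
            s(gene_a[la2]) * s(gene_b[lb2])
        )

    def _has_synteny(la: str, lb: str) -> bool:
        ia, ib = pos_a[la], pos_b[lb]
        for da in (-1, 1):
            ja = ia + da
            if not 0 <= ja < len(order_a):
                continue
            neighbor = order_a[ja].locus
            partner = paired_a.get(neighbor)
            if partner is None:
                continue
            if abs(pos_b[partner] - ib) == 1 and _same_relative_orientation(
                la, lb, neighbor, partner
            ):
                return True
        return False

    # Pass 2: rescue one-directional best hits with synteny support.
    candidates = []
    for g in order_a:
        if g.locus in paired_a:
            continue
        pid_a = g.protein_id or g.locus
        res = top(pid_a)
        if res is None or not _admissible(res):
            continue
        lb = locus_by_prot_b[res.subject_id]
        candidates.append((g.locus, lb, res.pct_identity))
    for pid_b, (negscore, negident, la) in best_for_b.items():
        lb = locus_by_prot_b[pid_b]
        if lb in paired_b or la in paired_a:
            continue
        res = res_by.get((la, lb))
        if res is None or not _admissible(res):
            continue
        candidates.append((la, lb, -negident))
    candidates = sorted(set(candidates), key=lambda c: (-c[2], c[0], c[1]))
    for la, lb, pid in candidates:
        if la in paired_a or lb in paired_b:
            continue
        if _has_synteny(la, lb):
            paired_a[la] = lb
            paired_b[lb] = la

    pairs = []
    for la in sorted(paired_a):
        lb = paired_a[la]
        support = 0
        ia, ib = pos_a[la], pos_b[lb]
        for da in (-1, 1):
            ja = ia + da
            if not 0 <= ja < len(order_a):
                continue
            partner = paired_a.get(order_a[ja].locus)
            if partner is not None and abs(pos_b[partner] - ib) == 1:
                support += 1
        pairs.append(
            OrthologPair(
                locus_a=la,
                locus_b=lb,
                pct_identity=ident[(la, lb)],
                reciprocal_best=(la, lb) in reciprocal,
                synteny_support=support,
            )
        )
    return pairs


def ortholog_pairs_to_frame(pairs: Sequence[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_a": [p.locus_a for p in pairs],
            "locus_b": [p.locus_b for p in pairs],
            "pct_identity": [f"{p.pct_identity:.1f}" for p in pairs],
            "reciprocal": [p.reciprocal_best for p in pairs],
            "synteny_support": [p.synteny_support for p in pairs],
        }
    )


def shared_orf_stats(
    pairs: Sequence[OrthologPair],
    n_total_a: int,
    n_total_b: int,
    n_total_union: int,
) -> dict[str, float | int]:
    """Shared-ORF accounting between two genomes.

    ``pct_shared`` is the pair count as a rounded percent of the stated
    union denominator (how that denominator is derived from two proteomes
    is a reporting choice, so it is an explicit input).
    """
    n = len(pairs)
    if n_total_a < n or n_total_b < n or n_total_union < n:
        raise ValueError("totals must be >= number of pairs")
    return {
        "n_shared": n,
        "pct_shared": int(round_half_up(100.0 * n / n_total_union, 0)),
        "n_unique_a": n_total_a - n,
        "n_unique_b": n_total_b - n,
    }
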