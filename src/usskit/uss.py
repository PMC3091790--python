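"""Uptake-signal-sequence (USS) scanning and flanking-composition profiling.

Pasteurellaceae genomes carry hundreds to thousands of copies of a 9-bp
uptake signal sequence core — AAGTGCGGT (USS1) in most species, ACAAGCGGT
(USS2) in a minority — that marks DNA for preferential internalization during
natural transformation. Each genome strongly favors one core or the other.
This module locates exact core matches on both strands, summarizes a genome
the way comparative USS tables are reported (counts for both cores, the
dominant core, USS density per kb, and the percentage of sites whose core is
immediately followed by a C), and computes per-position nucleotide
frequencies in the sequence flanking the core.

Position convention: flanking positions are numbered -U..-1 upstream of the
core, 1..9 within the core, and +1..+D downstream, all read 5'->3' in the
core's own orientation. Under the extended-USS numbering used in comparative
tables the core occupies nt 3-11, so "nt 12" is position +1 here — the base
immediately 3' of the core.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import GenomeSequence, reverse_complement

#: The two canonical 9-mer cores.
USS_CORES: dict[str, str] = {
    "USS1": "AAGTGCGGT",
    "USS2": "ACAAGCGGT",
}

CORE_LEN = 9

#: Default flanking window: 10 bases upstream, 30 downstream — wide enough
#: to cover the AT-rich tail and the USS2 GCAAA(A/T) element ~20 nt
#: downstream of the core.
DEFAULT_UP = 10
DEFAULT_DOWN = 30

NUCLEOTIDES = ("A", "C", "G", "T")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, matching printed-table arithmetic."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class UssOccurrence:
    """One located core hit.

    ``start`` is the 1-based forward-strand position of the core's first base
    *as read in the core's own orientation*: for a plus-strand hit this is
    the leftmost core base; for a minus-strand hit it is the rightmost
    forward-strand base of the reverse-complement match. ``window`` is the
    oriented sequence (5'->3' on the core's strand) containing up to ``u``
    upstream bases, the 9-base core, and up to ``d`` downstream bases;
    ``truncated5``/``truncated3`` flag windows cut short by the genome edge.
    """

    genome_id: str
    core: str
    start: int
    strand: str
    window: str
    u: int            # upstream bases actually present in window
    d: int            # downstream bases actually present in window
    truncated5: bool
    truncated3: bool

    @property
    def core_seq(self) -> str:
        return self.window[self.u : self.u + CORE_LEN]

    def flank_base(self, pos: int) -> str | None:
        """Base at flanking position ``pos`` (negative = upstream, positive
        = downstream, in core orientation); None if outside the window."""
        if pos == 0 or not (-self.u <= pos <= self.d):
            return None
        if pos < 0:
            return self.window[self.u + pos]
        return self.window[self.u + CORE_LEN + pos - 1]


@dataclass(frozen=True)
class UssProfile:
    """Per-position nucleotide frequencies around a core.

    ``freq`` is indexed by position label (-U..-1, 1..9, +1..+D) with columns
    A, C, G, T and ``n_obs`` (the per-position denominator: occurrences whose
    window covers that position). Positions with zero observations carry NaN
    frequencies and are flagged rather than emitted as frequencies.
    """

    core: str
    n_sites: int
    upstream_span: int
    downstream_span: int
    freq: pd.DataFrame


@dataclass(frozen=True)
class UssSummary:
    """A one-genome row of a comparative USS table.

    ``dominant`` is None (undefined) when neither core occurs; then density
    is 0 and ``c_at_12_pct`` is None.
    """

    genome_id: str
    genome_size_nt: int
    uss1_count: int
    uss2_count: int
    dominant: str | None
    c_at_12_pct: int | None
    density_uss_per_kb: float


def position_labels(u: int, d: int) -> list[str]:
    """Ordered flanking-position labels: -U..-1, 1..9, +1..+D."""
    return (
        [str(-k) for k in range(u, 0, -1)]
        + [str(k) for k in range(1, CORE_LEN + 1)]
        + [f"+{k}" for k in range(1, d + 1)]
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    """0-based start indices of every (possibly overlapping) exact match."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_core_occurrences(
    genome: GenomeSequence,
    core: str,
    upstream: int = DEFAULT_UP,
    downstream: int = DEFAULT_DOWN,
) -> list[UssOccurrence]:
    """Locate every exact match of a 9-mer core on both strands.

    Matches may overlap and are each counted; N never matches. The result is
    sorted by the leftmost forward-strand coordinate of the core (minus
    before plus at equal coordinate is impossible for distinct cores; ties
    order plus first for determinism).
    """
    core9 = USS_CORES[core] if core in USS_CORES else core
    if len(core9) != CORE_LEN:
        raise ValueError(f"core must be a 9-mer, got {core9!r}")
    seq = genome.residues
    n = len(seq)
    occs: list[tuple[int, int, UssOccurrence]] = []

    for i in _find_all(seq, core9):  # plus strand: core at seq[i:i+9]
        lo = max(0, i - upstream)
        hi = min(n, i + CORE_LEN + downstream)
        occs.append(
            (
                i,
                0,
                UssOccurrence(
                    genome_id=genome.id,
                    core=core,
                    start=i + 1,
                    strand="+",
                    window=seq[lo:hi],
                    u=i - lo,
                    d=hi - (i + CORE_LEN),
                    truncated5=i - lo < upstream,
                    truncated3=hi - (i + CORE_LEN) < downstream,
                ),
            )
        )

    rc_core = reverse_complement(core9)
    for j in _find_all(seq, rc_core):  # minus strand: rc(core) at seq[j:j+9]
        # In core orientation, upstream lies to the right on the forward
        # strand and downstream to the left.
        lo = max(0, j - downstream)
        hi = min(n, j + CORE_LEN + upstream)
        window = reverse_complement(seq[lo:hi])
        occs.append(
            (
                j,
                1,
                UssOccurrence(
                    genome_id=genome.id,
                    core=core,
                    start=j + CORE_LEN,  # 5'-most core base on minus strand
                    strand="-",
                    window=window,
                    u=hi - (j + CORE_LEN),
                    d=j - lo,
                    truncated5=hi - (j + CORE_LEN) < upstream,
                    truncated3=j - lo < downstream,
                ),
            )
        )

    occs.sort(key=lambda t: (t[0], t[1]))
    return [o for _, _, o in occs]


def uss_density(dominant_count: int, genome_size_nt: int) -> float:
    """USS density in sites/kb: dominant count over genome size in kb,
    rounded half-up to 2 decimals."""
    if genome_size_nt <= 0:
        raise ValueError("genome_size_nt must be positive")
    return round_half_up(dominant_count / (genome_size_nt / 1000.0), 2)


def dominant_core(uss1_count: int, uss2_count: int) -> str | None:
    """The core with the larger count; USS1 wins ties; None if both zero."""
    if uss1_count == 0 and uss2_count == 0:
        return None
    return "USS1" if uss1_count >= uss2_count else "USS2"


def c_at_12_percent(occurrences: Sequence[UssOccurrence]) -> int | None:
    """Percent of occurrences whose +1 base (nt 12 of the extended USS) is C.

    Occurrences whose +1 base falls off the sequence end are excluded from
    the denominator. None when no occurrence has an in-genome +1 base.
    """
    eligible = [o.flank_base(1) for o in occurrences if o.d >= 1]
    if not eligible:
        return None
    n_c = sum(1 for b in eligible if b == "C")
    return int(round_half_up(100.0 * n_c / len(eligible), 0))


def summarize_uss(genome: GenomeSequence) -> UssSummary:
    """Compute a comparative-table row for one genome.

    Counts both cores on both strands; the dominant core drives density and
    the C-at-nt-12 percentage.
    """
    if genome.length_bp == 0:
        raise ValueError("genome is empty")
    occ1 = find_core_occurrences(genome, "USS1")
    occ2 = find_core_occurrences(genome, "USS2")
    n1, n2 = len(occ1), len(occ2)
    dom = dominant_core(n1, n2)
    if dom is None:
        return UssSummary(
            genome_id=genome.id,
            genome_size_nt=genome.length_bp,
            uss1_count=0,
            uss2_count=0,
            dominant=None,
            c_at_12_pct=None,
            density_uss_per_kb=0.0,
        )
    dom_occ = occ1 if dom == "USS1" else occ2
    return UssSummary(
        genome_id=genome.id,
        genome_size_nt=genome.length_bp,
        uss1_count=n1,
        uss2_count=n2,
        dominant=dom,
        c_at_12_pct=c_at_12_percent(dom_occ),
        density_uss_per_kb=uss_density(len(dom_occ), genome.length_bp),
    )


def flanking_profile(
    occurrences: Sequence[UssOccurrence], upstream: int, downstream: int
) -> UssProfile:
    """Per-position nucleotide frequencies over an occurrence set.

    Edge-truncated occurrences are excluded position-wise, not globally:
    each position's denominator counts only occurrences whose window covers
    it. Windows containing N contribute only at positions where the base is
    unambiguous.
    """
    if not occurrences:
        raise ValueError("no occurrences: cannot profile an empty set")
    cores = {o.core for o in occurrences}
    if len(cores) != 1:
        raise ValueError(f"occurrences mix cores: {sorted(cores)}")
    if upstream < 0 or downstream < 0:
        raise ValueError("window spans must be >= 0")

    labels = position_labels(upstream, downstream)
    positions = list(range(-upstream, 0)) + list(range(1, CORE_LEN + 1))
    positions += [("down", k) for k in range(1, downstream + 1)]

    counts = np.zeros((len(labels), 4), dtype=np.int64)
    base_idx = {b: k for k, b in enumerate(NUCLEOTIDES)}
    for occ in occurrences:
        for row, pos in enumerate(positions):
            if isinstance(pos, tuple):
                base = occ.flank_base(pos[1])
            elif pos < 0:
                base = occ.flank_base(pos)
            else:  # core position 1..9
                base = occ.window[occ.u + pos - 1]
            if base in base_idx:
                counts[row, base_idx[base]] += 1

    n_obs = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / n_obs[:, None]
    df = pd.DataFrame(freqs, index=labels, columns=list(NUCLEOTIDES))
    df["n_obs"] = n_obs
    df.index.name = "position"
    return UssProfile(
        core=next(iter(cores)),
        n_sites=len(occurrences),
        upstream_span=upstream,
        downstream_span=downstream,
        freq=df,
    )


# ---------------------------------------------------------------------------
# TSV writers (report shapes mirror the comparative-table column order)


def occurrences_to_frame(occurrences: Sequence[UssOccurrence]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genome": [o.genome_id for o in occurrences],
            "core": [o.core for o in occurrences],
            "start": [o.start for o in occurrences],
            "strand": [o.strand for o in occurrences],
            "window": [o.window for o in occurrences],
            "truncated5": [o.truncated5 for o in occurrences],
            "truncated3": [o.truncated3 for o in occurrences],
        }
    )


def summaries_to_frame(summaries: Sequence[UssSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genome": [s.genome_id for s in summaries],
            "size_nt": [s.genome_size_nt for s in summaries],
            "uss1": [s.uss1_count for s in summaries],
            "uss2": [s.uss2_count for s in summaries],
            "dominant": [s.dominant or "NA" for s in summaries],
            "c_at_12_pct": [
                "NA" if s.c_at_12_pct is None else s.c_at_12_pct
                for s in summaries
            ],
            "density": [
                f"{s.density_uss_per_kb:.2f}" for s in summaries
            ],
        }
    )
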