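"""Manual-annotation decision rules: tiered product naming and RBS detection.

Product naming follows the tiered identity/coverage rules used in curated
bacterial genome annotation: a translated ORF highly similar to a protein of
known function inherits its product name outright; weaker homology qualifies
the name ("putative", "probable", "possible"); strong similarity to a
protein of unknown function yields "conserved hypothetical protein"; and
anything below the floor is a "hypothetical protein". Membership in an
equivalog family (an HMM family asserting one specific function) is taken as
an input flag and short-circuits the identity test for the top tier.

The tiers are evaluated as a lower-bound cascade — best tier first, falling
through when its identity or coverage minimum fails. This keeps every
published band's members in their band while making the rule total and
monotone (the printed bands overlap at 60-64% identity and leave some
identity/coverage combinations, e.g. 70%/50%, between bands).

The ribosome-binding-site rule searches for at least 3 consecutive bases of
the canonical Shine-Dalgarno sequence AAGGAGG in the window 5-10 nt upstream
of a start codon.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import HomologyHit

RBS_CONSENSUS = "AAGGAGG"
RBS_MIN_MATCH = 3
RBS_WINDOW_NEAR = 5   # nearest base of the window, nt upstream of start
RBS_WINDOW_FAR = 10   # farthest base of the window

#: Tier order, best first. ``conserved_hypothetical`` requires an
#: unknown-function subject and so sits outside the known-function ladder.
TIERS = (
    "product",
    "putative",
    "probable",
    "possible",
    "conserved_hypothetical",
    "hypothetical",
)

#: (identity floor, coverage floor) per known-function tier.
TIER_THRESHOLDS = {
    "product": (75.0, 75.0),
    "putative": (60.0, 65.0),
    "probable": (40.0, 40.0),
    "possible": (25.0, 25.0),
}

CONSERVED_HYPOTHETICAL_ID = 60.0


@dataclass(frozen=True)
class ProductCall:
    tier: str
    name: str
    pct_identity: float | None = None
    pct_coverage: float | None = None


@dataclass(frozen=True)
class RbsCall:
    """Result of the Shine-Dalgarno search upstream of one start codon.

    ``distance`` counts the bases between the match's 3' end and the base
    immediately 5' of the start codon (0 = adjacent). ``truncated`` flags
    upstream sequences shorter than the full 10-nt reach, which were
    evaluated on the available window only.
    """

    found: bool
    match: str = ""
    match_len: int = 0
    distance: int = -1
    truncated: bool = False


def _tier_name(tier: str, product: str) -> str:
    if tier == "product":
        return product
    if tier in ("putative", "probable", "possible"):
        return f"{tier} {product}" if product else tier
    if tier == "conserved_hypothetical":
        return "conserved hypothetical protein"
    return "hypothetical protein"


def coverage_percent(
    hit: HomologyHit, denominator: str = "subject"
) -> float:
    """Alignment length as a percent of subject (product) or query length.

    Annotation uses the subject denominator ("the product length"); the
    comparative screen uses the query denominator.
    """
    ref_len = hit.subject_len if denominator == "subject" else hit.query_len
    if ref_len <= 0:
        raise ValueError(
            f"hit {hit.query_id}->{hit.subject_id}: "
            f"{denominator} length must be positive to compute coverage"
        )
    return 100.0 * hit.aln_len / ref_len


def classify_product(
    hit: HomologyHit | None,
    subject_known: bool,
    equivalog_member: bool = False,
    subject_product: str = "",
    coverage_denominator: str = "subject",
) -> ProductCall:
    """Assign an annotation tier and product name from homology evidence.

    The cascade, best tier first:

    1. equivalog member, or identity >= 75 and coverage >= 75, with a
       known-function subject -> unqualified product name;
    2. identity >= 60 and coverage >= 65, known -> "putative ...";
    3. identity >= 40 and coverage >= 40, known -> "probable ...";
    4. identity >= 25 and coverage >= 25, known -> "possible ...";
    5. identity >= 60 to an unknown-function subject ->
       "conserved hypothetical protein";
    6. otherwise (no hit, identity < 25, or coverage < 25) ->
       "hypothetical protein".

    All thresholds are inclusive lower bounds.
    """
    if hit is None:
        if equivalog_member and subject_known:
            return ProductCall(
                tier="product", name=_tier_name("product", subject_product)
            )
        return ProductCall(
            tier="hypothetical", name=_tier_name("hypothetical", "")
        )

    pid = hit.pct_identity
    cov = coverage_percent(hit, coverage_denominator)

    if subject_known:
        if equivalog_member or (
            pid >= TIER_THRESHOLDS["product"][0]
            and cov >= TIER_THRESHOLDS["product"][1]
        ):
            tier = "product"
        elif pid >= 60.0 and cov >= 65.0:
            tier = "putative"
        elif pid >= 40.0 and cov >= 40.0:
            tier = "probable"
        elif pid >= 25.0 and cov >= 25.0:
            tier = "possible"
        else:
            tier = "hypothetical"
    else:
        if pid >= CONSERVED_HYPOTHETICAL_ID:
            tier = "conserved_hypothetical"
        else:
            tier = "hypothetical"

    return ProductCall(
        tier=tier,
        name=_tier_name(tier, subject_product),
        pct_identity=pid,
        pct_coverage=cov,
    )


def find_rbs(upstream: str, mode: str = "whole-match") -> RbsCall:
    """Search for a Shine-Dalgarno match 5-10 nt upstream of a start codon.

    ``upstream`` is given 5'->3' with its last base immediately 5' of the
    start codon. The search window is the bases 10 through 5 nt upstream
    (inclusive). In ``whole-match`` mode the entire match must lie inside
    the window; in ``three-prime-end`` mode only the match's 3'-end base is
    constrained to the window (the match may extend further upstream).

    The longest contiguous substring of AAGGAGG (length >= 3) wins; ties go
    to the match closer to the start codon.
    """
    if mode not in ("whole-match", "three-prime-end"):
        raise ValueError(f"unknown RBS window mode {mode!r}")
    n = len(upstream)
    truncated = n < RBS_WINDOW_FAR
    # Window indices: base k nt upstream sits at string index n - k.
    win_lo = max(0, n - RBS_WINDOW_FAR)
    win_hi = n - RBS_WINDOW_NEAR + 1  # exclusive end (index of base 4-upstream)
    if win_hi <= win_lo:
        return RbsCall(found=False, truncated=truncated)

    best: tuple[int, int, str] | None = None  # (match_len, -distance, match)
    max_len = len(RBS_CONSENSUS)
    for length in range(max_len, RBS_MIN_MATCH - 1, -1):
        for off in range(0, max_len - length + 1):
            sub = RBS_CONSENSUS[off : off + length]
            search_lo = win_lo if mode == "whole-match" else 0
            start = upstream.find(sub, search_lo)
            while start != -1:
                end = start + length  # exclusive
                end_in_window = win_lo <= end - 1 < win_hi
                whole_in_window = start >= win_lo and end <= win_hi
                ok = whole_in_window if mode == "whole-match" else end_in_window
                if ok:
                    distance = n - end
                    cand = (length, -distance, sub)
                    if best is None or cand > best:
                        best = cand
                start = upstream.find(sub, start + 1)
        if best is not None:
            break  # longer matches always beat shorter ones

    if best is None:
        return RbsCall(found=False, truncated=truncated)
    length, neg_dist, sub = best
    return RbsCall(
        found=True,
        match=sub,
        match_len=length,
        distance=-neg_dist,
        truncated=truncated,
    )
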