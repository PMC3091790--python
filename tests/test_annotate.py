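"""Tiered product naming and ribosome-binding-site detection."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from usskit.annotate import (
    RBS_CONSENSUS,
    classify_product,
    find_rbs,
)
from usskit.seqio import HomologyHit

TIER_RANK = {
    "product": 4,
    "putative": 3,
    "probable": 2,
    "possible": 1,
    "hypothetical": 0,
}


def make_hit(pct_identity: float, coverage: float) -> HomologyHit:
    """Hit with subject length 1000 so coverage maps exactly to aln_len."""
    return HomologyHit(
        "q", "s",
        pct_identity=pct_identity,
        aln_len=max(1, int(round(coverage * 10))),
        query_len=1000,
        subject_len=1000,
    )


class TestClassifyProduct:
    @pytest.mark.parametrize(
        "pid,cov,known,tier",
        [
            (80, 80, True, "product"),
            (65, 70, True, "putative"),
            (30, 30, True, "possible"),
            (70, 90, False, "conserved_hypothetical"),
            (20, 90, True, "hypothetical"),
            (70, 50, True, "probable"),   # between-band case, cascade
            (45, 60, True, "probable"),
            (62, 50, True, "probable"),   # putative coverage fails
        ],
    )
    def test_published_examples(self, pid, cov, known, tier):
        call = classify_product(
            make_hit(pid, cov), subject_known=known, subject_product="X"
        )
        assert call.tier == tier

    def test_names_follow_tier(self):
        assert classify_product(
            make_hit(80, 80), True, subject_product="citrate lyase"
        ).name == "citrate lyase"
        assert classify_product(
            make_hit(65, 70), True, subject_product="citrate lyase"
        ).name == "putative citrate lyase"
        assert classify_product(
            make_hit(70, 90), False
        ).name == "conserved hypothetical protein"
        assert classify_product(None, True).name == "hypothetical protein"

    def test_equivalog_short_circuits_identity(self):
        call = classify_product(
            make_hit(30, 30), subject_known=True, equivalog_member=True,
            subject_product="X",
        )
        assert call.tier == "product"

    def test_no_hit_is_hypothetical(self):
        assert classify_product(None, True).tier == "hypothetical"

    def test_zero_subject_length_rejected(self):
        hit = HomologyHit("q", "s", pct_identity=50.0, aln_len=10,
                          query_len=100, subject_len=0)
        with pytest.raises(ValueError):
            classify_product(hit, True)

    def test_boundary_grid(self):
        """Threshold boundaries are inclusive lower bounds."""
        expectations = {
            (75, 75): "product",
            (74, 75): "putative",
            (75, 74): "putative",
            (60, 65): "putative",
            (60, 64): "probable",
            (59, 65): "probable",
            (40, 40): "probable",
            (39, 40): "possible",
            (40, 39): "possible",
            (25, 25): "possible",
            (24, 25): "hypothetical",
            (25, 24): "hypothetical",
        }
        for (pid, cov), tier in expectations.items():
            call = classify_product(make_hit(pid, cov), True,
                                    subject_product="X")
            assert call.tier == tier, (pid, cov)

    def test_totality_and_monotonicity_on_grid(self):
        """Every (identity, coverage) yields one tier, and increasing either
        never demotes the tier for known-function subjects."""
        grid = range(0, 101, 5)
        tiers = {}
        for pid, cov in itertools.product(grid, grid):
            call = classify_product(make_hit(pid, cov), True)
            assert call.tier in TIER_RANK
            tiers[(pid, cov)] = TIER_RANK[call.tier]
        for pid, cov in itertools.product(grid, grid):
            if pid + 5 <= 100:
                assert tiers[(pid + 5, cov)] >= tiers[(pid, cov)]
            if cov + 5 <= 100:
                assert tiers[(pid, cov + 5)] >= tiers[(pid, cov)]

    @given(st.floats(0, 100), st.floats(0.1, 100))
    def test_total_on_real_inputs(self, pid, cov):
        call = classify_product(make_hit(pid, cov), True)
        assert call.tier in TIER_RANK

    def test_unknown_subject_boundary(self):
        assert classify_product(
            make_hit(60, 90), False
        ).tier == "conserved_hypothetical"
        assert classify_product(
            make_hit(59, 90), False
        ).tier == "hypothetical"


def brute_force_rbs(upstream: str):
    """Enumerate every (substring of the consensus, placement) pair and
    apply the window rule directly."""
    n = len(upstream)
    win_lo, win_hi = max(0, n - 10), n - 4  # indices of bases 10..5 upstream
    best = None
    for length in range(3, 8):
        for off in range(0, 7 - length + 1):
            sub = RBS_CONSENSUS[off : off + length]
            for start in range(0, n - length + 1):
                if upstream[start : start + length] != sub:
                    continue
                if start < win_lo or start + length > win_hi:
                    continue
                distance = n - (start + length)
                cand = (length, -distance, sub)
                if best is None or cand > best:
                    best = cand
    return best


class TestFindRbs:
    def test_maximal_in_window_match(self):
        # AGGAGG occupies bases 10..5 upstream exactly.
        call = find_rbs("AGGAGGTTTT")
        assert call.found and call.match == "AGGAGG" and call.match_len == 6

    def test_all_t_not_found(self):
        assert not find_rbs("T" * 10).found

    def test_match_outside_window_not_found(self):
        # AGGAGG adjacent to the start codon: 3' end only 0 nt upstream.
        assert not find_rbs("TTTTAGGAGG").found

    def test_short_upstream_flagged_truncated(self):
        call = find_rbs("AGGTT")
        assert call.truncated

    def test_match_in_window_reports_distance(self):
        # AAG at bases 7..5 upstream: distance 4 to the start codon.
        call = find_rbs("TTTAAGTTTT")
        assert call.found and call.match == "AAG" and call.distance == 4

    def test_three_prime_end_mode_allows_upstream_overhang(self):
        # Full AAGGAGG ending 5 nt upstream: whole match cannot fit the
        # 6-base window, but its 3' end does.
        upstream = "TTAAGGAGGTTTT"[:13]
        strict = find_rbs(upstream, mode="whole-match")
        relaxed = find_rbs(upstream, mode="three-prime-end")
        assert relaxed.match_len >= strict.match_len

    def test_agrees_with_exhaustive_enumerator(self):
        import numpy as np

        rng = np.random.default_rng(31)
        bases = np.array(list("ACGT"))
        for _ in range(500):
            upstream = "".join(
                bases[rng.integers(0, 4, size=rng.integers(10, 16))]
            )
            call = find_rbs(upstream)
            expected = brute_force_rbs(upstream)
            if expected is None:
                assert not call.found, upstream
            else:
                assert call.found, upstream
                assert (call.match_len, -call.distance, call.match) == (
                    expected
                ), upstream
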