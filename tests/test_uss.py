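"""USS scanning, comparative summaries, and flanking profiles."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from usskit.seqio import GenomeSequence, reverse_complement
from usskit.uss import (
    USS_CORES,
    c_at_12_percent,
    dominant_core,
    find_core_occurrences,
    flanking_profile,
    summarize_uss,
    uss_density,
)

USS1 = USS_CORES["USS1"]
USS2 = USS_CORES["USS2"]


def brute_force_counts(seq: str, core9: str) -> tuple[int, int]:
    """Independent position-by-position scan of both strands."""
    rc = reverse_complement(core9)
    fwd = sum(
        1 for i in range(len(seq) - 8) if seq[i : i + 9] == core9
    )
    rev = sum(
        1 for i in range(len(seq) - 8) if seq[i : i + 9] == rc
    )
    return fwd, rev


class TestFindCoreOccurrences:
    def test_single_forward_match(self):
        occ = find_core_occurrences(GenomeSequence("g", USS1), "USS1")
        assert len(occ) == 1
        assert occ[0].strand == "+" and occ[0].start == 1

    def test_single_reverse_match(self):
        occ = find_core_occurrences(
            GenomeSequence("g", reverse_complement(USS1)), "USS1"
        )
        assert len(occ) == 1
        assert occ[0].strand == "-"
        # 5'-most core base on the minus strand maps to forward position 9
        assert occ[0].start == 9
        assert occ[0].core_seq == USS1

    def test_n_never_matches(self):
        seq = USS1.replace("G", "N", 1)
        assert find_core_occurrences(GenomeSequence("g", seq), "USS1") == []

    def test_window_truncation_flags(self):
        occ = find_core_occurrences(
            GenomeSequence("g", "AA" + USS1 + "CCC"), "USS1"
        )[0]
        assert occ.truncated5 and occ.truncated3
        assert occ.u == 2 and occ.d == 3
        assert occ.window == "AA" + USS1 + "CCC"

    @given(st.text(alphabet="ACGTN", max_size=2000), st.integers(0, 400))
    def test_matches_brute_force(self, background, insert_at):
        seq = (
            background[: insert_at] + USS1 + background[insert_at:]
        )
        fwd, rev = brute_force_counts(seq, USS1)
        occ = find_core_occurrences(GenomeSequence("g", seq), "USS1")
        assert len(occ) == fwd + rev
        assert sum(1 for o in occ if o.strand == "+") == fwd

    def test_planted_simulation_matches_oracle(self, planted_genome):
        genome, truth = planted_genome
        fwd, rev = brute_force_counts(genome.residues, USS1)
        occ = find_core_occurrences(genome, "USS1")
        assert len(occ) == fwd + rev
        assert len(occ) >= len(truth.table)
        found = {(o.start, o.strand) for o in occ}
        for row in truth.table.itertuples():
            assert (row.start, row.strand) in found

    def test_strand_balance_of_symmetric_planting(self, planted_genome):
        genome, truth = planted_genome
        occ = find_core_occurrences(genome, "USS1")
        f = sum(1 for o in occ if o.strand == "+")
        r = len(occ) - f
        assert abs(f - r) <= 4 * math.sqrt(len(occ))

    def test_sorted_by_forward_coordinate(self, planted_genome):
        genome, _ = planted_genome
        occ = find_core_occurrences(genome, "USS1")
        lefts = [o.start if o.strand == "+" else o.start - 8 for o in occ]
        assert lefts == sorted(lefts)


class TestSummaries:
    @pytest.mark.parametrize(
        "uss1,uss2,size,dominant,density",
        [
            (1690, 73, 2_319_663, "USS1", 0.73),
            (1485, 95, 2_314_078, "USS1", 0.64),
            (41, 199, 1_698_955, "USS2", 0.12),
        ],
    )
    def test_printed_density_arithmetic(
        self, uss1, uss2, size, dominant, density
    ):
        assert dominant_core(uss1, uss2) == dominant
        dom_count = uss1 if dominant == "USS1" else uss2
        assert uss_density(dom_count, size) == density

    def test_core_followed_by_c(self):
        g = GenomeSequence("g", USS1 + "C")
        s = summarize_uss(g)
        assert s.c_at_12_pct == 100
        assert s.uss1_count == 1 and s.dominant == "USS1"

    def test_plus1_off_end_excluded_from_denominator(self):
        # Two sites; only one has an in-genome +1 base (a C).
        g = GenomeSequence("g", USS1 + "C" + "TTTT" + USS1)
        assert summarize_uss(g).c_at_12_pct == 100

    def test_no_occurrences_flagged_undefined(self):
        s = summarize_uss(GenomeSequence("g", "T" * 100))
        assert s.dominant is None
        assert s.c_at_12_pct is None
        assert s.density_uss_per_kb == 0.0

    def test_density_invariant_under_genome_revcomp(self, planted_genome):
        genome, _ = planted_genome
        flipped = GenomeSequence(
            "flip", reverse_complement(genome.residues)
        )
        assert (
            summarize_uss(genome).density_uss_per_kb
            == summarize_uss(flipped).density_uss_per_kb
        )

    def test_c_at_12_matches_profile_plus1(self, planted_genome):
        genome, _ = planted_genome
        occ = find_core_occurrences(genome, "USS1")
        profile = flanking_profile(occ, 10, 30)
        from usskit.uss import round_half_up

        expected = round_half_up(100.0 * profile.freq.loc["+1", "C"], 0)
        assert c_at_12_percent(occ) == expected


class TestFlankingProfile:
    def test_single_site_window(self):
        occ = find_core_occurrences(
            GenomeSequence("g", "A" + USS1 + "C"), "USS1", 1, 1
        )
        profile = flanking_profile(occ, 1, 1)
        assert profile.freq.loc["-1", "A"] == 1.0
        assert profile.freq.loc["+1", "C"] == 1.0

    def test_core_positions_frequency_one(self):
        occ = find_core_occurrences(
            GenomeSequence("g", "TT" + USS1 + "GG"), "USS1", 2, 2
        )
        profile = flanking_profile(occ, 2, 2)
        for k, base in enumerate(USS1, start=1):
            assert profile.freq.loc[str(k), base] == 1.0

    def test_rows_sum_to_one(self, planted_genome):
        genome, _ = planted_genome
        occ = find_core_occurrences(genome, "USS1")
        profile = flanking_profile(occ, 10, 30)
        observed = profile.freq[profile.freq["n_obs"] > 0]
        sums = observed[list("ACGT")].sum(axis=1)
        assert ((sums - 1.0).abs() < 1e-9).all()

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            flanking_profile([], 10, 30)

    def test_mixed_cores_rejected(self):
        occ1 = find_core_occurrences(GenomeSequence("g", USS1), "USS1")
        occ2 = find_core_occurrences(GenomeSequence("g", USS2), "USS2")
        with pytest.raises(ValueError):
            flanking_profile(occ1 + occ2, 10, 30)

    def test_flank_model_recovery(self):
        """Estimated P(C at +1) converges to the planted 0.71 within 3
        binomial standard errors at n=2000 sites."""
        from usskit.simulate import simulate_genome

        genome, truth = simulate_genome(
            length_bp=120_000, gc=0.45, n_forward=1000, n_reverse=1000,
            seed=11,
        )
        occ = find_core_occurrences(genome, "USS1")
        profile = flanking_profile(occ, 10, 30)
        p_hat = profile.freq.loc["+1", "C"]
        se = math.sqrt(0.71 * 0.29 / 2000)
        assert abs(p_hat - 0.71) <= 3 * se
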