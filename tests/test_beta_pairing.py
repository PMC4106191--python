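import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peptopo.beta_pairing import (
    PairingError,
    aggregation_profile,
    classify_amyloid,
    enumerate_pairings,
    load_table,
    save_table,
    score_pairing,
    toy_table,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_score(seq_a, seq_b, seg_a, seg_b, orientation, table):
    """Independent position-loop oracle."""
    length = seg_a[1] - seg_a[0] + 1
    total = 0.0
    for i in range(length):
        a = seq_a[seg_a[0] - 1 + i]
        if orientation == "parallel":
            b = seq_b[seg_b[0] - 1 + i]
        else:
            b = seq_b[seg_b[0] - 1 + (length - 1 - i)]
        total += table.energy(a, b, orientation)
    return total


def oracle_enumerate(seq_a, seq_b, table, min_len):
    """Exhaustive enumeration oracle for short sequences."""
    out = []
    for length in range(min_len, min(len(seq_a), len(seq_b)) + 1):
        for sa in range(1, len(seq_a) - length + 2):
            for sb in range(1, len(seq_b) - length + 2):
                for orientation in ("parallel", "antiparallel"):
                    seg_a = (sa, sa + length - 1)
                    seg_b = (sb, sb + length - 1)
                    out.append(
                        (oracle_score(seq_a, seq_b, seg_a, seg_b, orientation, table),
                         seg_a, seg_b, orientation)
                    )
    return out


class TestScorePairing:
    def test_length_one_segments_single_lookup(self, toy):
        # min_len guards enumeration, but score_pairing itself allows L=1
        assert score_pairing("AC", "AD", (1, 1), (1, 1), "parallel", toy) == toy.energy(
            "A", "A", "parallel"
        )

    def test_constant_table_energy_is_minus_length(self):
        par = {(a, b): -1.0 for a in AA for b in AA}
        anti = dict(par)
        from peptopo.beta_pairing import PairingEnergyTable

        table = PairingEnergyTable(par, anti, source="const")
        assert score_pairing("ACDEF", "GHIKL", (1, 5), (1, 5), "parallel", table) == -5.0
        assert score_pairing("ACDEF", "GHIKL", (2, 4), (3, 5), "antiparallel", table) == -3.0

    def test_unequal_lengths_rejected(self, toy):
        with pytest.raises(PairingError):
            score_pairing("ACDEF", "ACDEF", (1, 3), (1, 4), "parallel", toy)

    def test_out_of_bounds_rejected(self, toy):
        with pytest.raises(PairingError):
            score_pairing("ACDEF", "ACDEF", (3, 7), (1, 5), "parallel", toy)

    @given(
        seq_a=st.text(alphabet=AA, min_size=6, max_size=12),
        seq_b=st.text(alphabet=AA, min_size=6, max_size=12),
        data=st.data(),
    )
    @settings(max_examples=60)
    def test_matches_bruteforce_oracle(self, toy, seq_a, seq_b, data):
        length = data.draw(st.integers(2, min(len(seq_a), len(seq_b))))
        sa = data.draw(st.integers(1, len(seq_a) - length + 1))
        sb = data.draw(st.integers(1, len(seq_b) - length + 1))
        orientation = data.draw(st.sampled_from(["parallel", "antiparallel"]))
        seg_a, seg_b = (sa, sa + length - 1), (sb, sb + length - 1)
        assert score_pairing(seq_a, seq_b, seg_a, seg_b, orientation, toy) == pytest.approx(
            oracle_score(seq_a, seq_b, seg_a, seg_b, orientation, toy)
        )

    @given(
        seq=st.text(alphabet=AA, min_size=6, max_size=10),
        data=st.data(),
    )
    @settings(max_examples=40)
    def test_antiparallel_swap_invariance(self, toy, seq, data):
        length = data.draw(st.integers(2, len(seq)))
        sa = data.draw(st.integers(1, len(seq) - length + 1))
        sb = data.draw(st.integers(1, len(seq) - length + 1))
        seg_a, seg_b = (sa, sa + length - 1), (sb, sb + length - 1)
        e1 = score_pairing(seq, seq, seg_a, seg_b, "antiparallel", toy)
        e2 = score_pairing(seq, seq, seg_b, seg_a, "antiparallel", toy)
        assert e1 == pytest.approx(e2)


class TestEnumeratePairings:
    def test_self_pairing_best_is_parallel_in_register(self, toy):
        # [DERIVED] exhaustive oracle on a 10-mer with an identity-favoring table:
        # the global minimum is the full-length parallel in-register pairing.
        seq = "ACDEFGHIKL"
        ranked = enumerate_pairings(seq, seq, toy, min_len=2, max_results=5)
        best = ranked[0]
        assert best.orientation == "parallel"
        assert best.register == 0
        assert best.segment_a == best.segment_b == (1, 10)
        assert best.energy == pytest.approx(-10.0)

    def test_max_results_one_returns_global_minimum(self, toy):
        seq = "ACDEFGHIKL"
        full = enumerate_pairings(seq, seq, toy, min_len=2, max_results=10_000)
        top1 = enumerate_pairings(seq, seq, toy, min_len=2, max_results=1)
        assert top1 == full[:1]

    def test_short_inputs_empty(self, toy):
        assert enumerate_pairings("AC", "GH", toy, min_len=3) == []

    def test_sorted_and_complete_vs_oracle(self, toy):
        seq_a, seq_b = "ACDEFGHIK", "LMNPQRST"
        ranked = enumerate_pairings(seq_a, seq_b, toy, min_len=3, max_results=10**6)
        oracle = oracle_enumerate(seq_a, seq_b, toy, min_len=3)
        assert len(ranked) == len(oracle)
        energies = [r.energy for r in ranked]
        assert energies == sorted(energies)
        assert energies == pytest.approx(sorted(e for e, *_ in oracle))

    @given(
        seq_a=st.text(alphabet=AA, min_size=4, max_size=12),
        seq_b=st.text(alphabet=AA, min_size=4, max_size=12),
    )
    @settings(max_examples=15, deadline=None)
    def test_property_matches_exhaustive(self, toy, seq_a, seq_b):
        ranked = enumerate_pairings(seq_a, seq_b, toy, min_len=3, max_results=10**6)
        oracle = sorted(e for e, *_ in oracle_enumerate(seq_a, seq_b, toy, 3))
        assert [r.energy for r in ranked] == pytest.approx(oracle)


class TestClassifyAmyloid:
    def test_paper_energies(self):
        # [PAPER] -29.2 is amyloid-like at the -29.0 threshold; -22.2 is not.
        assert classify_amyloid(-29.2) is True
        assert classify_amyloid(-22.2) is False

    def test_boundary_strict(self):
        assert classify_amyloid(-29.0) is False

    def test_custom_threshold(self):
        assert classify_amyloid(-10.0, threshold=-5.0) is True


class TestAggregationProfile:
    def test_homopolymer_flat_interior(self, toy):
        profile = aggregation_profile("LLLLLLLLLL", toy, min_len=4, max_results=50)
        interior = profile[2:-2]
        assert all(v == interior[0] for v in interior)
        assert all(v <= 0 for v in profile)

    def test_short_sequence_all_zero(self, toy):
        assert aggregation_profile("ACD", toy, min_len=4) == [0.0, 0.0, 0.0]

    def test_matches_exhaustive_recomputation(self, toy):
        # [DERIVED] brute-force recomputation on a 12-mer
        seq = "ACDEFGHIKLMN"
        top = enumerate_pairings(seq, seq, toy, min_len=4, max_results=100)
        expected = [0.0] * len(seq)
        seen = [False] * len(seq)
        for r in top:
            for pos in range(r.segment_a[0] - 1, r.segment_a[1]):
                if not seen[pos] or r.energy < expected[pos]:
                    expected[pos] = r.energy
                    seen[pos] = True
        assert aggregation_profile(seq, toy, min_len=4, max_results=100) == pytest.approx(
            expected
        )


class TestTableIO:
    def test_round_trip(self, toy, tmp_path):
        path = tmp_path / "table.tsv"
        save_table(toy, path)
        back = load_table(path)
        assert back.parallel == toy.parallel
        assert back.antiparallel == toy.antiparallel

    def test_incomplete_table_rejected(self, tmp_path):
        path = tmp_path / "partial.tsv"
        path.write_text(
            "residue_a\tresidue_b\torientation\tenergy\nA\tA\tparallel\t-1.0\n"
        )
        with pytest.raises(PairingError):
            load_table(path)

    def test_asymmetric_antiparallel_rejected(self, toy):
        from peptopo.beta_pairing import PairingEnergyTable

        anti = dict(toy.antiparallel)
        anti[("A", "C")] = -9.0
        with pytest.raises(PairingError):
            PairingEnergyTable(toy.parallel, anti)
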