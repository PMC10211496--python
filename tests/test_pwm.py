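import numpy as np
import pytest

from trpwm.pwm import (
    DINUC_LABELS,
    CompositionProfile,
    PositionWeightMatrix,
    crossover,
    dinucleotide_index,
    frequency_matrix,
    mutate_pwm,
    normalize_pwm,
    random_pwm,
)
from trpwm.seqio import DnaSequence


class TestDinucleotideIndex:
    def test_bijection_matches_label_order(self):
        # brute force over all 16 pairs against the column label order
        seen = {}
        bases = "ATCG"  # code order 1..4
        for cur in range(1, 5):
            for prev in range(1, 5):
                idx = dinucleotide_index(prev, cur)
                assert DINUC_LABELS[idx - 1] == bases[prev - 1] + bases[cur - 1]
                seen[idx] = (prev, cur)
        assert sorted(seen) == list(range(1, 17))

    @pytest.mark.parametrize("prev,cur,expected", [(1, 2, 5), (1, 1, 1), (4, 4, 16)])
    def test_known_pairs(self, prev, cur, expected):
        # (A,T) lands in the 5th column "AT"; (A,A) and (G,G) bracket the range
        assert dinucleotide_index(prev, cur) == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            dinucleotide_index(0, 3)
        with pytest.raises(ValueError):
            dinucleotide_index(2, 5)


def uprof(n, K=4):
    import numpy as np
    from trpwm.pwm import CompositionProfile
    return CompositionProfile(p1=np.full(n, 1.0 / n), p2=np.full(K, 1.0 / K))


def _sums(w, prof):
    bg = np.outer(prof.p1, prof.p2)
    return float((w * bg).sum()), float((w**2).sum())


class TestNormalization:
    def test_shared_constants_across_matrices(self, rng):
        seq = DnaSequence("s", "".join(rng.choice(list("ACGT"), 600)))
        for n, K, mode in [(7, 16, "di"), (5, 4, "mono")]:
            prof = CompositionProfile.from_sequence(seq, n, mode)
            sums = [_sums(random_pwm(n, K, s, prof).w, prof) for s in range(5)]
            for s1, s2 in sums:
                assert s1 == pytest.approx(0.0, abs=1e-10)
                assert s2 == pytest.approx(n * K, rel=1e-12)

    def test_idempotent(self, rng):
        m = random_pwm(4, 4, 3, uprof(4))
        again = normalize_pwm(m, uprof(4))
        np.testing.assert_allclose(again.w, m.w, atol=1e-12)

    def test_degenerate_matrix_rejected(self):
        m = PositionWeightMatrix(w=np.zeros((4, 4)), mode="mono")
        with pytest.raises(ValueError, match="degenerate"):
            normalize_pwm(m, uprof(4))

    def test_invariant_under_relabeling(self):
        # permuting rows+columns before normalising == permuting after
        m = random_pwm(4, 4, 9, uprof(4))
        perm_r, perm_c = [2, 0, 3, 1], [1, 3, 0, 2]
        permuted = PositionWeightMatrix(w=m.w[perm_r][:, perm_c], mode="mono")
        out = normalize_pwm(permuted, uprof(4))
        np.testing.assert_allclose(out.w, m.w[perm_r][:, perm_c], atol=1e-12)


class TestRandomPwm:
    def test_deterministic(self):
        a = random_pwm(7, 16, 1)
        b = random_pwm(7, 16, 1)
        np.testing.assert_array_equal(a.w, b.w)

    def test_shapes_and_mode(self):
        assert random_pwm(2, 4, 0).w.shape == (2, 4)
        assert random_pwm(7, 16, 0).mode == "di"

    def test_rejects_period_one(self):
        with pytest.raises(ValueError):
            random_pwm(1, 4, 0)


class TestGaOperators:
    def test_mutation_changes_at_most_one_cell(self):
        m = random_pwm(5, 4, 2, uprof(5))
        mut = mutate_pwm(m, seed=11, prof=uprof(5), renormalize=False)
        assert (mut.w != m.w).sum() <= 1

    def test_mutation_deterministic_and_normalized(self):
        m = random_pwm(5, 4, 2, uprof(5))
        a = mutate_pwm(m, seed=11, prof=uprof(5))
        b = mutate_pwm(m, seed=11, prof=uprof(5))
        np.testing.assert_array_equal(a.w, b.w)
        s1, s2 = _sums(a.w, uprof(5))
        assert s1 == pytest.approx(0.0, abs=1e-10)
        assert s2 == pytest.approx(20.0, rel=1e-12)

    def test_crossover_cells_come_from_parents(self):
        p1 = random_pwm(5, 4, 3, uprof(5))
        p2 = random_pwm(5, 4, 4, uprof(5))
        child = crossover(p1, p2, seed=5, renormalize=False)
        from_either = (child.w == p1.w) | (child.w == p2.w)
        assert from_either.all()

    def test_crossover_identical_parents_is_identity(self):
        p = random_pwm(5, 4, 3, uprof(5))
        child = crossover(p, p, seed=5, renormalize=False)
        np.testing.assert_array_equal(child.w, p.w)

    def test_crossover_dimension_mismatch(self):
        with pytest.raises(ValueError):
            crossover(random_pwm(4, 4, 0), random_pwm(5, 4, 0), seed=1)


class TestFrequencyMatrix:
    def _block_seq_and_phase(self, rng, L=1200):
        blocks = ["ATCG", "TAGC", "CCAA", "GGTT"]
        picks = rng.integers(4, size=L // 4)
        seq = DnaSequence("s", "".join(blocks[i] for i in picks))
        phase = np.tile([1, 2, 3, 4], L // 4)
        return seq, phase

    def test_block_sequence_mono_matrix_even(self, rng):
        # every base appears equally often at every phase, so M(4,4) is flat
        seq, phase = self._block_seq_and_phase(rng)
        fm = frequency_matrix(seq, phase, 4, "mono")
        expected = len(seq) / 16
        assert np.all(np.abs(fm.counts - expected) <= 0.25 * expected)

    def test_block_sequence_di_matrix_uneven_with_zeros(self, rng):
        seq, phase = self._block_seq_and_phase(rng)
        fm = frequency_matrix(seq, phase, 4, "di")
        assert (fm.counts == 0).sum() > 16  # many impossible pairs
        assert fm.counts.max() > 3 * fm.counts.mean()

    def test_di_total_is_L_minus_1(self, rng):
        seq, phase = self._block_seq_and_phase(rng, L=400)
        fm = frequency_matrix(seq, phase, 4, "di")
        assert fm.counts.sum() == len(seq) - 1

    def test_phase_out_of_range_rejected(self):
        seq = DnaSequence("s", "ACGT")
        with pytest.raises(ValueError):
            frequency_matrix(seq, [1, 2, 5, 1], 4, "mono")


def test_matrix_tsv_roundtrip():
    m = random_pwm(3, 4, 8, uprof(3))
    back = PositionWeightMatrix.from_tsv(m.to_tsv())
    np.testing.assert_array_equal(back.w, m.w)
    assert back.mode == "mono"


def test_format_table_has_labels_and_one_decimal():
    m = random_pwm(2, 16, 0)
    text = m.format_table()
    assert "AA" in text and "GG" in text
    assert len(text.splitlines()) == 3
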