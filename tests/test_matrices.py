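"""Matrix parsing, construction, log-odds conversion and strand transforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifmodules import (BackgroundModel, JasparParseError, MatrixError,
                          MotifCountMatrix, build_pfm_from_sequences,
                          parse_jaspar, pfm_to_pwm, reverse_complement_matrix,
                          write_jaspar)


class TestParseJaspar:
    def test_single_record_maps_fields(self, jaspar_one_text):
        (m,) = parse_jaspar(jaspar_one_text)
        assert m.matrix_id == "MA0001.1"
        assert m.name == "TEST"
        assert m.length == 3
        assert m.source == "jaspar_file"
        np.testing.assert_array_equal(
            m.counts, [[4, 0, 0, 0], [0, 4, 0, 0], [0, 0, 4, 0]]
        )

    def test_two_records_preserve_order(self, jaspar_two_text):
        ms = parse_jaspar(jaspar_two_text)
        assert [m.matrix_id for m in ms] == ["MA0001.1", "MA0002.1"]

    @pytest.mark.parametrize("mutation, needle", [
        # T row shorter than the others
        ("T [ 0 0 ]", "MA0001.1"),
        # negative count
        ("T [ 0 -1 0 ]", "MA0001.1"),
        # non-numeric count
        ("T [ 0 x 0 ]", "MA0001.1"),
    ])
    def test_malformed_record_names_offender(self, jaspar_one_text, mutation, needle):
        bad = jaspar_one_text.replace("T [ 0 0 0 ]", mutation)
        with pytest.raises(JasparParseError, match=needle):
            parse_jaspar(bad)

    def test_counts_before_header_rejected(self):
        with pytest.raises(JasparParseError):
            parse_jaspar("A [ 1 2 ]\n")

    def test_empty_input_rejected(self):
        with pytest.raises(JasparParseError):
            parse_jaspar("\n\n")

    def test_unnormalized_columns_accepted(self):
        # JASPAR distributes matrices whose column sums differ per position
        text = ">MA0999.1 UNEVEN\nA [ 10 1 ]\nC [ 0 1 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        (m,) = parse_jaspar(text)
        assert m.counts.sum(axis=1).tolist() == [10, 2]


class TestWriteJaspar:
    def test_round_trip_is_identity(self, jaspar_two_text):
        first = parse_jaspar(jaspar_two_text)
        second = parse_jaspar(write_jaspar(first))
        assert len(first) == len(second)
        for a, b in zip(first, second):
            assert a.matrix_id == b.matrix_id and a.name == b.name
            np.testing.assert_array_equal(a.counts, b.counts)

    def test_round_trip_preserves_fractional_counts(self):
        m = build_pfm_from_sequences(["AR", "CN"], "FRAC")
        (back,) = parse_jaspar(write_jaspar([m]))
        np.testing.assert_allclose(back.counts, m.counts, rtol=0, atol=0)


class TestBuildPfm:
    def test_counting_over_two_sequences(self):
        m = build_pfm_from_sequences(["AATAAA", "ATTAAA"], "P")
        assert m.source == "user_consensus"
        # position 2 splits A/T; the rest of the A positions carry 2
        np.testing.assert_array_equal(m.counts[1], [1, 0, 0, 1])
        for i in (0, 3, 4, 5):
            np.testing.assert_array_equal(m.counts[i], [2, 0, 0, 0])

    def test_single_sequence_identity_pfm(self):
        m = build_pfm_from_sequences(["ACGT"], "I")
        np.testing.assert_array_equal(m.counts, np.eye(4))

    def test_iupac_degenerate_code_splits_fractionally(self):
        m = build_pfm_from_sequences(["AR"], "R")
        np.testing.assert_array_equal(m.counts[0], [1, 0, 0, 0])
        np.testing.assert_array_equal(m.counts[1], [0.5, 0, 0.5, 0])

    def test_uracil_counts_as_thymine(self):
        m = build_pfm_from_sequences(["AU"], "U")
        np.testing.assert_array_equal(m.counts[1], [0, 0, 0, 1])

    @pytest.mark.parametrize("seqs", [[], ["AC", "A"], ["AX"]])
    def test_invalid_input_rejected(self, seqs):
        with pytest.raises(MatrixError):
            build_pfm_from_sequences(seqs, "BAD")


class TestPfmToPwm:
    def test_conserved_base_scores_two_without_pseudocount(self):
        pwm = pfm_to_pwm(build_pfm_from_sequences(["ACGT"], "I"),
                         BackgroundModel(pseudocount=0.0))
        for i in range(4):
            assert pwm.weights[i, i] == 2.0
            off = np.delete(pwm.weights[i], i)
            assert np.all(np.isneginf(off))
        assert pwm.lm == 8.0

    def test_background_equal_counts_score_zero(self):
        pfm = MotifCountMatrix("E", "E", np.array([[5.0, 5.0, 5.0, 5.0]]))
        pwm = pfm_to_pwm(pfm, BackgroundModel(pseudocount=0.0))
        np.testing.assert_array_equal(pwm.weights, [[0, 0, 0, 0]])

    def test_hand_computed_weight_table(self):
        """Frozen values from an independent per-cell evaluation of
        log2(((n+p*bg)/(N+p))/bg) for AATAAA/ATTAAA/TATAAA, p=1, uniform bg."""
        pwm = pfm_to_pwm(build_pfm_from_sequences(
            ["AATAAA", "ATTAAA", "TATAAA"], "PA"), BackgroundModel(pseudocount=1.0))
        wA2 = 1.1699250014423124   # log2(2.25): 2 of 3 observations
        wT1 = 0.32192809488736235  # log2(1.25): 1 of 3
        w3 = 1.7004397181410922    # log2(3.25): 3 of 3
        expected = np.array([
            [wA2, -2.0, -2.0, wT1],
            [wA2, -2.0, -2.0, wT1],
            [-2.0, -2.0, -2.0, w3],
            [w3, -2.0, -2.0, -2.0],
            [w3, -2.0, -2.0, -2.0],
            [w3, -2.0, -2.0, -2.0],
        ])
        np.testing.assert_allclose(pwm.weights, expected, rtol=0, atol=1e-12)
        assert pwm.lm == pytest.approx(9.141608875448995, abs=1e-12)

    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 10.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_positive_pseudocount_bounds_weights(self, seed, pc):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(rng.integers(1, 15), 4)).astype(float)
        counts[:, 0] += 1  # no all-zero columns
        pwm = pfm_to_pwm(MotifCountMatrix("H", "H", counts),
                         BackgroundModel(pseudocount=pc))
        assert np.all(np.isfinite(pwm.weights))
        assert np.all(pwm.weights <= 2.0 + 1e-12)  # log2(1/0.25) with uniform bg
        assert pwm.lm == pytest.approx(pwm.weights.max(axis=1).sum())

    def test_nonuniform_background_bound(self):
        bg = BackgroundModel(freq=(0.4, 0.1, 0.1, 0.4), pseudocount=0.5)
        pwm = pfm_to_pwm(build_pfm_from_sequences(["CC", "CG"], "GC"), bg)
        assert np.all(pwm.weights <= math.log2(1 / 0.1) + 1e-12)


class TestReverseComplement:
    def test_consensus_flips(self):
        pwm = pfm_to_pwm(build_pfm_from_sequences(["AATAAA"], "PA"))
        assert pwm.consensus == "AATAAA"
        assert reverse_complement_matrix(pwm).consensus == "TTTATT"

    def test_involution_bitwise(self, rng):
        counts = rng.integers(1, 30, size=(9, 4)).astype(float)
        pwm = pfm_to_pwm(MotifCountMatrix("R", "R", counts))
        back = reverse_complement_matrix(reverse_complement_matrix(pwm))
        np.testing.assert_array_equal(back.weights, pwm.weights)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_lm_invariant(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 30, size=(rng.integers(1, 12), 4)).astype(float)
        pwm = pfm_to_pwm(MotifCountMatrix("R", "R", counts))
        rc = reverse_complement_matrix(pwm)
        assert rc.lm == pwm.lm
        assert rc.weights.max(axis=1).sum() == pytest.approx(pwm.lm)


class TestValidation:
    def test_all_zero_column_rejected(self):
        with pytest.raises(MatrixError):
            MotifCountMatrix("Z", "Z", np.array([[0.0, 0.0, 0.0, 0.0]]))

    def test_background_must_sum_to_one(self):
        with pytest.raises(MatrixError):
            BackgroundModel(freq=(0.3, 0.3, 0.3, 0.3))

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(MatrixError):
            BackgroundModel(pseudocount=-1.0)
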