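"""Binomial correction terms and the single-pass transforms."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import nacorr as nc
from nacorr.correction import _weight_matrix

NA = 0.01109


def sig3(x: float) -> float:
    return float(f"{x:.3g}")


class TestBinomialTerm:
    # every published cell of the four-carbon worked example, 3 sig figs
    @pytest.mark.parametrize(
        "n, k, expected",
        [
            (0, 1, 4.29e-2),
            (0, 2, 7.22e-4),
            (0, 3, 5.40e-6),
            (0, 4, 1.51e-8),
            (1, 2, 3.25e-2),
            (1, 3, 3.65e-4),
            (1, 4, 1.36e-6),
            (2, 3, 2.19e-2),
            (2, 4, 1.23e-4),
            (3, 4, 1.11e-2),
        ],
    )
    def test_four_carbon_cells(self, n, k, expected):
        assert sig3(nc.binomial_term(n, k, 4, NA)) == pytest.approx(expected)

    def test_no_abundance_means_no_redistribution(self):
        assert nc.binomial_term(3, 3, 7, 0.0) == 1.0
        assert nc.binomial_term(1, 4, 7, 0.0) == 0.0

    @pytest.mark.parametrize(
        "n, k, m, na",
        [(-1, 0, 4, NA), (2, 1, 4, NA), (0, 5, 4, NA), (0, 0, 4, 1.0), (0, 0, 4, -0.1)],
    )
    def test_out_of_range_rejected(self, n, k, m, na):
        with pytest.raises(nc.CorrectionError):
            nc.binomial_term(n, k, m, na)


class TestLossFractionSum:
    @pytest.mark.parametrize(
        "n, expected", [(0, 4.36e-2), (1, 3.29e-2), (2, 2.21e-2), (3, 1.11e-2)]
    )
    def test_four_carbon_sums(self, n, expected):
        assert sig3(nc.loss_fraction_sum(n, 4, NA)) == pytest.approx(expected)

    def test_fully_labeled_has_nothing_to_lose(self):
        assert nc.loss_fraction_sum(4, 4, NA) == 0.0
        assert nc.loss_fraction_sum(17, 17, 0.3) == 0.0

    @pytest.mark.parametrize("element_max", [1, 4, 20, 100])
    def test_matches_closed_form(self, element_max):
        for n in range(element_max + 1):
            closed = 1.0 - (1.0 - NA) ** (element_max - n)
            assert nc.loss_fraction_sum(n, element_max, NA) == pytest.approx(
                closed, abs=1e-14
            )

    def test_tapering_strictly_decreasing_in_label_count(self):
        # fewer unlabeled atoms remain as labeling rises, so less leaks out
        sums = [nc.loss_fraction_sum(n, 20, NA) for n in range(21)]
        assert all(a > b for a, b in zip(sums, sums[1:]))


class TestBinomialTable:
    def test_invariants(self):
        table = nc.build_binomial_table(100, NA)
        m = table.element_max
        for n in range(m + 1):
            assert table.terms[n, n] == pytest.approx((1 - NA) ** (m - n), rel=1e-13)
            assert table.loss_sums[n] == pytest.approx(
                1.0 - table.terms[n, n], abs=1e-12
            )
            assert table.terms[n, n:].sum() == pytest.approx(1.0, abs=1e-12)
        assert table.loss_sums[m] == 0.0

    def test_zero_element_molecule(self):
        table = nc.build_binomial_table(0, NA)
        assert table.terms[0, 0] == 1.0
        assert table.loss_sums[0] == 0.0

    def test_double_mode_capability_limit(self):
        nc.build_binomial_table(269, NA)  # at the limit: fine
        with pytest.raises(nc.CapabilityError, match="269"):
            nc.build_binomial_table(270, NA)

    def test_extended_mode_passes_the_double_limit(self):
        table = nc.build_binomial_table(300, NA, "extended")
        assert float(table.terms[0, 0]) == pytest.approx((1 - NA) ** 300, rel=1e-12)

    def test_extended_matches_double_where_both_apply(self):
        d = nc.build_binomial_table(12, NA)
        e = nc.build_binomial_table(12, NA, "extended")
        for n in range(13):
            for k in range(n, 13):
                assert float(e.terms[n, k]) == pytest.approx(d.terms[n, k], rel=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(nc.CorrectionError):
            nc.build_binomial_table(-1, NA)
        with pytest.raises(nc.CorrectionError):
            nc.build_binomial_table(4, 1.2)
        with pytest.raises(nc.CorrectionError):
            nc.build_binomial_table(4, NA, "quad")


class TestSequentialTransforms:
    def test_four_carbon_correction(self, table1_observed, four_carbon_table):
        corrected = nc.correct_sequential(table1_observed, four_carbon_table)
        assert np.round(corrected, 2) == pytest.approx([1.00, 1.00, 0.00, 0.00, 0.00])

    def test_contaminate_of_monoisotopic_delta(self, four_carbon_table):
        # a pure-12C molecule spreads exactly as the n=0 binomial row
        out = nc.contaminate_sequential(np.array([1.0, 0, 0, 0, 0]), four_carbon_table)
        for value, printed in zip(out, (0.9564, 4.29e-2, 7.22e-4, 5.40e-6, 1.51e-8)):
            assert float(f"{value:.3g}") == pytest.approx(printed, rel=1e-3)

    def test_fully_labeled_delta_unchanged(self):
        table = nc.build_binomial_table(20, NA)
        delta = np.zeros(21)
        delta[20] = 1.0
        assert nc.contaminate_sequential(delta, table) == pytest.approx(delta)

    def test_conservation_of_total_intensity(self):
        rng = np.random.default_rng(7)
        table = nc.build_binomial_table(33, NA)
        v = rng.random(34)
        v /= v.sum()
        out = nc.contaminate_sequential(v, table)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch_rejected(self, four_carbon_table):
        with pytest.raises(nc.CorrectionError):
            nc.correct_sequential(np.ones(3), four_carbon_table)
        with pytest.raises(nc.CorrectionError):
            nc.contaminate_sequential(np.ones(3), four_carbon_table)

    def test_missing_entries_rejected(self, four_carbon_table):
        bad = np.array([1.0, np.nan, 0, 0, 0])
        with pytest.raises(nc.CorrectionError, match="missing"):
            nc.correct_sequential(bad, four_carbon_table)

    @given(
        element_max=st.integers(1, 60),
        na=st.sampled_from([0.001, 0.01109, 0.1]),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_inverse_pair_property(self, element_max, na, seed):
        """correct∘contaminate and contaminate∘correct are identities."""
        rng = np.random.default_rng(seed)
        table = nc.build_binomial_table(element_max, na)
        v = rng.uniform(0.1, 1.0, element_max + 1)
        forward_back = nc.correct_sequential(nc.contaminate_sequential(v, table), table)
        assert np.max(np.abs(forward_back - v) / v) <= 1e-12
        back_forward = nc.contaminate_sequential(nc.correct_sequential(v, table), table)
        assert np.max(np.abs(back_forward - v) / v) <= 1e-12

    @given(element_max=st.integers(1, 40), seed=st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_property(self, element_max, seed):
        """Analytic forward model equals explicit binomial convolution."""
        rng = np.random.default_rng(seed)
        v = rng.uniform(0.1, 1.0, element_max + 1)
        table = nc.build_binomial_table(element_max, NA)
        analytic = nc.contaminate_sequential(v, table)
        oracle = nc.brute_force_contaminate(
            v, nc.CorrectionConstants(), {"C": element_max}
        )
        assert np.max(np.abs(analytic - oracle) / oracle) <= 1e-12

    def test_roundtrip_error_does_not_grow_with_size(self):
        rng = np.random.default_rng(11)
        errors = {}
        for element_max in (10, 100, 269):
            table = nc.build_binomial_table(element_max, NA)
            v = np.zeros(element_max + 1)
            v[rng.choice(element_max + 1, 3, replace=False)] = 1 / 3
            back = nc.correct_sequential(nc.contaminate_sequential(v, table), table)
            nz = v > 0
            errors[element_max] = np.max(np.abs(back[nz] - v[nz]) / v[nz])
        assert all(err <= 1e-12 for err in errors.values())


class TestDualTransforms:
    def make_tables(self, c_max=3, n_max=2):
        return (
            nc.build_binomial_table(c_max, NA),
            nc.build_binomial_table(n_max, nc.NA_15N_IUPAC),
        )

    def test_round_trip_identity(self):
        tc, tn = self.make_tables()
        rng = np.random.default_rng(3)
        m = rng.uniform(0.1, 1.0, (4, 3))
        back = nc.correct_dual(nc.contaminate_dual(m, tc, tn), tc, tn)
        assert np.max(np.abs(back - m) / m) <= 1e-12

    def test_monoisotopic_delta_round_trip(self):
        tc = nc.build_binomial_table(2, NA)
        tn = nc.build_binomial_table(1, nc.NA_15N_IUPAC)
        delta = np.zeros((3, 2))
        delta[0, 0] = 1.0
        back = nc.correct_dual(nc.contaminate_dual(delta, tc, tn), tc, tn)
        assert back == pytest.approx(delta, abs=1e-12)

    def test_single_atom_factorization(self):
        na_c, na_n = NA, nc.NA_15N_IUPAC
        tc = nc.build_binomial_table(1, na_c)
        tn = nc.build_binomial_table(1, na_n)
        delta = np.zeros((2, 2))
        delta[0, 0] = 1.0
        out = nc.contaminate_dual(delta, tc, tn)
        expected = np.array(
            [
                [(1 - na_c) * (1 - na_n), (1 - na_c) * na_n],
                [na_c * (1 - na_n), na_c * na_n],
            ]
        )
        assert out == pytest.approx(expected, rel=1e-12)

    def test_fully_labeled_cell_unchanged(self):
        tc, tn = self.make_tables()
        delta = np.zeros((4, 3))
        delta[3, 2] = 1.0
        assert nc.contaminate_dual(delta, tc, tn) == pytest.approx(delta)

    def test_degenerate_nitrogen_reduces_to_sequential(self):
        tc = nc.build_binomial_table(5, NA)
        tn = nc.build_binomial_table(0, nc.NA_15N_IUPAC)
        v = np.random.default_rng(4).uniform(0.1, 1.0, 6)
        dual = nc.correct_dual(v[:, None], tc, tn)[:, 0]
        single = nc.correct_sequential(v, tc)
        assert dual == pytest.approx(single, rel=1e-13)

    def test_separability_rows_then_columns(self):
        # independent per-element thinning: the 2-D transform equals the 1-D
        # carbon transform on every column then the nitrogen one on every row
        tc, tn = self.make_tables()
        m = np.random.default_rng(5).uniform(0.1, 1.0, (4, 3))
        expected = np.stack(
            [nc.contaminate_sequential(col, tc) for col in m.T], axis=1
        )
        expected = np.stack(
            [nc.contaminate_sequential(row, tn) for row in expected]
        )
        assert nc.contaminate_dual(m, tc, tn) == pytest.approx(expected, rel=1e-12)

    def test_oracle_equivalence(self):
        tc = nc.build_binomial_table(6, NA)
        tn = nc.build_binomial_table(4, nc.NA_15N_IUPAC)
        m = np.random.default_rng(6).uniform(0.1, 1.0, (7, 5))
        analytic = nc.contaminate_dual(m, tc, tn)
        oracle = nc.brute_force_contaminate(
            m,
            nc.CorrectionConstants(na_15n=nc.NA_15N_IUPAC),
            {"C": 6, "N": 4},
        )
        assert np.max(np.abs(analytic - oracle) / oracle) <= 1e-12

    def test_dimension_mismatch_rejected(self):
        tc, tn = self.make_tables()
        with pytest.raises(nc.CorrectionError):
            nc.correct_dual(np.ones((3, 3)), tc, tn)


class TestConstants:
    def test_defaults(self):
        constants = nc.CorrectionConstants()
        assert constants.na_13c == pytest.approx(0.01109)
        assert constants.na_15n is None

    def test_nitrogen_must_be_explicit(self):
        with pytest.raises(nc.CorrectionError, match="na_15n"):
            nc.CorrectionConstants().require_nitrogen()
        assert (
            nc.CorrectionConstants(na_15n=nc.NA_15N_IUPAC).require_nitrogen()
            == nc.NA_15N_IUPAC
        )

    @pytest.mark.parametrize("bad", [{"na_13c": 0.6}, {"na_13c": -0.1},
                                     {"na_15n": 0.5}, {"precision_mode": "half"}])
    def test_invalid_rejected(self, bad):
        with pytest.raises(nc.CorrectionError):
            nc.CorrectionConstants(**bad)


def test_weight_matrix_rows_sum_to_one():
    table = nc.build_binomial_table(25, NA)
    w = _weight_matrix(table)
    assert w.sum(axis=1) == pytest.approx(np.ones(26), abs=1e-14)
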