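"""Equilibrium algebra: macro/micro transformation, interactivity,
correction factors and Gaussian error propagation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microspec as ms
from microspec.speciation import CooperativityWarning

from printed_values import MODEL_DERIVED, PARENT_DERIVED

LOG2 = math.log10(2.0)

finite = st.floats(min_value=-20, max_value=20, allow_nan=False)
small_se = st.floats(min_value=0, max_value=1, allow_nan=False)


def _macro(lk1, lk2, se1=0.01, se2=0.01, method="nmr"):
    return ms.MacroConstants(
        compound_id="x",
        method=method,
        log_K=(lk1, lk2),
        se_log_K=(se1, se2),
        symmetric=True,
    )


class TestCumulativeBeta:
    @pytest.mark.parametrize(
        "log_K, expected",
        [
            ([5.22, 2.700], [5.22, 7.92]),
            ([9.4], [9.4]),
            ([0.0, 0.0, 0.0], [0.0, 0.0, 0.0]),
        ],
    )
    def test_log_beta_is_running_sum_of_stepwise_constants(
        self, log_K, expected
    ):
        macro = ms.MacroConstants(
            compound_id="x",
            method="nmr",
            log_K=tuple(log_K),
            se_log_K=(0.0,) * len(log_K),
        )
        beta = ms.cumulative_beta(macro)
        assert beta == pytest.approx(expected, abs=1e-12)


class TestSymmetricTransform:
    @pytest.mark.parametrize(
        "lk1, lk2, kf, ks",
        [
            (5.22, 2.700, 4.92, 3.00),  # dicarboxylic, NMR
            (0.60206, 0.0, 0.30103, 0.30103),  # non-interacting sites
            (4.27, 1.28, 3.97, 1.58),  # dicarboxylic, potentiometric
        ],
    )
    def test_micro_from_macro_shifts_by_log2(self, lk1, lk2, kf, ks):
        micro = ms.macro_to_micro_symmetric(_macro(lk1, lk2))
        assert micro.log_k_first == pytest.approx(kf, abs=5e-3)
        assert micro.log_k_second == pytest.approx(ks, abs=5e-3)

    def test_errors_pass_through_the_exact_log2_shift(self):
        micro = ms.macro_to_micro_symmetric(_macro(5.22, 2.700, 0.01, 0.008))
        assert micro.se_first == 0.01
        assert micro.se_second == 0.008

    def test_rejects_non_diprotic_and_non_symmetric(self):
        mono = ms.MacroConstants(
            compound_id="x", method="nmr", log_K=(5.0,), se_log_K=(0.01,)
        )
        with pytest.raises(ValueError, match="2 sites"):
            ms.macro_to_micro_symmetric(mono)
        asym = ms.MacroConstants(
            compound_id="x",
            method="nmr",
            log_K=(5.0, 2.0),
            se_log_K=(0.01, 0.01),
            symmetric=False,
        )
        with pytest.raises(ValueError, match="symmetric"):
            ms.macro_to_micro_symmetric(asym)

    def test_cooperative_input_warns_but_is_accepted(self):
        with pytest.warns(CooperativityWarning):
            micro = ms.macro_to_micro_symmetric(_macro(3.0, 3.0))
        assert micro.log_k_first < micro.log_k_second

    @given(
        lk1=finite, lk2=finite, se1=small_se, se2=small_se
    )
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_is_identity(self, lk1, lk2, se1, se2):
        import warnings

        macro = _macro(lk1, lk2, se1, se2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CooperativityWarning)
            back = ms.micro_to_macro_symmetric(
                ms.macro_to_micro_symmetric(macro)
            )
        assert back.log_K[0] == pytest.approx(lk1, abs=1e-12)
        assert back.log_K[1] == pytest.approx(lk2, abs=1e-12)
        assert back.se_log_K == macro.se_log_K


class TestInteractivity:
    @pytest.mark.parametrize(
        "lk1, lk2, eps",
        [
            (5.22, 2.700, 1.92),  # anticooperative dicarboxylic
            (5.87, 1.93, 3.34),  # strongly interacting (Z)-diacid
        ],
    )
    def test_matches_macroconstant_difference_minus_2log2(self, lk1, lk2, eps):
        micro = ms.macro_to_micro_symmetric(_macro(lk1, lk2))
        assert ms.interactivity(micro).value == pytest.approx(eps, abs=5e-3)

    def test_equal_microconstants_have_zero_interactivity(self):
        micro = ms.macro_to_micro_symmetric(_macro(2 * LOG2, 0.0))
        assert ms.interactivity(micro).value == pytest.approx(0.0, abs=1e-12)

    @given(lk1=finite, lk2=finite)
    @settings(max_examples=200, derandomize=True)
    def test_identity_log_eps_plus_2log2_equals_logK_gap(self, lk1, lk2):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CooperativityWarning)
            micro = ms.macro_to_micro_symmetric(_macro(lk1, lk2))
        eps = ms.interactivity(micro).value
        assert eps + 2 * LOG2 == pytest.approx(lk1 - lk2, abs=1e-9)


class TestCorrectionFactor:
    def test_model_constant_minus_second_microconstant(self):
        micro = ms.macro_to_micro_symmetric(_macro(5.22, 2.700, 0.01, 0.008))
        corr, se = ms.correction_factor(3.530, 0.005, micro)
        assert corr == pytest.approx(0.529, abs=1e-3)
        assert se == pytest.approx(0.00943, abs=1e-4)

    def test_perfect_model_has_zero_correction(self):
        micro = ms.macro_to_micro_symmetric(_macro(5.22, 2.700))
        corr, _ = ms.correction_factor(micro.log_k_second, 0.0, micro)
        assert corr == 0.0

    @given(model=finite, lk1=finite, lk2=finite)
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetric_in_role_swap(self, model, lk1, lk2):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CooperativityWarning)
            micro = ms.macro_to_micro_symmetric(_macro(lk1, lk2))
            swapped = ms.MicroConstants(
                compound_id="x",
                method="nmr",
                log_k_first=micro.log_k_first,
                se_first=0.0,
                log_k_second=model,
                se_second=0.0,
            )
        fwd, _ = ms.correction_factor(model, 0.0, micro)
        rev, _ = ms.correction_factor(micro.log_k_second, 0.0, swapped)
        assert fwd == pytest.approx(-rev, abs=1e-12)


class TestGaussianPropagation:
    @pytest.mark.parametrize(
        "partials, expected",
        [
            ([(1, 0.005), (1, 0.008)], 0.00943),
            ([(1, 0.0), (1, 0.0)], 0.0),
            ([(1, 0.02), (1, 0.03)], 0.036),
        ],
    )
    def test_quadrature_sum(self, partials, expected):
        assert ms.propagate_gaussian(partials) == pytest.approx(
            expected, abs=5e-4
        )

    def test_rejects_negative_se(self):
        with pytest.raises(ValueError):
            ms.propagate_gaussian([(1.0, -0.1)])


class TestPublishedTableReproduction:
    """Every parent and model row of the reference table reproduces its
    printed derived columns from the printed macroconstants."""

    @pytest.mark.parametrize("key", sorted(PARENT_DERIVED))
    def test_parent_derived_columns(self, constants_table, key):
        cid, method = key
        kf, se_kf, ks, se_ks, eps, se_eps, tol_eps = PARENT_DERIVED[key]
        row = constants_table[
            (constants_table["compound_id"] == cid)
            & (constants_table["method"] == method)
            & (constants_table["role"] == "parent")
        ].iloc[0]
        macro = _macro(
            row["log_K1"], row["log_K2"], row["se_K1"], row["se_K2"], method
        )
        micro = ms.macro_to_micro_symmetric(macro)
        assert micro.log_k_first == pytest.approx(kf, abs=0.01)
        assert micro.log_k_second == pytest.approx(ks, abs=0.01)
        assert micro.se_first == pytest.approx(se_kf, abs=0.005)
        assert micro.se_second == pytest.approx(se_ks, abs=0.005)
        got = ms.interactivity(micro)
        assert got.value == pytest.approx(eps, abs=tol_eps)
        assert got.se == pytest.approx(se_eps, abs=0.005)

    @pytest.mark.parametrize("key", sorted(MODEL_DERIVED))
    def test_model_correction_factors(self, correction_records, key):
        model_id, method = key
        corr, se_corr, tol, tol_se = MODEL_DERIVED[key]
        rec = next(
            r
            for r in correction_records
            if r.model_id == model_id and r.method == method
        )
        assert rec.correction == pytest.approx(corr, abs=tol)
        assert rec.se_correction == pytest.approx(se_corr, abs=tol_se)

    def test_record_census_by_model_type(self, correction_records):
        counts = {}
        for rec in correction_records:
            counts[rec.model_type] = counts.get(rec.model_type, 0) + 1
        assert counts == {"O_methyl": 16, "amide": 7, "S_methyl": 3}
        # propagated error always dominates each input error
        for rec in correction_records:
            assert rec.se_correction >= rec.se_model
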