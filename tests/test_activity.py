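"""Activity semantics: L thresholds, the AND/OR/XOR formula language, and
cell-wise matrix combination, plus their monotonicity properties."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from kpminer import (
    CaseExceptionSpec,
    FormulaError,
    cellwise_combine,
    count_inactive_cases,
    evaluate_formula,
    matrix_activity,
    parse_formula,
    resolve_case_exceptions,
)

from .conftest import matrix_of


class TestResolveCaseExceptions:
    @pytest.mark.parametrize(
        "percent,n_cases,expected",
        [
            (25, 155, 39),  # 25% of the expression cohort
            (25, 291, 73),  # 25% of the methylation cohort
            (0, 7, 0),
            (100, 7, 7),
            (50, 3, 2),  # ceil(1.5)
        ],
    )
    def test_percent_uses_ceiling(self, percent, n_cases, expected):
        spec = CaseExceptionSpec("percent", percent)
        assert resolve_case_exceptions(spec, n_cases) == expected

    def test_absolute_passes_through(self):
        assert resolve_case_exceptions(CaseExceptionSpec("absolute", 5), 10) == 5

    def test_absolute_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="kpminer"):
            assert resolve_case_exceptions(CaseExceptionSpec("absolute", 5), 3) == 3
        assert "clamping" in caplog.text

    @pytest.mark.parametrize("mode,value", [("percent", 101), ("percent", -1), ("absolute", -2)])
    def test_invalid_spec_rejected(self, mode, value):
        with pytest.raises(ValueError):
            CaseExceptionSpec(mode, value)

    @pytest.mark.parametrize("text,mode,value", [("39", "absolute", 39), ("25%", "percent", 25.0)])
    def test_parse_spec_strings(self, text, mode, value):
        spec = CaseExceptionSpec.parse(text)
        assert (spec.mode, spec.value) == (mode, value)

    @given(
        p=st.integers(0, 100), p2=st.integers(0, 100),
        n=st.integers(1, 400), n2=st.integers(1, 400),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_percent_and_cases(self, p, p2, n, n2):
        lo_p, hi_p = sorted((p, p2))
        lo_n, hi_n = sorted((n, n2))
        base = resolve_case_exceptions(CaseExceptionSpec("percent", lo_p), lo_n)
        assert resolve_case_exceptions(CaseExceptionSpec("percent", hi_p), lo_n) >= base
        assert resolve_case_exceptions(CaseExceptionSpec("percent", lo_p), hi_n) >= base


class TestMatrixActivity:
    def test_count_inactive_cases(self):
        assert count_inactive_cases(matrix_of({"g": [1, 0, 1, 0]}), "g") == 2
        assert count_inactive_cases(matrix_of({"g": [1, 1, 1]}), "g") == 0

    def test_absent_gene_counts_all_cases_inactive(self):
        m = matrix_of({"g1": [1] * 7})
        assert count_inactive_cases(m, "ghost") == 7

    def test_threshold_splits_genes(self):
        m = matrix_of({"g1": [1, 0, 1], "g2": [0, 0, 1]})
        act = matrix_activity(m, 1, ["g1", "g2"])
        assert act == {"g1": True, "g2": False}

    def test_vacuous_threshold_activates_everything(self):
        m = matrix_of({"g1": [0, 0, 0], "g2": [1, 0, 1]})
        assert all(matrix_activity(m, 3, ["g1", "g2", "ghost"]).values())

    def test_zero_threshold_requires_all_ones(self):
        m = matrix_of({"g1": [1, 1, 1], "g2": [1, 0, 1]})
        assert matrix_activity(m, 0, ["g1", "g2"]) == {"g1": True, "g2": False}

    def test_l_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            matrix_activity(matrix_of({"g": [1, 0]}), 3, ["g"])

    @given(st.data())
    @settings(max_examples=60, derandomize=True)
    def test_active_set_monotone_in_l(self, data):
        n_cases = data.draw(st.integers(1, 6))
        rows = data.draw(
            st.dictionaries(
                st.sampled_from([f"g{i}" for i in range(5)]),
                st.lists(st.integers(0, 1), min_size=n_cases, max_size=n_cases),
                min_size=1,
            )
        )
        m = matrix_of(rows)
        l_lo = data.draw(st.integers(0, n_cases))
        l_hi = data.draw(st.integers(l_lo, n_cases))
        genes = list(rows)
        lo = {g for g, a in matrix_activity(m, l_lo, genes).items() if a}
        hi = {g for g, a in matrix_activity(m, l_hi, genes).items() if a}
        assert lo <= hi


class TestFormulaParsing:
    def test_unparenthesized_chain_associates_left(self):
        f = parse_formula("M1 AND M2 OR M3")
        assert str(f) == "((M1 AND M2) OR M3)"

    def test_parentheses_override(self):
        f = parse_formula("M1 AND (M2 OR M3)")
        assert str(f) == "(M1 AND (M2 OR M3))"

    def test_operators_case_insensitive(self):
        assert str(parse_formula("M1 and M2 xOr M3")) == "((M1 AND M2) XOR M3)"

    @pytest.mark.parametrize(
        "text,match",
        [
            ("(M1", "unbalanced parentheses"),
            ("M1 AND M2)", "unbalanced parentheses"),
            ("M1 AND", "ends unexpectedly"),
            ("AND M1", "expected matrix name"),
            ("M1 M2", "expected AND/OR/XOR"),
            ("", "empty formula"),
        ],
    )
    def test_parse_errors_with_position(self, text, match):
        with pytest.raises(FormulaError, match=match):
            parse_formula(text)

    def test_unknown_matrix_name_rejected(self):
        with pytest.raises(FormulaError, match="unknown matrix"):
            parse_formula("M1 AND M9", {"M1", "M2"})

    def test_unused_matrix_rejected(self):
        with pytest.raises(FormulaError, match="never appears"):
            parse_formula("M1", {"M1", "M2"})


class TestFormulaEvaluation:
    @pytest.mark.parametrize(
        "expr,values,expected",
        [
            ("M1 AND M2", (True, False), False),
            ("M1 OR M2", (True, False), True),
            ("M1 XOR M2", (True, False), True),
            ("M1 XOR M2", (True, True), False),
        ],
    )
    def test_binary_truth_tables(self, expr, values, expected):
        f = parse_formula(expr)
        assert f.evaluate({"M1": values[0], "M2": values[1]}) is expected

    def test_four_matrix_case_study_shape(self):
        # pairing aberrant expression with aberrant methylation
        f = parse_formula("(M1 AND M2) OR (M3 AND M4)")
        assert f.evaluate({"M1": True, "M2": True, "M3": False, "M4": False}) is True
        assert f.evaluate({"M1": True, "M2": False, "M3": False, "M4": True}) is False

    def test_xor_chain_folds_left(self):
        f = parse_formula("M1 XOR M2 XOR M1")
        assert f.evaluate({"M1": True, "M2": True}) is True  # (T xor T)=F, F xor T = T

    def test_single_leaf_equals_matrix_activity(self):
        m = matrix_of({"g1": [1, 0, 1], "g2": [0, 0, 1]})
        lits = {"M1": matrix_activity(m, 1, ["g1", "g2"])}
        prof = evaluate_formula(parse_formula("M1"), lits, ["g1", "g2"])
        assert prof.active == lits["M1"]

    def test_missing_literal_rejected(self):
        with pytest.raises(FormulaError, match="no literals"):
            evaluate_formula(parse_formula("M1 AND M2"), {"M1": {"g": True}}, ["g"])

    def test_raising_l_can_deactivate_under_xor(self):
        # XOR breaks monotonicity: activating the second literal flips a gene off
        m1 = matrix_of({"g": [1, 1]}, "M1")
        m2 = matrix_of({"g": [1, 0]}, "M2")
        f = parse_formula("M1 XOR M2")

        def active(l2):
            lits = {
                "M1": matrix_activity(m1, 0, ["g"]),
                "M2": matrix_activity(m2, l2, ["g"]),
            }
            return evaluate_formula(f, lits, ["g"]).active["g"]

        assert active(0) is True and active(1) is False


class TestCellwiseCombine:
    def test_or_merges_activity(self):
        m1 = matrix_of({"g": [1, 0]}, "M1")
        m2 = matrix_of({"g": [0, 0]}, "M2")
        mc = cellwise_combine(m1, m2, "OR")
        assert mc.values.loc["g"].tolist() == [1, 0]

    def test_and_with_itself_is_identity(self):
        m = matrix_of({"g1": [1, 0, 1], "g2": [0, 1, 1]})
        assert (cellwise_combine(m, m, "AND").values.values == m.values.values).all()

    def test_xor_with_itself_is_zero(self):
        m = matrix_of({"g1": [1, 0, 1]})
        assert (cellwise_combine(m, m, "XOR").values.values == 0).all()

    def test_absent_gene_rows_are_zero(self):
        m1 = matrix_of({"g1": [1, 1]}, "M1")
        m2 = matrix_of({"g2": [1, 1]}, "M2")
        mc = cellwise_combine(m1, m2, "AND")
        assert mc.values.loc["g1"].tolist() == [0, 0]
        assert sorted(mc.genes) == ["g1", "g2"]

    def test_differing_cohorts_rejected(self):
        m1 = matrix_of({"g": [1, 0]}, "M1")
        m2 = matrix_of({"g": [1, 0, 1]}, "M2")
        with pytest.raises(ValueError, match="case lists differ"):
            cellwise_combine(m1, m2, "OR")

    def test_and_formula_agrees_with_cellwise_and_at_l0(self):
        # at L=0 both routes demand all-ones rows in both matrices, so the
        # formula pathway and the cell-wise pathway coincide exactly
        m1 = matrix_of({"g1": [1, 1], "g2": [1, 0], "g3": [0, 0]}, "M1")
        m2 = matrix_of({"g1": [1, 1], "g2": [0, 1], "g3": [1, 1]}, "M2")
        genes = ["g1", "g2", "g3"]
        lits = {
            "M1": matrix_activity(m1, 0, genes),
            "M2": matrix_activity(m2, 0, genes),
        }
        via_formula = evaluate_formula(parse_formula("M1 AND M2"), lits, genes).active
        mc = cellwise_combine(m1, m2, "AND")
        via_cellwise = matrix_activity(mc, 0, genes)
        assert via_formula == via_cellwise

    def test_or_cellwise_dominates_or_formula_at_l0(self):
        # OR is one-sided: a gene covered per-case across the two matrices
        # (case 1 by M1, case 2 by M2) is cellwise-OR active at L=0 yet
        # inactive under the formula route, which needs one full row of 1s
        m1 = matrix_of({"g1": [1, 1], "g2": [1, 0], "g3": [0, 0]}, "M1")
        m2 = matrix_of({"g1": [0, 0], "g2": [0, 1], "g3": [1, 1]}, "M2")
        genes = ["g1", "g2", "g3"]
        lits = {
            "M1": matrix_activity(m1, 0, genes),
            "M2": matrix_activity(m2, 0, genes),
        }
        via_formula = evaluate_formula(parse_formula("M1 OR M2"), lits, genes).active
        via_cellwise = matrix_activity(cellwise_combine(m1, m2, "OR"), 0, genes)
        assert all(via_cellwise[g] for g in genes if via_formula[g])
        assert via_formula["g2"] is False and via_cellwise["g2"] is True
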