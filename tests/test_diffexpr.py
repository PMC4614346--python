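import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srnakit.diffexpr import (count_p_value, de_table, fold_change, normalize,
                              replicate_pearson)

from oracles import ac_p_value_exact

# pooled clean-read totals from the printed accounting table
TOTAL_TREATED = 5_804_468 + 5_834_651   # resistant strain
TOTAL_CONTROL = 5_763_509 + 5_840_702   # susceptible strain


class TestNormalize:
    def test_printed_value(self):
        assert normalize(31180, TOTAL_TREATED) == pytest.approx(2678.8969, abs=5e-5)

    def test_printed_value_control(self):
        assert normalize(18929, TOTAL_CONTROL) == pytest.approx(1631.2182, abs=5e-5)

    def test_zero_substitution(self):
        assert normalize(0, 10 ** 6) == 0.01

    def test_identity_scale(self):
        assert normalize(10 ** 6, 10 ** 6) == pytest.approx(10 ** 6)

    def test_invalid_total(self):
        with pytest.raises(ValueError):
            normalize(5, 0)


class TestFoldChange:
    @pytest.mark.parametrize("treated,control,expected", [
        (2678.8969, 0.01, 18.0313),     # zero-substituted, strong up
        (2.5775, 0.01, 8.0098),
        (627.6248, 1631.2182, -1.3780),
        (329.9219, 273.0043, 0.2732),
        (880.1353, 172.3512, 2.3524),
    ])
    def test_printed_rows(self, treated, control, expected):
        assert fold_change(treated, control) == pytest.approx(expected, abs=5e-5)

    def test_strong_down_row_from_counts(self):
        # the printed normalized pair (0.1718, 39.1237) is rounded; the
        # printed fold-change -7.8309 reproduces from the raw counts
        fc = fold_change(normalize(2, TOTAL_TREATED),
                         normalize(454, TOTAL_CONTROL))
        assert fc == pytest.approx(-7.8309, abs=5e-5)

    def test_identity(self):
        assert fold_change(3.14, 3.14) == 0.0

    def test_antisymmetry(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.01, 1e4, size=2)
            assert fold_change(a, b) == pytest.approx(-fold_change(b, a))

    def test_requires_positive(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 1.0)


class TestCountPValue:
    def test_symmetric_case(self):
        assert count_p_value(5, 5, 1e6, 1e6) == 1.0

    def test_against_exact_oracle(self):
        assert count_p_value(0, 8, 10 ** 6, 10 ** 6) == \
            pytest.approx(ac_p_value_exact(0, 8, 10 ** 6, 10 ** 6), rel=1e-10)

    def test_oracle_random_cases(self, rng):
        for _ in range(50):
            x = int(rng.integers(0, 120))
            y = int(rng.integers(0, 120))
            n1 = int(rng.integers(10 ** 5, 2 * 10 ** 6))
            n2 = int(rng.integers(10 ** 5, 2 * 10 ** 6))
            got = count_p_value(x, y, n1, n2)
            want = ac_p_value_exact(x, y, n1, n2)
            assert got == pytest.approx(want, rel=1e-10), (x, y, n1, n2)

    def test_monotone_in_y(self):
        previous = 1.1
        for y in range(1, 51):
            p = count_p_value(0, y, 1e6, 1e6)
            assert p < previous
            previous = p

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            count_p_value(-1, 2, 1e6, 1e6)
        with pytest.raises(ValueError):
            count_p_value(1, 2, 0, 1e6)

    def test_in_unit_interval(self, rng):
        for _ in range(30):
            p = count_p_value(int(rng.integers(0, 500)),
                              int(rng.integers(0, 500)), 1e6, 2e6)
            assert 0 < p <= 1

    def test_type_one_error_null_poisson(self, rng):
        # conservative behavior under the null at alpha = 0.05
        reps = 1000
        means = rng.uniform(5, 500, size=reps)
        false_positives = 0
        for mu in means:
            x, y = rng.poisson(mu, size=2)
            if count_p_value(int(x), int(y), 1e6, 1e6) < 0.05:
                false_positives += 1
        assert false_positives / reps <= 0.07


class TestReplicatePearson:
    def test_identical(self):
        assert replicate_pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_negated(self):
        assert replicate_pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            replicate_pearson([1, 1, 1], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            replicate_pearson([1, 2], [1, 2, 3])


class TestDETable:
    def test_printed_row_reproduced(self):
        counts = {"Ofu-miR-4954-3p": {"t1": 31180, "c1": 0}}
        rows = de_table(counts, TOTAL_TREATED, TOTAL_CONTROL,
                        treated_libs=["t1"], control_libs=["c1"])
        row = rows[0]
        assert row.norm_treated == pytest.approx(2678.8969, abs=5e-5)
        assert row.norm_control == 0.01
        assert row.fold_change == pytest.approx(18.0313, abs=5e-5)
        assert row.significant == (row.p_value < 0.05)

    def test_low_expression_filtered(self):
        # normalized < 1 in all libraries -> excluded
        counts = {"low": {"t1": 2, "c1": 3}}
        rows = de_table(counts, TOTAL_TREATED, TOTAL_CONTROL,
                        library_totals={"t1": TOTAL_TREATED,
                                        "c1": TOTAL_CONTROL},
                        treated_libs=["t1"], control_libs=["c1"])
        assert rows == []

    def test_sorted_by_p(self):
        counts = {"a": {"t1": 500, "c1": 400},
                  "b": {"t1": 900, "c1": 100}}
        rows = de_table(counts, 10 ** 6, 10 ** 6,
                        treated_libs=["t1"], control_libs=["c1"])
        assert rows[0].name == "b"
        assert rows[0].p_value <= rows[1].p_value


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 60), st.integers(0, 60))
def test_p_value_matches_oracle_property(x, y):
    got = count_p_value(x, y, 10 ** 6, 3 * 10 ** 6)
    want = ac_p_value_exact(x, y, 10 ** 6, 3 * 10 ** 6)
    assert got == pytest.approx(want, rel=1e-9)


def test_p_value_near_symmetry(rng):
    # swapping (x, n1) with (y, n2) changes the tail only by inclusion of
    # the observed point, so the two p-values agree closely
    for _ in range(20):
        x = int(rng.integers(0, 80))
        y = int(rng.integers(0, 80))
        a = count_p_value(x, y, 1e6, 2e6)
        b = count_p_value(y, x, 2e6, 1e6)
        # agree within a small factor (boundary-point inclusion differs)
        assert 0.25 <= (a + 1e-300) / (b + 1e-300) <= 4.0
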