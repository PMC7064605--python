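"""Unit and property tests for the LZ76 complexity estimator and its rescaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from simbias.complexity import (
    DegenerateScalingError,
    EmptyStringError,
    SymbolString,
    c_lz,
    c_lz_batch,
    calibrate_scaling,
    complexity_value,
    complexity_table,
    lz76_word_count,
    scaled_complexity,
)

from oracles import reference_lz76_words


@pytest.mark.parametrize(
    "s,expected",
    [("0", 1), ("1", 1), ("0000", 2), ("1111111", 2), ("01", 2), ("00", 2)],
)
def test_word_count_trivial_examples(s, expected):
    assert lz76_word_count(s) == expected


def test_word_count_matches_reference_on_short_binary_strings():
    """Exhaustive agreement with the definition-based parser up to length 8."""
    for n in range(1, 9):
        for i in range(2 ** n):
            s = format(i, f"0{n}b")
            assert lz76_word_count(s) == reference_lz76_words(s), s


def test_word_count_empty_string_error():
    with pytest.raises((EmptyStringError, ValueError)):
        lz76_word_count(SymbolString((), ("0", "1")))


@pytest.mark.parametrize("n", range(2, 65))
def test_trivial_string_floor(n):
    """C_LZ of a repeated symbol is log2(n), the complexity of encoding n."""
    assert c_lz("0" * n) == pytest.approx(math.log2(n))
    assert c_lz("1" * n) == pytest.approx(math.log2(n))


@settings(derandomize=True, max_examples=300)
@given(st.integers(2, 4), st.data())
def test_reversal_symmetry(alpha_size, data):
    alphabet = "ACGU"[:alpha_size]
    s = data.draw(st.text(alphabet=alphabet, min_size=1, max_size=40))
    assert c_lz(SymbolString.from_text(s, alphabet)) == pytest.approx(
        c_lz(SymbolString.from_text(s[::-1], alphabet)))


@settings(derandomize=True, max_examples=200)
@given(st.text(alphabet="ABC", min_size=1, max_size=30), st.permutations(["X", "Y", "Z"]))
def test_relabeling_invariance(s, perm):
    """Any bijective alphabet relabeling leaves the phrase count unchanged."""
    relabel = dict(zip("ABC", perm))
    t = "".join(relabel[ch] for ch in s)
    a = SymbolString.from_text(s, "ABC")
    b = SymbolString.from_text(t, tuple(perm))
    assert lz76_word_count(a) == lz76_word_count(b)
    assert c_lz(a) == pytest.approx(c_lz(b))


def test_batch_kernel_agrees_with_scalar_path():
    rng = np.random.default_rng(7)
    arr = rng.integers(0, 2, size=(200, 24)).astype(np.uint8)
    batch = c_lz_batch(arr)
    for row, expect in zip(arr, batch):
        s = SymbolString(tuple(str(b) for b in row), ("0", "1"))
        assert c_lz(s) == pytest.approx(expect)


class TestScaling:
    def test_floor_maps_to_zero(self):
        lo = c_lz("0" * 16)
        assert scaled_complexity("0" * 16, 16.0, lo, 40.0) == 0.0

    def test_max_maps_to_range(self):
        assert scaled_complexity(40.0, 16.0, 4.0, 40.0) == pytest.approx(16.0)

    def test_affine_monotone(self):
        vals = [scaled_complexity(v, 10.0, 0.0, 50.0) for v in (5.0, 10.0, 30.0)]
        assert vals == sorted(vals)

    def test_clamped_outside_population(self):
        assert scaled_complexity(100.0, 10.0, 0.0, 50.0) == 10.0
        assert scaled_complexity(-5.0, 10.0, 0.0, 50.0) == 0.0

    def test_degenerate_scaling_error(self):
        with pytest.raises(DegenerateScalingError):
            scaled_complexity("0101", 4.0, 5.0, 5.0)

    def test_scaled_in_range_for_calibrated_population(self):
        rng = np.random.default_rng(0)
        pop = ["".join(rng.choice(list("01"), 20)) for _ in range(50)]
        lo, hi = calibrate_scaling(pop)
        assert lo <= hi
        for s in pop:
            assert 0.0 <= scaled_complexity(s, 20.0, lo, hi) <= 20.0


class TestCalibration:
    def test_trivial_member_sets_floor(self):
        lo, hi = calibrate_scaling(["00000000", "01010101"])
        assert lo == pytest.approx(3.0)

    def test_exhaustive_small_population_max(self):
        pop = [format(i, "010b") for i in range(1024)]
        lo, hi = calibrate_scaling(pop)
        assert hi == pytest.approx(max(c_lz(s) for s in pop))
        assert lo <= hi

    def test_single_string_population_degenerate(self):
        with pytest.raises(DegenerateScalingError):
            calibrate_scaling(["0101"])


def test_complexity_value_records_constants():
    cv = complexity_value("0011010110", 10.0, 3.0, 40.0)
    assert cv.n_words_forward >= 1 and cv.n_words_reverse >= 1
    assert cv.c_lz == pytest.approx(math.log2(10) * (cv.n_words_forward + cv.n_words_reverse) / 2)
    assert cv.scale_min == 3.0 and cv.scale_max == 40.0 and cv.scale_range_bits == 10.0
    assert 0.0 <= cv.k_scaled <= 10.0


def test_complexity_table_roundtrip(tmp_path):
    strings = ["0000000000", "0101010101", "0011010110"]
    df = complexity_table(strings)
    assert list(df["string"]) == strings
    out = tmp_path / "scores.tsv"
    df.to_csv(out, sep="\t", index=False)
    assert out.read_text().startswith("string\t")
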