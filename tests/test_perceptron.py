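"""Lattice perceptron tests: thresholding, weight encoding, exhaustive map."""

import numpy as np
import pytest

from simbias.perceptron import (
    DiscretePerceptron,
    decode_weight_bitstring,
    enumerate_perceptron_map,
    hypercube_vertices,
    perceptron_function,
    sample_continuous_map,
    weight_bitstring,
)


def _p(n, k, weights, bias):
    return DiscretePerceptron(n_inputs=n, bits_per_weight=k,
                              weights=tuple(weights), bias=bias)


class TestFunction:
    def test_min_lattice_weights_and_bias_all_zeros(self):
        a = 3.5  # k=3 lattice half-range
        p = _p(7, 3, [-a] * 7, -a)
        assert str(perceptron_function(p)) == "0" * 128

    def test_max_bias_all_ones_on_zero_vertex(self):
        a = 1.5
        p = _p(3, 2, [a] * 3, a)
        assert str(perceptron_function(p)) == "1" * 8

    def test_tie_maps_to_zero_under_strict_convention(self):
        # w.x + b = 0 at vertex (1,): w = 0.5, b = -0.5
        p = _p(1, 1, [0.5], -0.5)
        assert str(perceptron_function(p, "strict")) == "00"
        assert str(perceptron_function(p, "nonstrict")) == "01"

    def test_vertex_order_msb_first(self):
        X = hypercube_vertices(3)
        assert X[0].tolist() == [0, 0, 0]
        assert X[1].tolist() == [0, 0, 1]
        assert X[4].tolist() == [1, 0, 0]


class TestWeightBitstring:
    def test_published_length(self):
        p = _p(7, 3, [-3.5] * 7, -3.5)
        assert len(weight_bitstring(p)) == 24

    def test_all_minimum_lattice_is_zeros(self):
        p = _p(5, 2, [-1.5] * 5, -1.5)
        assert str(weight_bitstring(p)) == "0" * 12

    def test_roundtrip_random(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n, k = int(rng.integers(1, 6)), int(rng.integers(1, 4))
            a = ((1 << k) - 1) / 2
            vals = rng.integers(0, 1 << k, size=n + 1) - a
            p = _p(n, k, vals[:-1], vals[-1])
            q = decode_weight_bitstring(weight_bitstring(p), n, k)
            assert q.weights == p.weights and q.bias == p.bias

    def test_off_lattice_value_rejected(self):
        with pytest.raises(ValueError):
            _p(2, 1, [0.0, 0.5], 0.5)


class TestEnumeration:
    def test_n2_k1_matches_hand_oracle(self, frozen):
        """The 8-setting map equals the hand-computed truth tables, setting by setting."""
        for rec in frozen["perceptron_oracle"]:
            p = _p(2, 1, rec["weights"], rec["bias"])
            assert str(perceptron_function(p)) == rec["truth_table"]
        emap = enumerate_perceptron_map(2, 1)
        tally = {}
        for rec in frozen["perceptron_oracle"]:
            tally[rec["truth_table"]] = tally.get(rec["truth_table"], 0) + 1
        got = dict(zip(emap.table["output"], emap.table["neutral_set_size"]))
        assert got == tally

    def test_conservation_and_normalization(self, perceptron_map_n5k2):
        emap = perceptron_map_n5k2
        assert emap.table["neutral_set_size"].sum() == 2 ** 12
        assert emap.table["probability"].sum() == pytest.approx(1.0)

    def test_constant_functions_most_probable(self, perceptron_map_n5k2):
        top2 = set(perceptron_map_n5k2.table.head(2)["output"])
        assert top2 == {"0" * 32, "1" * 32}

    def test_xor_never_realized(self):
        emap = enumerate_perceptron_map(2, 2)
        assert "0110" not in set(emap.table["output"])
        assert "1001" not in set(emap.table["output"])

    def test_coordinate_permutation_preserves_neutral_set_multiset(self):
        """Permuting input coordinates permutes truth tables but not the count multiset."""
        emap = enumerate_perceptron_map(3, 2)
        perm = [2, 0, 1]
        X = hypercube_vertices(3)
        # vertex v under coordinate permutation maps to vertex with permuted bits
        vertex_map = [int("".join(str(X[v][p]) for p in perm), 2) for v in range(8)]
        permuted = {}
        for _, row in emap.table.iterrows():
            tt = row["output"]
            ptt = "".join(tt[vertex_map[v]] for v in range(8))
            permuted[ptt] = permuted.get(ptt, 0) + row["neutral_set_size"]
        assert sorted(permuted.values()) == sorted(emap.table["neutral_set_size"])
        assert set(permuted) == set(emap.table["output"])


def test_continuous_weight_demonstration_sampled_map():
    emap = sample_continuous_map(n=5, n_samples=20000, rng_seed=1)
    assert not emap.complete
    assert emap.table["probability"].sum() == pytest.approx(1.0)
    # simplicity bias is visible even in the sampled continuous map
    top = emap.table.head(2)["output"]
    assert ("0" * 32 in set(top)) or ("1" * 32 in set(top))
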