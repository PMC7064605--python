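"""Parameter -> function map of a perceptron with lattice weights.

The map sends a weight-bias setting (w, b) to the Boolean function
f_{w,b}(x) = 1(w.x + b > 0) it computes on the hypercube {0,1}^n.  Each
of the n weights and the bias takes one of D = 2^k values on the lattice
{-a, -a+1, ..., a-1, a} with a = (2^k - 1)/2 (half-integer spacing 1),
so a setting is described by k(n+1) bits: the k-bit rank codes of
w_1..w_n, b concatenated in that order.  Exhaustive enumeration over all
2^{k(n+1)} settings counts how often each truth table appears; only
linearly separable functions ever occur.

Truth tables list the function value on every vertex, vertices ordered
by the integer value of their bit pattern (first input = most
significant bit).  The indicator convention is strict: w.x + b = 0 maps
to 0 (exact zeros can occur on this lattice); it is configurable and
recorded in catalogue metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .catalog import EnumeratedMap, build_catalog
from .complexity import SymbolString, c_lz_batch

__all__ = [
    "DiscretePerceptron", "perceptron_function", "weight_bitstring",
    "decode_weight_bitstring", "enumerate_perceptron_map", "hypercube_vertices",
    "sample_continuous_map",
]

_CHUNK = 1 << 16  # parameter settings per enumeration chunk


@dataclass(frozen=True, eq=False)
class DiscretePerceptron:
    """One lattice weight-bias setting of an n-input perceptron.

    ``weights`` (length n) and ``bias`` hold lattice values in
    {-a, ..., a}; ``bits_per_weight`` = k fixes the lattice D = 2^k.
    """

    n_inputs: int
    bits_per_weight: int
    weights: tuple
    bias: float

    def __post_init__(self):
        if len(self.weights) != self.n_inputs:
            raise ValueError("need exactly n_inputs weights")
        a = self.lattice_half_range
        for v in (*self.weights, self.bias):
            r = v + a
            if not (0 <= r <= 2 * a) or abs(r - round(r)) > 1e-9:
                raise ValueError(f"value {v} not on the lattice [-{a}, {a}] step 1")

    @property
    def levels(self) -> int:
        """D = 2^k lattice points per parameter."""
        return 1 << self.bits_per_weight

    @property
    def lattice_half_range(self) -> float:
        """a = (2^k - 1)/2."""
        return (self.levels - 1) / 2

    @property
    def lattice_step(self) -> float:
        return 1.0


def hypercube_vertices(n: int) -> np.ndarray:
    """(2^n, n) matrix of hypercube vertices, ordered by bit-pattern value (MSB = first input)."""
    idx = np.arange(1 << n, dtype=np.uint32)
    return ((idx[:, None] >> np.arange(n - 1, -1, -1, dtype=np.uint32)) & 1).astype(np.int8)


def _threshold(z: np.ndarray, convention: str) -> np.ndarray:
    if convention == "strict":      # 1(z) = 1 iff z > 0; ties to 0
        return (z > 0).astype(np.uint8)
    if convention == "nonstrict":   # ties to 1
        return (z >= 0).astype(np.uint8)
    raise ValueError(f"unknown threshold convention {convention!r}")


def perceptron_function(p: DiscretePerceptron, convention: str = "strict") -> SymbolString:
    """Truth table of f_{w,b} on the hypercube as a 2^n-bit string."""
    X = hypercube_vertices(p.n_inputs)
    z = X @ np.asarray(p.weights, dtype=float) + p.bias
    bits = _threshold(z, convention)
    return SymbolString(tuple(str(b) for b in bits), ("0", "1"))


def weight_bitstring(p: DiscretePerceptron) -> SymbolString:
    """k(n+1)-bit description: rank codes of w_1..w_n then b, each in standard binary."""
    a = p.lattice_half_range
    k = p.bits_per_weight
    bits = []
    for v in (*p.weights, p.bias):
        bits.append(format(int(round(v + a)), f"0{k}b"))
    return SymbolString(tuple("".join(bits)), ("0", "1"))


def decode_weight_bitstring(bits: SymbolString | str, n_inputs: int,
                            bits_per_weight: int) -> DiscretePerceptron:
    """Inverse of :func:`weight_bitstring`."""
    text = str(bits)
    k = bits_per_weight
    if len(text) != k * (n_inputs + 1):
        raise ValueError("bitstring length must be k*(n+1)")
    a = ((1 << k) - 1) / 2
    vals = [int(text[i * k:(i + 1) * k], 2) - a for i in range(n_inputs + 1)]
    return DiscretePerceptron(n_inputs=n_inputs, bits_per_weight=k,
                              weights=tuple(vals[:-1]), bias=vals[-1])


def _truth_tables_chunk(ranks: np.ndarray, a: float, X: np.ndarray,
                        convention: str) -> np.ndarray:
    """Threshold outputs for a chunk of rank matrices; returns (N, 2^n) uint8."""
    W = ranks[:, :-1].astype(np.float64) - a
    b = ranks[:, -1].astype(np.float64) - a
    z = W @ X.T.astype(np.float64) + b[:, None]
    return _threshold(z, convention)


def enumerate_perceptron_map(
    n: int = 5,
    k: int = 2,
    convention: str = "strict",
) -> EnumeratedMap:
    """Enumerate all 2^{k(n+1)} lattice settings and group by truth table.

    Input description length is k(n+1) bits (the weight bitstrings);
    output complexity is scored on the 2^n-bit truth tables with scale
    range 2^n bits.
    """
    if n < 1 or k < 1:
        raise ValueError("need n >= 1 and k >= 1")
    n_bits = k * (n + 1)
    if n_bits > 26:
        raise ValueError("2^{k(n+1)} settings exceed the enumeration budget")
    m = 1 << n           # truth table length
    if m > 63:
        raise ValueError("truth tables longer than 63 bits need a wider packing")
    total = 1 << n_bits
    a = ((1 << k) - 1) / 2
    X = hypercube_vertices(n)
    tt_weights = (1 << np.arange(m - 1, -1, -1, dtype=np.uint64))

    codes = np.empty(total, dtype=np.uint64)
    input_bits_mat = np.empty((total, n_bits), dtype=np.uint8)
    shifts = np.arange(n_bits - 1, -1, -1, dtype=np.uint64)
    for start in range(0, total, _CHUNK):
        stop = min(start + _CHUNK, total)
        idx = np.arange(start, stop, dtype=np.uint64)
        bits = ((idx[:, None] >> shifts) & np.uint64(1)).astype(np.uint8)
        input_bits_mat[start:stop] = bits
        # rank of parameter i = value of its k-bit field
        ranks = np.zeros((stop - start, n + 1), dtype=np.int64)
        for i in range(n + 1):
            field = bits[:, i * k:(i + 1) * k].astype(np.int64)
            ranks[:, i] = field @ (1 << np.arange(k - 1, -1, -1))
        tts = _truth_tables_chunk(ranks, a, X, convention)
        codes[start:stop] = (tts.astype(np.uint64) * tt_weights).sum(axis=1)

    input_raw = c_lz_batch(input_bits_mat)

    def strings(distinct):
        return [format(int(c), f"0{m}b") for c in distinct]

    def out_clz(distinct):
        arr = ((distinct[:, None] >> np.arange(m - 1, -1, -1, dtype=np.uint64))
               & np.uint64(1)).astype(np.uint8)
        return c_lz_batch(arr)

    return build_catalog(
        map_label=f"perceptron_n{n}_k{k}",
        output_ids=codes,
        output_strings=strings,
        output_raw_clz=out_clz,
        input_raw_clz=input_raw,
        input_bits=float(n_bits),
        output_range_bits=float(m),
        input_scale_min=math.log2(n_bits),
        output_scale_min=math.log2(m),
        meta={"n": n, "k": k, "threshold_convention": convention,
              "vertex_order": "lexicographic-msb-first"},
    )


def sample_continuous_map(
    n: int = 7,
    n_samples: int = 100_000,
    rng_seed: int = 0,
    convention: str = "strict",
) -> EnumeratedMap:
    """Sampled truth-table distribution for standard-normal (continuous) weights.

    Demonstration counterpart of the lattice enumeration: weights and
    bias are drawn i.i.d. N(0,1), so probabilities are estimates and the
    catalogue is flagged incomplete (no input complexity scale exists
    for real-valued weights; k_max_input/delta_max are reported as 0).
    """
    rng = np.random.default_rng(rng_seed)
    m = 1 << n
    X = hypercube_vertices(n)
    W = rng.standard_normal((n_samples, n))
    b = rng.standard_normal(n_samples)
    tts = _threshold(W @ X.T.astype(np.float64) + b[:, None], convention)
    if m > 63:
        packed = np.packbits(tts, axis=1)
        codes = np.ascontiguousarray(packed).view(
            np.dtype((np.void, packed.shape[1]))).ravel()
    else:
        codes = (tts.astype(np.uint64) * (1 << np.arange(m - 1, -1, -1, dtype=np.uint64))).sum(axis=1)

    distinct, counts = np.unique(codes, return_counts=True)
    if m > 63:
        dist_bits = np.unpackbits(distinct.view(np.uint8).reshape(len(distinct), -1),
                                  axis=1)[:, :m]
    else:
        dist_bits = ((distinct[:, None] >> np.arange(m - 1, -1, -1, dtype=np.uint64))
                     & np.uint64(1)).astype(np.uint8)
    out_raw = c_lz_batch(dist_bits.astype(np.uint8))

    from .catalog import build_catalog_from_groups
    return build_catalog_from_groups(
        map_label=f"perceptron_continuous_n{n}",
        output_strings=["".join(str(int(x)) for x in row) for row in dist_bits],
        counts=counts,
        input_raw_max=np.zeros(len(distinct)),
        input_raw_lo=0.0,
        input_raw_hi=0.0,
        input_bits=0.0,
        output_raw_clz=out_raw,
        output_range_bits=float(m),
        output_scale_min=math.log2(m),
        n_inputs=n_samples,
        meta={"n": n, "weights": "standard-normal", "n_samples": n_samples,
              "threshold_convention": convention},
        complete=False,
    )
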