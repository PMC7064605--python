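"""Analytic toy maps and frozen fixtures.

Toy maps (:func:`make_toy_map`) are binary-string maps with closed-form
output probabilities, enumerated both analytically and through the
standard catalogue path so the two can be compared exactly.

Frozen fixtures (:func:`frozen_fixtures`) pin every value that depends
on a choice the underlying theory leaves open, in one versioned JSON
file that is never recomputed silently:

* the two length-15 worked-example structures S1/S2 together with the
  complexity-scale calibration that reproduces their published scaled
  complexity of 21.4 bits (scale_min = log2(30), the analytic
  trivial-string floor; scale_max = the maximum C_LZ over the binary
  encodings of all 2481 well-formed length-15 dot-bracket structures);
* one seeded 5-state Mealy machine with its hand-traced output;
* the 8-setting n=2, k=1 perceptron truth-table oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable

import numpy as np

from .catalog import EnumeratedMap, enumerate_function_map
from .fst import MealyMachine, machine_from_json
from .rna import RNAStructure

__all__ = ["ToyMap", "make_toy_map", "frozen_fixtures", "TOY_KINDS"]

TOY_KINDS = ("constant", "identity", "majority", "first-bit-repeat")


@dataclass(frozen=True)
class ToyMap:
    """A toy map with closed-form neutral set sizes."""

    label: str
    n_bits: int
    closed_form: dict            # output string -> |f^-1(x)|
    rule: Callable = None

    @property
    def n_inputs(self) -> int:
        return 1 << self.n_bits

    def probabilities(self) -> dict:
        return {x: c / self.n_inputs for x, c in self.closed_form.items()}


def _toy_rule(kind: str, n: int) -> Callable[[np.ndarray], np.ndarray]:
    if kind == "constant":
        return lambda bits: np.zeros_like(bits)
    if kind == "identity":
        return lambda bits: bits
    if kind == "majority":
        return lambda bits: np.repeat(
            (bits.sum(axis=1) * 2 > n).astype(np.uint8)[:, None], n, axis=1)
    if kind == "first-bit-repeat":
        return lambda bits: np.repeat(bits[:, :1], n, axis=1)
    raise ValueError(f"unknown toy map kind {kind!r}; choose from {TOY_KINDS}")


def _toy_closed_form(kind: str, n: int) -> dict:
    if kind == "constant":
        return {"0" * n: 1 << n}
    if kind == "identity":
        return {format(i, f"0{n}b"): 1 for i in range(1 << n)}
    if kind == "majority":
        if n % 2 == 0:
            raise ValueError("majority toy map needs odd n")
        upper = sum(math.comb(n, j) for j in range(n // 2 + 1, n + 1))
        return {"1" * n: upper, "0" * n: (1 << n) - upper}
    if kind == "first-bit-repeat":
        return {"0" * n: 1 << (n - 1), "1" * n: 1 << (n - 1)}
    raise ValueError(f"unknown toy map kind {kind!r}; choose from {TOY_KINDS}")


def make_toy_map(kind: str, n: int) -> tuple[ToyMap, EnumeratedMap]:
    """Closed-form answer plus the catalogue built through the standard enumeration path."""
    if n > 20:
        raise ValueError("toy maps are for n <= 20")
    rule = _toy_rule(kind, n)
    toy = ToyMap(label=f"toy_{kind}_n{n}", n_bits=n,
                 closed_form=_toy_closed_form(kind, n), rule=rule)
    emap = enumerate_function_map(toy.label, rule, n)
    return toy, emap


def _load_frozen() -> dict:
    with resources.files("simbias").joinpath("data/frozen.json").open() as fh:
        return json.load(fh)


def frozen_fixtures() -> dict:
    """Deserialize the frozen fixture set.

    Returns a dict with keys ``s1``/``s2`` (:class:`RNAStructure`),
    ``calibration`` (scale_min/scale_max/range_bits/expected_k_scaled),
    ``machine`` (:class:`MealyMachine`), ``machine_trace`` (input,
    states visited, output), and ``perceptron_oracle`` (list of
    {weights, bias, truth_table} for n=2, k=1).
    """
    raw = _load_frozen()
    return dict(
        s1=RNAStructure(raw["worked_example"]["s1"]),
        s2=RNAStructure(raw["worked_example"]["s2"]),
        calibration=raw["worked_example"]["calibration"],
        machine=machine_from_json(raw["mealy_machine"]),
        machine_trace=raw["mealy_machine_trace"],
        perceptron_oracle=raw["perceptron_oracle_n2_k1"],
    )
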