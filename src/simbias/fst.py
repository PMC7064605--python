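"""Finite state transducers (Mealy machines) as input-output maps.

A Mealy machine has a finite state set, input and output alphabets, a
complete transition function T: S x I -> S x O and a start state S0.
Reading an input string of length L produces an output string of the
same length.  Machines are sampled uniformly over complete transition
tables and accepted only if initially connected (every state reachable
from S0); output symbols on the transitions are i.i.d. uniform.

The exhaustive map sends all |I|^L inputs of length L through the
machine and groups outputs.  Input and output complexities are scored
directly on the binary strings (scale range L bits).

Not every machine produces a biased (low-entropy) output distribution;
:func:`output_entropy` and :func:`is_biased` implement the screening
used to pick fixture machines that do, since only biased machines show
measurable simplicity bias.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .catalog import EnumeratedMap, ResumableInterrupt, build_catalog
from .complexity import SymbolString, c_lz_batch

__all__ = [
    "MealyMachine", "InvalidInputError", "transduce", "sample_machine",
    "initially_connected", "enumerate_fst_map", "output_entropy", "is_biased",
    "machine_to_json", "machine_from_json",
]


class InvalidInputError(ValueError):
    """Input string contains a token outside the machine's input alphabet."""


@dataclass(frozen=True, eq=False)
class MealyMachine:
    """Complete, initially connected deterministic finite state transducer.

    ``next_state[s, a]`` and ``output[s, a]`` give the successor state
    and emitted token index for state ``s`` reading input-alphabet token
    index ``a``.  The start state is state 0.
    """

    n_states: int
    input_alphabet: tuple
    output_alphabet: tuple
    next_state: np.ndarray
    output: np.ndarray
    start_state: int = 0
    seed: int | None = None

    def __post_init__(self):
        ns = np.asarray(self.next_state)
        out = np.asarray(self.output)
        shape = (self.n_states, len(self.input_alphabet))
        if ns.shape != shape or out.shape != shape:
            raise ValueError("transition tables must have shape (n_states, |input alphabet|)")
        if ns.min() < 0 or ns.max() >= self.n_states:
            raise ValueError("next-state entries out of range")
        if out.min() < 0 or out.max() >= len(self.output_alphabet):
            raise ValueError("output entries out of range")
        if not initially_connected(ns, self.start_state):
            raise ValueError("machine is not initially connected")


def initially_connected(next_state: np.ndarray, start: int = 0) -> bool:
    """True if every state is reachable from the start state."""
    n = next_state.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for s in range(n):
        for a in range(next_state.shape[1]):
            g.add_edge(s, int(next_state[s, a]))
    return len(nx.descendants(g, start) | {start}) == n


def transduce(m: MealyMachine, inp: SymbolString | str) -> SymbolString:
    """Run the machine on one input string; output has the same length."""
    tokens = inp.symbols if isinstance(inp, SymbolString) else tuple(inp)
    lookup = {tok: i for i, tok in enumerate(m.input_alphabet)}
    out = []
    s = m.start_state
    for tok in tokens:
        try:
            a = lookup[tok]
        except KeyError:
            raise InvalidInputError(f"token {tok!r} not in input alphabet {m.input_alphabet}")
        out.append(m.output_alphabet[int(m.output[s, a])])
        s = int(m.next_state[s, a])
    return SymbolString(tuple(out), m.output_alphabet)


def sample_machine(
    n_states: int,
    in_alpha=("0", "1"),
    out_alpha=("0", "1"),
    rng_seed: int | np.random.Generator = 0,
) -> MealyMachine:
    """Rejection-sample an initially connected machine.

    A complete transition table is drawn uniformly; it is accepted iff
    every state is reachable from the start state.  Output tokens are
    then attached to each transition independently and uniformly.
    Reproducible from the seed.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    na = len(in_alpha)
    while True:
        ns = rng.integers(0, n_states, size=(n_states, na))
        if initially_connected(ns):
            break
    out = rng.integers(0, len(out_alpha), size=(n_states, na))
    seed = rng_seed if isinstance(rng_seed, int) else None
    return MealyMachine(
        n_states=n_states, input_alphabet=tuple(in_alpha), output_alphabet=tuple(out_alpha),
        next_state=ns, output=out, seed=seed,
    )


def acceptance_rate(n_states: int, n_alpha: int = 2, n_trials: int = 2000,
                    rng_seed: int = 0) -> float:
    """Fraction of uniform complete transition tables that are initially connected."""
    rng = np.random.default_rng(rng_seed)
    ok = 0
    for _ in range(n_trials):
        ns = rng.integers(0, n_states, size=(n_states, n_alpha))
        ok += initially_connected(ns)
    return ok / n_trials


# ---------------------------------------------------------------------------
# Exhaustive enumeration
# ---------------------------------------------------------------------------

def _transduce_all(m: MealyMachine, L: int) -> tuple[np.ndarray, np.ndarray]:
    """(output codes, input bit matrix) for all 2^L binary inputs, vectorized."""
    if len(m.input_alphabet) != 2 or len(m.output_alphabet) != 2:
        raise NotImplementedError("exhaustive enumeration is implemented for binary alphabets")
    n = 1 << L
    idx = np.arange(n, dtype=np.uint64)
    bits = ((idx[:, None] >> np.arange(L - 1, -1, -1, dtype=np.uint64)) & 1).astype(np.uint8)
    state = np.full(n, m.start_state, dtype=np.uint8)
    codes = np.zeros(n, dtype=np.uint64)
    ns = np.asarray(m.next_state, dtype=np.uint8)
    out = np.asarray(m.output, dtype=np.uint8)
    for t in range(L):
        a = bits[:, t]
        codes = (codes << np.uint64(1)) | out[state, a].astype(np.uint64)
        state = ns[state, a]
    return codes, bits


def enumerate_fst_map(
    m: MealyMachine,
    L: int,
    budget_seconds: float | None = None,
) -> EnumeratedMap:
    """Map all 2^L binary inputs through the machine and build the catalogue.

    Input description length is n = L bits; output strings also have
    length L, so both complexity scales have range L.  ``budget_seconds``
    guards accidental huge runs (the evaluation itself is vectorized and
    not checkpointed: re-running is cheaper than checkpointing it).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if L > 28:
        raise ValueError("2^L inputs exceed the in-memory budget; use L <= 28")
    t0 = time.monotonic()
    codes, bits = _transduce_all(m, L)
    input_raw = c_lz_batch(bits)
    if budget_seconds is not None and time.monotonic() - t0 > budget_seconds:
        raise ResumableInterrupt("<fst enumeration is not checkpointed>", 1 << L, 1 << L)

    weights = np.arange(L - 1, -1, -1, dtype=np.uint64)

    def strings(distinct):
        return [format(int(c), f"0{L}b") for c in distinct]

    def out_clz(distinct):
        arr = ((distinct[:, None] >> weights) & np.uint64(1)).astype(np.uint8)
        return c_lz_batch(arr)

    return build_catalog(
        map_label=f"fst_{m.n_states}state_L{L}",
        output_ids=codes,
        output_strings=strings,
        output_raw_clz=out_clz,
        input_raw_clz=input_raw,
        input_bits=float(L),
        output_range_bits=float(L),
        input_scale_min=math.log2(L) if L >= 2 else None,
        output_scale_min=math.log2(L) if L >= 2 else None,
        meta={"n_states": m.n_states, "seed": m.seed, "L": L},
    )


# ---------------------------------------------------------------------------
# Bias screening (fixture selection)
# ---------------------------------------------------------------------------

def output_entropy(m: MealyMachine, L: int = 14) -> float:
    """Shannon entropy (bits) of the machine's output distribution at length L."""
    codes, _ = _transduce_all(m, L)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def is_biased(m: MealyMachine, L: int = 14, margin_bits: float = 2.0) -> bool:
    """Screen for machines with a low-entropy (biased) output distribution.

    A machine counts as biased when its output entropy at length L falls
    below L - margin_bits; an unbiased (e.g. identity-like) machine has
    entropy close to L.
    """
    return output_entropy(m, L) < L - margin_bits


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def machine_to_json(m: MealyMachine) -> dict:
    return dict(
        n_states=m.n_states,
        input_alphabet=list(m.input_alphabet),
        output_alphabet=list(m.output_alphabet),
        next_state=np.asarray(m.next_state).tolist(),
        output=np.asarray(m.output).tolist(),
        start_state=m.start_state,
        seed=m.seed,
    )


def machine_from_json(obj: dict | str) -> MealyMachine:
    if isinstance(obj, str):
        obj = json.loads(obj)
    return MealyMachine(
        n_states=obj["n_states"],
        input_alphabet=tuple(obj["input_alphabet"]),
        output_alphabet=tuple(obj["output_alphabet"]),
        next_state=np.asarray(obj["next_state"], dtype=np.int64),
        output=np.asarray(obj["output"], dtype=np.int64),
        start_state=obj.get("start_state", 0),
        seed=obj.get("seed"),
    )
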