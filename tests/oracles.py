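"""Independent reference implementations used only as test oracles.

These are deliberately written from the definitions, in plain Python,
without reusing any code from the package under test.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

#: complementary base pairs (Watson-Crick + GU wobble)
COMPLEMENT = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def reference_lz76_words(s: str) -> int:
    """Exhaustive-history LZ76 parse, straight from the definition.

    The next word is the shortest extension of the current position that
    is not reproducible from the prior history, where "reproducible"
    means the candidate occurs as a substring of everything before its
    last character (so copies may overlap the word being built).  The
    final, possibly incomplete, word counts as one.
    """
    n = len(s)
    words = []
    p = 0
    while p < n:
        k = 1
        while p + k <= n and s[p:p + k] in s[:p + k - 1]:
            k += 1
        words.append(s[p:p + k])
        p += k
    return len(words)


def all_structures(L: int, min_hairpin: int = 3) -> list[str]:
    """Every non-crossing pairing of L bases as a dot-bracket string."""

    @lru_cache(maxsize=None)
    def gen(n):
        if n == 0:
            return ("",)
        out = ["." + rest for rest in gen(n - 1)]
        for j in range(min_hairpin + 1, n):
            for inner in gen(j - 1):
                for rest in gen(n - j - 1):
                    out.append("(" + inner + ")" + rest)
        return tuple(out)

    return list(gen(L))


def structure_pairs(db: str) -> list[tuple[int, int]]:
    stack, pairs = [], []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs.append((stack.pop(), i))
    return pairs


def brute_force_max_pairs(seq: str, min_hairpin: int = 3) -> int:
    """Maximum number of base pairs over ALL valid structures, by exhaustive enumeration."""
    best = 0
    for db in all_structures(len(seq), min_hairpin):
        pairs = structure_pairs(db)
        if all((seq[i], seq[j]) in COMPLEMENT for i, j in pairs):
            best = max(best, len(pairs))
    return best


def exhaustive_connected_fraction(n_states: int, n_symbols: int = 2) -> float:
    """Exact fraction of complete transition tables that are initially connected.

    Enumerates all n_states^(n_states * n_symbols) next-state tables and
    checks reachability from state 0 by breadth-first search.
    """
    n_cells = n_states * n_symbols
    total = n_states ** n_cells
    connected = 0
    for table in itertools.product(range(n_states), repeat=n_cells):
        seen = {0}
        frontier = [0]
        while frontier:
            s = frontier.pop()
            for a in range(n_symbols):
                t = table[s * n_symbols + a]
                if t not in seen:
                    seen.add(t)
                    frontier.append(t)
        if len(seen) == n_states:
            connected += 1
    return connected / total
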