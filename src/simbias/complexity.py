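"""Lempel-Ziv (1976) complexity estimation for finite strings.

The estimator used throughout the package is the exhaustive-history
phrase count of Lempel & Ziv (1976): the string is parsed left to right
into words, each word being the shortest extension of the current
position that cannot be reproduced (copied, overlap allowed) from the
text preceding it; a final incomplete word counts as one.  The phrase
count is turned into a bit-valued measure

    C_LZ(x) = log2(n)                                     if x = s^n (one repeated symbol)
            = log2(n) * [N_w(x) + N_w(reverse(x))] / 2    otherwise

where n = len(x) and N_w is the phrase count.  The trivial-string branch
restores the log2(n) scaling a repeated symbol should have (the raw
parser assigns 2 words to any s^n with n >= 2), and averaging the
forward and reverse parses makes the measure finer grained.

Because C_LZ exceeds n for short strings and its floor is not 0, a
second affine rescaling maps it onto the 0..range_bits interval expected
of a Kolmogorov-complexity proxy:

    K~(x) = range_bits * (C_LZ(x) - scale_min) / (scale_max - scale_min)

with scale_min/scale_max calibrated over a declared string population
(:func:`calibrate_scaling`) and the result clamped to [0, range_bits]
for strings outside it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numba import njit

logger = logging.getLogger("simbias")

__all__ = [
    "SymbolString",
    "ComplexityValue",
    "EmptyStringError",
    "DegenerateScalingError",
    "lz76_word_count",
    "c_lz",
    "scaled_complexity",
    "calibrate_scaling",
    "complexity_value",
    "lz76_word_counts_batch",
    "c_lz_batch",
    "complexity_table",
    "read_strings",
]


class EmptyStringError(ValueError):
    """Complexity of the empty string is undefined."""


class DegenerateScalingError(ValueError):
    """scale_max <= scale_min: the affine rescaling is undefined."""


@dataclass(frozen=True)
class SymbolString:
    """A finite sequence of tokens over a declared alphabet.

    ``symbols`` is the ordered token sequence; ``alphabet`` the declared
    token set (size >= 2).  Tokens are single-character strings for all
    alphabets used here (binary, nucleotide, dot-bracket).
    """

    symbols: tuple
    alphabet: tuple

    def __post_init__(self):
        if len(self.alphabet) < 2:
            raise ValueError("alphabet must have size >= 2")
        bad = set(self.symbols) - set(self.alphabet)
        if bad:
            raise ValueError(f"tokens {sorted(bad)!r} not in declared alphabet")

    @classmethod
    def from_text(cls, text: str, alphabet: str | Sequence[str] | None = None) -> "SymbolString":
        if alphabet is None:
            alphabet = sorted(set(text))
            if len(alphabet) < 2:
                # pad so trivial strings still carry a valid >=2-token alphabet
                alphabet = sorted(set(alphabet) | {"0", "1"})
        return cls(tuple(text), tuple(alphabet))

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return "".join(str(s) for s in self.symbols)

    def reverse(self) -> "SymbolString":
        return SymbolString(self.symbols[::-1], self.alphabet)

    def as_codes(self) -> np.ndarray:
        """Token sequence as integer codes (rank in the declared alphabet)."""
        lookup = {tok: i for i, tok in enumerate(self.alphabet)}
        return np.fromiter((lookup[s] for s in self.symbols), dtype=np.uint8, count=len(self.symbols))


@dataclass(frozen=True)
class ComplexityValue:
    """Raw LZ phrase counts plus the derived bit-valued measures.

    ``scale_min``/``scale_max`` record the calibration constants that
    produced ``k_scaled`` so every scaled value is reproducible.
    """

    n_words_forward: int
    n_words_reverse: int
    c_lz: float
    k_scaled: float
    scale_min: float
    scale_max: float
    scale_range_bits: float


def _coerce(x) -> SymbolString:
    if isinstance(x, SymbolString):
        return x
    if isinstance(x, str):
        return SymbolString.from_text(x)
    raise TypeError(f"expected SymbolString or str, got {type(x).__name__}")


# ---------------------------------------------------------------------------
# LZ76 phrase counting
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lz76_count_codes(s):  # pragma: no cover - exercised via wrappers
    n = s.shape[0]
    p = 0
    c = 0
    while p < n:
        k = 1
        while p + k <= n:
            # is s[p:p+k] reproducible from s[:p+k-1]? (overlap allowed)
            found = False
            for st in range(p):
                ok = True
                for t in range(k):
                    if s[st + t] != s[p + t]:
                        ok = False
                        break
                if ok:
                    found = True
                    break
            if found:
                k += 1
            else:
                break
        c += 1
        p += k
    return c


@njit(cache=True)
def lz76_word_counts_batch(arr):  # pragma: no cover - exercised via wrappers
    """Forward and reverse LZ76 phrase counts for each row of a 2-D code array."""
    n_rows, n = arr.shape
    out = np.empty((n_rows, 2), dtype=np.int64)
    rev = np.empty(n, dtype=arr.dtype)
    for r in range(n_rows):
        out[r, 0] = _lz76_count_codes(arr[r])
        for t in range(n):
            rev[t] = arr[r, n - 1 - t]
        out[r, 1] = _lz76_count_codes(rev)
    return out


@njit(cache=True)
def c_lz_batch(arr):  # pragma: no cover - exercised via wrappers
    """C_LZ for each row of a 2-D code array (trivial-string branch included)."""
    n_rows, n = arr.shape
    out = np.empty(n_rows, dtype=np.float64)
    log2n = math.log2(n)
    rev = np.empty(n, dtype=arr.dtype)
    for r in range(n_rows):
        trivial = True
        for t in range(1, n):
            if arr[r, t] != arr[r, 0]:
                trivial = False
                break
        if trivial:
            out[r] = log2n
        else:
            fwd = _lz76_count_codes(arr[r])
            for t in range(n):
                rev[t] = arr[r, n - 1 - t]
            bwd = _lz76_count_codes(rev)
            out[r] = log2n * (fwd + bwd) / 2.0
    return out


def lz76_word_count(x: SymbolString | str) -> int:
    """Number of words in the LZ76 exhaustive-history parsing of ``x``.

    Deterministic and invariant under any bijective relabeling of the
    alphabet.  The final, possibly incomplete, word counts as one.
    """
    x = _coerce(x)
    if len(x) == 0:
        raise EmptyStringError("LZ76 word count undefined for the empty string")
    return int(_lz76_count_codes(x.as_codes()))


def c_lz(x: SymbolString | str) -> float:
    """Bit-valued LZ complexity: log2(n) for s^n, else the forward/reverse phrase-count average times log2(n)."""
    x = _coerce(x)
    n = len(x)
    if n == 0:
        raise EmptyStringError("C_LZ undefined for the empty string")
    if len(set(x.symbols)) == 1:
        return math.log2(n)
    fwd = lz76_word_count(x)
    bwd = lz76_word_count(x.reverse())
    return math.log2(n) * (fwd + bwd) / 2.0


def scaled_complexity(
    x: SymbolString | str | float,
    range_bits: float,
    scale_min: float,
    scale_max: float,
) -> float:
    """Affine rescaling of C_LZ onto [0, range_bits].

    ``x`` may be a string (C_LZ is computed) or an already-computed C_LZ
    value.  Values for strings outside the calibration population are
    clamped into the range, with a warning.
    """
    if scale_max <= scale_min:
        raise DegenerateScalingError(
            f"scale_max ({scale_max}) must exceed scale_min ({scale_min})"
        )
    if range_bits <= 0:
        raise ValueError("range_bits must be positive")
    value = x if isinstance(x, (int, float)) else c_lz(x)
    k = range_bits * (value - scale_min) / (scale_max - scale_min)
    if k < 0.0 or k > range_bits:
        logger.warning(
            "scaled complexity %.3f outside [0, %.3f]; clamping (string outside calibration population?)",
            k, range_bits,
        )
        k = min(max(k, 0.0), range_bits)
    return k


def calibrate_scaling(
    population: Iterable[SymbolString | str] | np.ndarray,
    range_bits: float | None = None,
) -> tuple[float, float]:
    """(scale_min, scale_max) = (min, max) of C_LZ over a string population.

    Accepts an iterable of strings or a pre-computed array of C_LZ
    values.  A population whose complexities do not span a positive
    range cannot calibrate the affine map and raises
    :class:`DegenerateScalingError`.
    """
    if isinstance(population, np.ndarray):
        values = np.asarray(population, dtype=float)
    else:
        values = np.array([c_lz(s) for s in population], dtype=float)
    if values.size == 0:
        raise ValueError("population is empty")
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise DegenerateScalingError(
            "population complexities span no range; cannot calibrate"
        )
    return lo, hi


def complexity_value(
    x: SymbolString | str,
    range_bits: float,
    scale_min: float,
    scale_max: float,
) -> ComplexityValue:
    """Full complexity record for one string under a given calibration."""
    x = _coerce(x)
    fwd = lz76_word_count(x)
    bwd = lz76_word_count(x.reverse())
    raw = c_lz(x)
    k = scaled_complexity(raw, range_bits, scale_min, scale_max)
    return ComplexityValue(
        n_words_forward=fwd,
        n_words_reverse=bwd,
        c_lz=raw,
        k_scaled=k,
        scale_min=scale_min,
        scale_max=scale_max,
        scale_range_bits=range_bits,
    )


# ---------------------------------------------------------------------------
# Plain-text scoring interface
# ---------------------------------------------------------------------------

def read_strings(path) -> list[str]:
    """Read strings one per line, ignoring blank lines."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def complexity_table(
    strings: Sequence[str],
    range_bits: float | None = None,
    scale_min: float | None = None,
    scale_max: float | None = None,
):
    """Score a batch of strings; returns a pandas DataFrame (TSV-ready).

    If calibration constants are not supplied, scale_min/scale_max are
    calibrated over the given strings themselves and range_bits defaults
    to the (common) string length.
    """
    import pandas as pd

    if not strings:
        raise ValueError("no strings to score")
    raws = np.array([c_lz(s) for s in strings])
    if scale_min is None or scale_max is None:
        scale_min, scale_max = calibrate_scaling(raws)
    if range_bits is None:
        range_bits = float(max(len(s) for s in strings))
    rows = []
    for s in strings:
        cv = complexity_value(s, range_bits, scale_min, scale_max)
        rows.append(
            dict(
                string=s,
                n_words_forward=cv.n_words_forward,
                n_words_reverse=cv.n_words_reverse,
                c_lz=cv.c_lz,
                k_scaled=cv.k_scaled,
                scale_min=cv.scale_min,
                scale_max=cv.scale_max,
            )
        )
    return pd.DataFrame(rows)
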