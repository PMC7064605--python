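"""RNA sequence -> minimum-free-energy secondary-structure map.

The genotype-phenotype map folds every one of the 4^L nucleotide
sequences of length L to its minimum-free-energy (MFE) secondary
structure and groups sequences by structure.  The number of sequences
folding to a structure is its *neutral set size*; divided by 4^L it is
the probability P(x) of obtaining structure x when sampling sequences
uniformly at random.

Two folding backends are provided:

``vienna``
    ViennaRNA's MFE fold with all parameters at their defaults
    (temperature 37 C).  This is the thermodynamically realistic
    backend; its version is recorded in every catalogue.

``fallback``
    A Nussinov-style maximum-base-pairing folder (Watson-Crick + GU
    wobble pairs, minimum hairpin loop of 3), compiled with numba for
    exhaustive runs.  It is self-contained and fast but does NOT
    reproduce thermodynamic-backend numbers; catalogues built with it
    are flagged accordingly.

Structures are represented in dot-bracket notation and, for complexity
estimation, binary-encoded two bits per symbol: '.' -> 00, '(' -> 10,
')' -> 01, so a length-L structure becomes a 2L-bit string.  Sequence
(input) complexity is scored directly on the 4-letter alphabet with a
scale range of 2L bits (two bits of description per base).
"""

from __future__ import annotations

import json
import logging
import math
import os
import time
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from numba import njit

from .catalog import EnumeratedMap, ResumableInterrupt, build_catalog_from_groups
from .complexity import SymbolString, c_lz, c_lz_batch

logger = logging.getLogger("simbias")

__all__ = [
    "RNAStructure", "MalformedStructureError", "InvalidSequenceError",
    "BackendUnavailableError", "encode_dotbracket", "decode_dotbracket",
    "fold", "enumerate_rna_map", "valid_structures", "structure_calibration",
    "read_fasta", "BASES", "ENCODING",
]

BASES = "ACGU"
#: dot-bracket symbol -> two-bit code
ENCODING = {".": "00", "(": "10", ")": "01"}
_DECODING = {v: k for k, v in ENCODING.items()}

#: minimum number of unpaired bases enclosed by a hairpin
MIN_HAIRPIN = 3

_CHUNK = 1 << 16  # sequences per enumeration chunk


class MalformedStructureError(ValueError):
    """Dot-bracket string is unbalanced or contains foreign characters."""


class InvalidSequenceError(ValueError):
    """Sequence contains characters outside {A, C, G, U}."""


class BackendUnavailableError(RuntimeError):
    """The requested folding backend cannot be loaded."""


def _check_dotbracket(db: str) -> None:
    depth = 0
    for ch in db:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise MalformedStructureError(f"unmatched ')' in {db!r}")
        elif ch != ".":
            raise MalformedStructureError(f"foreign character {ch!r} in {db!r}")
    if depth != 0:
        raise MalformedStructureError(f"unbalanced brackets in {db!r}")


@dataclass(frozen=True)
class RNAStructure:
    """A secondary structure in dot-bracket notation."""

    dotbracket: str

    def __post_init__(self):
        _check_dotbracket(self.dotbracket)

    @property
    def length(self) -> int:
        return len(self.dotbracket)

    @property
    def binary_encoding(self) -> SymbolString:
        return encode_dotbracket(self)

    def __str__(self) -> str:
        return self.dotbracket


def encode_dotbracket(s: RNAStructure | str) -> SymbolString:
    """Two-bit binary encoding of a dot-bracket string ('.'->00, '('->10, ')'->01)."""
    db = s.dotbracket if isinstance(s, RNAStructure) else s
    _check_dotbracket(db)
    bits = "".join(ENCODING[ch] for ch in db)
    return SymbolString(tuple(bits), ("0", "1"))


def decode_dotbracket(bits: SymbolString | str) -> RNAStructure:
    """Inverse of :func:`encode_dotbracket`."""
    text = str(bits) if isinstance(bits, SymbolString) else bits
    if len(text) % 2:
        raise MalformedStructureError("binary encoding must have even length")
    try:
        db = "".join(_DECODING[text[i:i + 2]] for i in range(0, len(text), 2))
    except KeyError as exc:
        raise MalformedStructureError(f"invalid two-bit code {exc}") from exc
    return RNAStructure(db)


# ---------------------------------------------------------------------------
# Folding backends
# ---------------------------------------------------------------------------

# base codes: A=0, C=1, G=2, U=3; allowed pairs AU, UA, CG, GC, GU, UG
_CAN_PAIR = np.zeros((4, 4), dtype=np.uint8)
for _i, _j in [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]:
    _CAN_PAIR[_i, _j] = 1


@njit(cache=True)
def _nussinov_code(seq, dp, struct):  # pragma: no cover - exercised via wrappers
    """Maximum-pairing fold of one coded sequence; returns the 2-bit structure code.

    dp is a scratch (L, L) int16 array, struct a scratch length-L uint8
    array (0='.', 1='(', 2=')').  Ties are broken by a deterministic
    canonical traceback: the leftmost base of each region is paired
    whenever pairing preserves optimality, with its smallest optimal
    partner.
    """
    L = seq.shape[0]
    for i in range(L):
        for j in range(L):
            dp[i, j] = 0
    for d in range(MIN_HAIRPIN + 1, L):
        for i in range(L - d):
            j = i + d
            best = dp[i + 1, j]
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                if _CAN_PAIR[seq[i], seq[k]]:
                    inner = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    rest = dp[k + 1, j] if k + 1 <= j else 0
                    v = 1 + inner + rest
                    if v > best:
                        best = v
            dp[i, j] = best
    for i in range(L):
        struct[i] = 0
    # iterative traceback over an explicit region stack
    stack_i = np.empty(2 * L + 2, dtype=np.int64)
    stack_j = np.empty(2 * L + 2, dtype=np.int64)
    top = 0
    stack_i[top] = 0
    stack_j[top] = L - 1
    top += 1
    while top > 0:
        top -= 1
        i = stack_i[top]
        j = stack_j[top]
        if i >= j or j - i <= MIN_HAIRPIN:
            continue
        target = dp[i, j]
        paired = False
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if _CAN_PAIR[seq[i], seq[k]]:
                inner = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                rest = dp[k + 1, j] if k + 1 <= j else 0
                if 1 + inner + rest == target:
                    struct[i] = 1
                    struct[k] = 2
                    stack_i[top] = i + 1
                    stack_j[top] = k - 1
                    top += 1
                    stack_i[top] = k + 1
                    stack_j[top] = j
                    top += 1
                    paired = True
                    break
        if not paired:
            stack_i[top] = i + 1
            stack_j[top] = j
            top += 1
    # pack: '.'=00, '('=10, ')'=01, MSB first
    code = np.uint64(0)
    for i in range(L):
        code = code << np.uint64(2)
        if struct[i] == 1:
            code |= np.uint64(2)
        elif struct[i] == 2:
            code |= np.uint64(1)
    return code


@njit(cache=True)
def _fold_range(start, stop, L):  # pragma: no cover - exercised via wrappers
    """Fold coded sequences ``start <= index < stop`` (base-4, MSB-first).

    Returns (structure codes, sequence code matrix) for the chunk.
    """
    n = stop - start
    codes = np.empty(n, dtype=np.uint64)
    seqs = np.empty((n, L), dtype=np.uint8)
    dp = np.zeros((L, L), dtype=np.int16)
    struct = np.zeros(L, dtype=np.uint8)
    for r in range(n):
        idx = start + r
        for pos in range(L - 1, -1, -1):
            seqs[r, pos] = idx & 3
            idx >>= 2
        codes[r] = _nussinov_code(seqs[r], dp, struct)
    return codes, seqs


def _seq_from_index(idx: int, L: int) -> str:
    out = []
    for _ in range(L):
        out.append(BASES[idx & 3])
        idx >>= 2
    return "".join(reversed(out))


def _seq_to_codes(seq: str) -> np.ndarray:
    try:
        return np.fromiter((BASES.index(ch) for ch in seq), dtype=np.uint8, count=len(seq))
    except ValueError as exc:
        raise InvalidSequenceError(f"sequence {seq!r} not over alphabet ACGU") from exc


def _code_to_dotbracket(code: int, L: int) -> str:
    sym = {0: ".", 2: "(", 1: ")"}
    out = []
    for pos in range(L):
        out.append(sym[(int(code) >> (2 * (L - 1 - pos))) & 3])
    return "".join(out)


class FallbackFolder:
    """Nussinov-style maximum-base-pairing folder (not thermodynamic)."""

    name = "fallback"

    @property
    def version(self) -> str:
        return "nussinov-maxpair-hairpin3"

    def fold(self, seq: str) -> RNAStructure:
        codes = _seq_to_codes(seq)
        L = len(codes)
        if L == 0:
            raise InvalidSequenceError("empty sequence")
        dp = np.zeros((L, L), dtype=np.int16)
        struct = np.zeros(L, dtype=np.uint8)
        code = _nussinov_code(codes, dp, struct)
        return RNAStructure(_code_to_dotbracket(int(code), L))


class ViennaFolder:
    """ViennaRNA MFE folder, default parameters, 37 C."""

    name = "vienna"

    def __init__(self):
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover
            raise BackendUnavailableError(
                "ViennaRNA Python bindings (module 'RNA') are not installed"
            ) from exc
        self._RNA = RNA

    @property
    def version(self) -> str:
        return getattr(self._RNA, "__version__", "unknown")

    def fold(self, seq: str) -> RNAStructure:
        _seq_to_codes(seq)  # validation
        db, _mfe = self._RNA.fold(seq)
        return RNAStructure(db)


_FOLDERS = {"fallback": FallbackFolder, "vienna": ViennaFolder}


def get_folder(folder: str | FallbackFolder | ViennaFolder):
    if isinstance(folder, str):
        try:
            return _FOLDERS[folder]()
        except KeyError:
            raise ValueError(f"unknown folder backend {folder!r}")
    return folder


def fold(seq: str | SymbolString, folder="vienna") -> RNAStructure:
    """Fold one sequence to its single reported MFE / maximum-pairing structure."""
    return get_folder(folder).fold(str(seq))


# ---------------------------------------------------------------------------
# Exhaustive enumeration
# ---------------------------------------------------------------------------

def _load_checkpoint(path):
    with open(path) as fh:
        return json.load(fh)


def _save_checkpoint(path, state):
    tmp = str(path) + ".tmp"
    with open(tmp, "w") as fh:
        json.dump(state, fh)
    os.replace(tmp, path)


def _seq_bits(seqs: np.ndarray) -> np.ndarray:
    """Two-bit binary encoding of coded sequences (A=00, C=01, G=10, U=11)."""
    bits = np.empty((seqs.shape[0], 2 * seqs.shape[1]), dtype=np.uint8)
    bits[:, 0::2] = seqs >> 1
    bits[:, 1::2] = seqs & 1
    return bits


def enumerate_rna_map(
    L: int,
    folder="fallback",
    budget_seconds: float | None = None,
    checkpoint_path: str | None = None,
    input_scoring: str = "binary",
) -> EnumeratedMap:
    """Fold all 4^L sequences and build the output catalogue.

    Probabilities follow from neutral set sizes (P(x) = |f^-1(x)| / 4^L);
    output complexities are scored on the 2L-bit binary structure
    encodings.  Sequence (input) complexities are scored either on the
    2L-bit binary encoding of the sequence (``input_scoring='binary'``,
    the default: two description bits per base, same granularity as the
    structure scale) or directly on the 4-letter alphabet
    (``'nucleotide'``); both use scale range 2L bits.

    Long runs can be bounded by ``budget_seconds``: when exceeded, the
    aggregation state is checkpointed to ``checkpoint_path`` (required in
    that case) and :class:`ResumableInterrupt` is raised; re-invoking
    with the same arguments resumes from the checkpoint.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if input_scoring not in ("binary", "nucleotide"):
        raise ValueError("input_scoring must be 'binary' or 'nucleotide'")
    backend = get_folder(folder)
    total = 4 ** L
    t0 = time.monotonic()

    counts: dict[int, int] = {}
    in_max_raw: dict[int, float] = {}
    global_in_max = -math.inf
    start = 0
    if checkpoint_path and os.path.exists(checkpoint_path):
        state = _load_checkpoint(checkpoint_path)
        if state["L"] != L or state["backend"] != backend.name \
                or state.get("input_scoring") != input_scoring:
            raise ValueError("checkpoint does not match requested enumeration")
        counts = {int(k): v for k, v in state["counts"].items()}
        in_max_raw = {int(k): v for k, v in state["in_max_raw"].items()}
        global_in_max = state["global_in_max"]
        start = state["next_index"]
        logger.info("resuming RNA enumeration at %d/%d", start, total)

    use_batch = backend.name == "fallback"
    while start < total:
        stop = min(start + _CHUNK, total)
        if use_batch:
            codes, seqs = _fold_range(start, stop, L)
        else:
            codes = np.empty(stop - start, dtype=np.uint64)
            seqs = np.empty((stop - start, L), dtype=np.uint8)
            for r in range(stop - start):
                seq = _seq_from_index(start + r, L)
                db = backend.fold(seq).dotbracket
                code = 0
                for ch in db:
                    code = (code << 2) | (2 if ch == "(" else (1 if ch == ")" else 0))
                codes[r] = code
                seqs[r] = _seq_to_codes(seq)
        scored = _seq_bits(seqs) if input_scoring == "binary" else seqs
        raw = c_lz_batch(scored) if scored.shape[1] >= 2 else np.zeros(stop - start)
        global_in_max = max(global_in_max, float(raw.max()))
        distinct, inverse, cnt = np.unique(codes, return_inverse=True, return_counts=True)
        gmax = np.full(distinct.shape[0], -np.inf)
        np.maximum.at(gmax, inverse, raw)
        for d, c, g in zip(distinct.tolist(), cnt.tolist(), gmax.tolist()):
            counts[d] = counts.get(d, 0) + c
            if g > in_max_raw.get(d, -math.inf):
                in_max_raw[d] = g
        start = stop
        if budget_seconds is not None and time.monotonic() - t0 > budget_seconds and start < total:
            if checkpoint_path is None:
                raise ResumableInterrupt("<no checkpoint path given>", start, total)
            _save_checkpoint(checkpoint_path, dict(
                L=L, backend=backend.name, input_scoring=input_scoring,
                next_index=start,
                counts={str(k): v for k, v in counts.items()},
                in_max_raw={str(k): v for k, v in in_max_raw.items()},
                global_in_max=global_in_max,
            ))
            raise ResumableInterrupt(checkpoint_path, start, total)

    distinct = sorted(counts)
    dbs = [_code_to_dotbracket(c, L) for c in distinct]
    if len(dbs) > 1:
        enc = np.array([[int(b) for b in str(encode_dotbracket(db))] for db in dbs], dtype=np.uint8)
        out_raw = c_lz_batch(enc)
    else:
        out_raw = np.array([c_lz(str(encode_dotbracket(dbs[0])))])

    input_lo = math.log2(2 * L) if input_scoring == "binary" else (
        math.log2(L) if L >= 2 else 0.0)
    emap = build_catalog_from_groups(
        map_label=f"rna_L{L}_{backend.name}",
        output_strings=dbs,
        counts=np.array([counts[c] for c in distinct]),
        input_raw_max=np.array([in_max_raw[c] for c in distinct]),
        input_raw_lo=input_lo,
        input_raw_hi=global_in_max,
        input_bits=2.0 * L,
        output_raw_clz=out_raw,
        output_range_bits=2.0 * L,
        output_scale_min=math.log2(2 * L) if L >= 1 else 0.0,
        n_inputs=total,
        meta={"backend": backend.name, "backend_version": backend.version, "L": L,
              "input_scoring": input_scoring},
    )
    if checkpoint_path and os.path.exists(checkpoint_path):
        os.remove(checkpoint_path)
    return emap


# ---------------------------------------------------------------------------
# Structure population utilities
# ---------------------------------------------------------------------------

def valid_structures(L: int) -> Iterator[str]:
    """All well-formed dot-bracket strings of length L (hairpin loops >= 3).

    The recursion is on the first position: either unpaired, or paired
    with a partner at least MIN_HAIRPIN+1 positions away.
    """
    cache: dict[int, list[str]] = {0: [""]}

    def gen(n: int) -> list[str]:
        if n not in cache:
            out = ["." + r for r in gen(n - 1)]
            for j in range(MIN_HAIRPIN + 1, n):
                for inner in gen(j - 1):
                    for rest in gen(n - j - 1):
                        out.append("(" + inner + ")" + rest)
            cache[n] = out
        return cache[n]

    yield from gen(L)


def structure_calibration(L: int) -> tuple[float, float]:
    """(scale_min, scale_max) for 2L-bit structure encodings of length-L RNA.

    scale_min is the analytic floor log2(2L) (the all-dots open chain);
    scale_max the empirical maximum of C_LZ over the binary encodings of
    every well-formed structure of length L.
    """
    lo = math.log2(2 * L)
    enc = np.array(
        [[int(b) for b in str(encode_dotbracket(db))] for db in valid_structures(L)],
        dtype=np.uint8,
    )
    hi = float(c_lz_batch(enc).max())
    return lo, hi


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file; T is read as U."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper().replace("T", "U")))
    return out
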