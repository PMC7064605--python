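"""Output catalogues of exhaustively enumerated input-output maps.

Every enumerator in the package (RNA folding, transducer, perceptron,
toy maps) reduces to the same bookkeeping: map every input through f,
group inputs by output, and attach to each output x

* its neutral set size |f^-1(x)| and probability P(x) = |f^-1(x)| / N_I
  under uniform random sampling of inputs,
* the scaled complexity K~(x) of the output string (``k_out``),
* the maximum scaled complexity over its neutral set, K_max(p|n)
  (``k_max_input``), and the randomness deficit
  delta_max(x) = n - K_max(p|n) where n = ``input_bits``.

:func:`build_catalog` performs that bookkeeping from flat arrays;
:class:`EnumeratedMap` is the resulting container with TSV round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .complexity import calibrate_scaling, scaled_complexity, c_lz, DegenerateScalingError

__all__ = ["OutputRecord", "EnumeratedMap", "build_catalog", "build_catalog_from_groups",
           "input_complexity_stats", "enumerate_function_map", "ResumableInterrupt"]


class ResumableInterrupt(RuntimeError):
    """An enumeration ran out of budget; state was checkpointed for resumption.

    ``checkpoint_path`` names the saved state, ``done``/``total`` report
    progress.  Re-invoking the enumerator with the same checkpoint path
    resumes where it stopped.
    """

    def __init__(self, checkpoint_path, done: int, total: int):
        super().__init__(
            f"budget exhausted after {done}/{total} inputs; "
            f"checkpoint written to {checkpoint_path}"
        )
        self.checkpoint_path = checkpoint_path
        self.done = done
        self.total = total

#: columns of the catalogue table, in output order
CATALOG_COLUMNS = [
    "output", "neutral_set_size", "probability", "k_out", "k_max_input", "delta_max",
]


@dataclass(frozen=True)
class OutputRecord:
    """One output of an enumerated map with its probability and complexity stats."""

    output: str
    neutral_set_size: int
    probability: float
    k_out: float
    k_max_input: float
    delta_max: float


@dataclass
class EnumeratedMap:
    """Full output catalogue of a computable input-output map.

    ``table`` has one row per distinct output (columns
    :data:`CATALOG_COLUMNS`); ``meta`` records backend versions and the
    complexity-scaling constants so results are reproducible.
    """

    map_label: str
    n_inputs: int
    input_bits: float
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)
    complete: bool = True

    @property
    def n_outputs(self) -> int:
        return len(self.table)

    def records(self) -> list[OutputRecord]:
        return [OutputRecord(**row) for row in self.table[CATALOG_COLUMNS].to_dict("records")]

    def validate(self, atol: float = 1e-9) -> None:
        """Check the conservation and normalization invariants."""
        if self.complete and int(self.table["neutral_set_size"].sum()) != self.n_inputs:
            raise AssertionError("neutral set sizes do not sum to N_I")
        if abs(self.table["probability"].sum() - 1.0) > atol:
            raise AssertionError("probabilities do not sum to 1")
        if (self.table["neutral_set_size"] < 1).any():
            raise AssertionError("empty neutral set in catalogue")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, map_label: str, n_inputs: int, input_bits: float,
                 meta: dict | None = None) -> "EnumeratedMap":
        table = pd.read_csv(path, sep="\t", dtype={"output": str})
        return cls(map_label=map_label, n_inputs=n_inputs, input_bits=input_bits,
                   table=table, meta=meta or {})


def input_complexity_stats(
    neutral_set_k: Sequence[float] | np.ndarray,
    input_bits: float,
    complete: bool = True,
) -> tuple[float, float]:
    """K_max(p|n) and delta_max for one output's neutral set.

    ``neutral_set_k`` holds the scaled complexities of the inputs in the
    neutral set.  For a sampled (incomplete) neutral set the returned
    K_max is only a lower bound on the true maximum; callers flag that
    through ``complete=False`` on the catalogue.
    """
    ks = np.asarray(neutral_set_k, dtype=float)
    if ks.size == 0:
        raise ValueError("neutral set is empty")
    k_max = float(ks.max())
    return k_max, float(input_bits) - k_max


def _scale_or_floor(raw: np.ndarray, range_bits: float, scale_min: float | None = None):
    """Calibrate + rescale a C_LZ array; degenerate populations collapse to 0 bits.

    Returns (scaled array, scale_min, scale_max). When every string in
    the population has the same C_LZ (e.g. the one-output constant map)
    there is no range to calibrate; all strings sit at the floor and get
    0 bits, with the degenerate constants recorded as equal.
    """
    lo = float(raw.min()) if scale_min is None else scale_min
    hi = float(raw.max())
    if hi <= lo:
        return np.zeros_like(raw, dtype=float), lo, hi
    k = range_bits * (raw - lo) / (hi - lo)
    return np.clip(k, 0.0, range_bits), lo, hi


def build_catalog_from_groups(
    map_label: str,
    output_strings: Sequence[str],
    counts: np.ndarray,
    input_raw_max: np.ndarray,
    input_raw_lo: float,
    input_raw_hi: float,
    input_bits: float,
    output_raw_clz: np.ndarray,
    output_range_bits: float,
    output_scale_min: float | None = None,
    n_inputs: int | None = None,
    meta: dict | None = None,
    complete: bool = True,
) -> EnumeratedMap:
    """Assemble a catalogue from per-output aggregates.

    Used directly by checkpointed enumerators that aggregate counts and
    per-output maxima of the raw input C_LZ chunk by chunk instead of
    materialising one value per input.  ``input_raw_lo``/``input_raw_hi``
    are the calibration constants of the input complexity scale (floor
    and population maximum of C_LZ over all inputs).
    """
    counts = np.asarray(counts, dtype=np.int64)
    n_inputs = int(counts.sum()) if n_inputs is None else int(n_inputs)

    input_raw_max = np.asarray(input_raw_max, dtype=float)
    if input_raw_hi > input_raw_lo:
        k_max = np.clip(
            float(input_bits) * (input_raw_max - input_raw_lo) / (input_raw_hi - input_raw_lo),
            0.0, float(input_bits),
        )
    else:
        k_max = np.zeros_like(input_raw_max)
    delta_max = float(input_bits) - k_max

    out_raw = np.asarray(output_raw_clz, dtype=float)
    k_out, out_lo, out_hi = _scale_or_floor(out_raw, float(output_range_bits), output_scale_min)

    table = pd.DataFrame(
        {
            "output": list(output_strings),
            "neutral_set_size": counts,
            "probability": counts / n_inputs,
            "k_out": k_out,
            "k_max_input": k_max,
            "delta_max": delta_max,
        }
    ).sort_values("neutral_set_size", ascending=False, kind="mergesort").reset_index(drop=True)

    meta = dict(meta or {})
    meta.update(
        input_scale_min=input_raw_lo, input_scale_max=input_raw_hi,
        input_range_bits=float(input_bits),
        output_scale_min=out_lo, output_scale_max=out_hi,
        output_range_bits=float(output_range_bits),
    )
    emap = EnumeratedMap(
        map_label=map_label, n_inputs=n_inputs, input_bits=float(input_bits),
        table=table, meta=meta, complete=complete,
    )
    emap.validate()
    return emap


def build_catalog(
    map_label: str,
    output_ids: np.ndarray,
    output_strings: Callable[[np.ndarray], list[str]],
    output_raw_clz: Callable[[np.ndarray], np.ndarray],
    input_raw_clz: np.ndarray,
    input_bits: float,
    output_range_bits: float,
    input_scale_min: float | None = None,
    output_scale_min: float | None = None,
    meta: dict | None = None,
    complete: bool = True,
) -> EnumeratedMap:
    """Group per-input results into an :class:`EnumeratedMap`.

    Parameters
    ----------
    output_ids
        integer code of the output produced by each input (length N_I).
    output_strings
        maps an array of distinct output codes to their string forms.
    output_raw_clz
        maps an array of distinct output codes to their raw C_LZ values.
    input_raw_clz
        raw C_LZ of every input string (length N_I).
    input_bits
        n, the input description length in bits (range of the input
        complexity scale, so delta_max = n - K_max >= 0).
    output_range_bits
        range of the output complexity scale (output string length in bits).
    input_scale_min, output_scale_min
        optional analytic floors (log2 of string length); default is the
        empirical minimum over the respective population.
    """
    output_ids = np.asarray(output_ids)
    n_inputs = output_ids.shape[0]

    distinct, inverse, counts = np.unique(output_ids, return_inverse=True, return_counts=True)

    input_raw = np.asarray(input_raw_clz, dtype=float)
    in_lo = float(input_raw.min()) if input_scale_min is None else float(input_scale_min)
    in_hi = float(input_raw.max())
    raw_max = np.full(distinct.shape[0], -np.inf)
    np.maximum.at(raw_max, inverse, input_raw)

    return build_catalog_from_groups(
        map_label=map_label,
        output_strings=output_strings(distinct),
        counts=counts,
        input_raw_max=raw_max,
        input_raw_lo=in_lo,
        input_raw_hi=in_hi,
        input_bits=input_bits,
        output_raw_clz=np.asarray(output_raw_clz(distinct), dtype=float),
        output_range_bits=output_range_bits,
        output_scale_min=output_scale_min,
        n_inputs=n_inputs,
        meta=meta,
        complete=complete,
    )


def enumerate_function_map(
    map_label: str,
    fn: Callable[[np.ndarray], np.ndarray],
    n_bits: int,
) -> EnumeratedMap:
    """Enumerate a binary-string function f: {0,1}^n -> {0,1}^m through the standard path.

    ``fn`` receives a (N, n) uint8 bit matrix (one row per input, MSB
    first) and must return a (N, m) uint8 bit matrix of outputs.  Used
    by the toy maps and available for ad-hoc experiments.
    """
    from .complexity import c_lz_batch
    import math

    if n_bits > 24:
        raise ValueError("enumerate_function_map is for small n (<= 24 bits)")
    n = 1 << n_bits
    idx = np.arange(n, dtype=np.uint32)
    bits = ((idx[:, None] >> np.arange(n_bits - 1, -1, -1, dtype=np.uint32)) & 1).astype(np.uint8)
    out_bits = np.asarray(fn(bits), dtype=np.uint8)
    m = out_bits.shape[1]
    if m > 63:
        raise ValueError("output strings longer than 63 bits not supported here")
    weights = (1 << np.arange(m - 1, -1, -1, dtype=np.uint64))
    codes = (out_bits.astype(np.uint64) * weights).sum(axis=1)

    input_raw = c_lz_batch(bits)

    def strings(distinct):
        return [format(int(c), f"0{m}b") for c in distinct]

    def out_clz(distinct):
        arr = ((distinct[:, None].astype(np.uint64) >> weights_pow) & 1).astype(np.uint8)
        return c_lz_batch(arr)

    weights_pow = np.arange(m - 1, -1, -1, dtype=np.uint64)
    return build_catalog(
        map_label=map_label,
        output_ids=codes,
        output_strings=strings,
        output_raw_clz=out_clz,
        input_raw_clz=input_raw,
        input_bits=float(n_bits),
        output_range_bits=float(m),
        input_scale_min=math.log2(n_bits) if n_bits >= 2 else None,
        output_scale_min=math.log2(m) if m >= 2 else None,
    )
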