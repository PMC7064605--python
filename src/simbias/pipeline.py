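"""Experiment orchestration: enumerate a map, fit the bounds, emit tables.

An :class:`ExperimentConfig` fully determines a run (map choice and
parameters, complexity-scaling and fit options, seed, output directory,
budget); the config is serialized alongside every result so identical
config + seed reproduce identical outputs, modulo the folding-backend
version, which is recorded in the catalogue metadata.

:func:`run_experiment` writes into the output directory:

``catalog.tsv``        the output catalogue (one row per distinct output)
``bounds.tsv``         per-output bound quantities (P0, lower bound, Delta, q)
``cumulative.tsv``     the cumulative-probability curve and its reference
``fit.json``           fitted constants a, b, c0, c1, c2 and tolerances
``fig1.tsv``           probability vs output complexity, coloured by K_max(p|n)
``fig2.tsv``           deviation vs randomness deficit (optional grouping)
``fig3.tsv``           cumulative probability vs deviation
``data_dictionary.tsv``  one row per emitted column
``config.json``        the resolved configuration
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bounds as bounds_mod
from .bounds import UnderdeterminedFitError, cumulative_curve, evaluate_bounds, fit_upper_bound
from .catalog import EnumeratedMap
from .complexity import c_lz, complexity_value, lz76_word_count
from .fixtures import frozen_fixtures, make_toy_map
from .fst import enumerate_fst_map, machine_from_json, sample_machine
from .perceptron import enumerate_perceptron_map
from .rna import encode_dotbracket, enumerate_rna_map

logger = logging.getLogger("simbias")

__all__ = ["ExperimentConfig", "run_experiment", "fig_tables", "worked_example",
           "setup_logging"]


def setup_logging(log_file=None, level=logging.INFO) -> None:
    """Log to stderr and optionally to a file."""
    handlers = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    map: str = "rna"                      # rna | fst | perceptron | toy
    # rna
    length: int = 12
    folder: str = "fallback"
    input_scoring: str = "binary"
    # fst
    n_states: int = 5
    machine_json: str | None = None       # path; None -> sample from seed
    # perceptron
    n: int = 5
    k: int = 2
    threshold_convention: str = "strict"
    # toy
    toy_kind: str = "constant"
    # shared
    fit_method: str = "bin-maxima"
    fig2_group_by_p_and_k: bool = False
    render_plots: bool = False
    rng_seed: int = 0
    budget_seconds: float | None = None
    checkpoint: str | None = None
    outdir: str = "simbias-out"

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _enumerate(cfg: ExperimentConfig) -> EnumeratedMap:
    if cfg.map == "rna":
        return enumerate_rna_map(cfg.length, cfg.folder,
                                 budget_seconds=cfg.budget_seconds,
                                 checkpoint_path=cfg.checkpoint,
                                 input_scoring=cfg.input_scoring)
    if cfg.map == "fst":
        if cfg.machine_json:
            with open(cfg.machine_json) as fh:
                m = machine_from_json(json.load(fh))
        else:
            m = sample_machine(cfg.n_states, rng_seed=cfg.rng_seed)
        return enumerate_fst_map(m, cfg.length, budget_seconds=cfg.budget_seconds)
    if cfg.map == "perceptron":
        return enumerate_perceptron_map(cfg.n, cfg.k, cfg.threshold_convention)
    if cfg.map == "toy":
        _, emap = make_toy_map(cfg.toy_kind, cfg.length)
        return emap
    raise ValueError(f"unknown map {cfg.map!r}")


_DATA_DICTIONARY = [
    ("catalog.tsv", "output", "output string (dot-bracket / binary / truth table)"),
    ("catalog.tsv", "neutral_set_size", "|f^-1(x)|, number of inputs mapping to the output"),
    ("catalog.tsv", "probability", "P(x) = |f^-1(x)| / N_I"),
    ("catalog.tsv", "k_out", "scaled output complexity K~(x), bits"),
    ("catalog.tsv", "k_max_input", "K_max(p|n): max scaled complexity over the neutral set, bits"),
    ("catalog.tsv", "delta_max", "randomness deficit n - K_max(p|n), bits"),
    ("bounds.tsv", "p0", "upper-bound probability P0(x) = 2^(-a k_out - b)"),
    ("bounds.tsv", "lower_bound", "P0 * 2^(-delta_max + c0)"),
    ("bounds.tsv", "deviation_bits", "Delta = log2 P0 - log2 P, bits below the upper bound"),
    ("bounds.tsv", "predicted_prob", "normalized predictor q(x) ~ 2^(-a k_out - delta_max)"),
    ("bounds.tsv", "zero_prob_flag", "true when P(x) is a zero estimate (sampled runs only)"),
    ("cumulative.tsv", "delta_grid", "deviation threshold Delta, bits"),
    ("cumulative.tsv", "cumulative_prob", "sum of P(x) over outputs with deviation >= Delta"),
    ("cumulative.tsv", "bound_curve", "reference curve 2^(-Delta+1)"),
    ("fig1.tsv", "k_out", "x-axis: scaled output complexity, bits"),
    ("fig1.tsv", "log2_probability", "y-axis: log2 P(x)"),
    ("fig1.tsv", "k_max_input", "colour: K_max(p|n), bits"),
    ("fig2.tsv", "delta_max", "x-axis: randomness deficit, bits"),
    ("fig2.tsv", "deviation_bits", "y-axis: Delta, bits"),
    ("fig2.tsv", "k_out", "colour: output complexity, bits"),
    ("fig3.tsv", "delta_grid", "x-axis: Delta, bits"),
    ("fig3.tsv", "cumulative_prob", "y-axis: cumulative probability"),
    ("fig3.tsv", "bound_curve", "reference 2^(-Delta+1)"),
]


def fig_tables(emap: EnumeratedMap, evaluation, curve,
               fig2_group_by_p_and_k: bool = False) -> dict[str, pd.DataFrame]:
    """Plot-ready tables with exactly the plotted quantities of the three figure families."""
    t = evaluation.table
    fig1 = pd.DataFrame({
        "output": t["output"],
        "k_out": t["k_out"],
        "log2_probability": np.log2(t["probability"]),
        "k_max_input": t["k_max_input"],
    })
    if fig2_group_by_p_and_k:
        g = (t.groupby(["probability", "k_out"], as_index=False)
               .agg(delta_max=("delta_max", "mean"),
                    deviation_bits=("deviation_bits", "mean"),
                    n_outputs=("output", "size")))
        fig2 = g[["delta_max", "deviation_bits", "k_out", "probability", "n_outputs"]]
    else:
        fig2 = t[["output", "delta_max", "deviation_bits", "k_out"]].copy()
    fig3 = pd.DataFrame({
        "delta_grid": curve.delta_grid,
        "cumulative_prob": curve.cumulative_prob,
        "bound_curve": curve.bound_curve,
    })
    return {"fig1": fig1, "fig2": fig2, "fig3": fig3}


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Enumerate, fit, evaluate and write the result bundle; returns it in memory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    logger.info("enumerating %s map", cfg.map)
    emap = _enumerate(cfg)
    logger.info("%d outputs from %d inputs (%.1f s)", emap.n_outputs, emap.n_inputs,
                time.monotonic() - t0)

    bundle: dict = {"map": emap, "config": cfg}
    emap.to_tsv(outdir / "catalog.tsv")
    with open(outdir / "catalog_meta.json", "w") as fh:
        json.dump(dict(map_label=emap.map_label, n_inputs=emap.n_inputs,
                       input_bits=emap.input_bits, complete=emap.complete,
                       **emap.meta), fh, indent=2)
    cfg.to_json(outdir / "config.json")

    try:
        fit = fit_upper_bound(emap, cfg.fit_method)
    except UnderdeterminedFitError as exc:
        # trivial maps (e.g. the constant toy map) admit no envelope fit
        logger.warning("bound fit skipped: %s", exc)
        with open(outdir / "fit.json", "w") as fh:
            json.dump({"fit_skipped": str(exc)}, fh, indent=2)
        pd.DataFrame(_DATA_DICTIONARY, columns=["file", "column", "meaning"]).to_csv(
            outdir / "data_dictionary.tsv", sep="\t", index=False)
        return bundle

    evaluation = evaluate_bounds(emap, fit)
    curve = cumulative_curve(emap, evaluation)
    bundle.update(fit=fit, evaluation=evaluation, curve=curve)

    evaluation.table.to_csv(outdir / "bounds.tsv", sep="\t", index=False)
    pd.DataFrame({
        "delta_grid": curve.delta_grid,
        "cumulative_prob": curve.cumulative_prob,
        "bound_curve": curve.bound_curve,
    }).to_csv(outdir / "cumulative.tsv", sep="\t", index=False)
    bounds_mod.fit_summary_json(evaluation, curve, outdir / "fit.json")

    figs = fig_tables(emap, evaluation, curve, cfg.fig2_group_by_p_and_k)
    for name, df in figs.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    bundle["figs"] = figs
    if cfg.render_plots:
        from .plots import render_figures
        render_figures(figs, outdir)

    pd.DataFrame(_DATA_DICTIONARY, columns=["file", "column", "meaning"]).to_csv(
        outdir / "data_dictionary.tsv", sep="\t", index=False)
    logger.info("experiment complete in %.1f s -> %s", time.monotonic() - t0, outdir)
    return bundle


def worked_example(catalog_tsv=None) -> dict:
    """The two symmetric length-15 structures with equal complexity but very different probability.

    Computes the binary encodings, LZ phrase counts, C_LZ and the scaled
    complexity under the frozen calibration.  Neutral set sizes and the
    probability ratio P(S2)/P(S1) require a completed exhaustive L=15
    catalogue; pass its TSV path to fill them in.
    """
    fx = frozen_fixtures()
    cal = fx["calibration"]
    out = {"calibration": cal}
    for name in ("s1", "s2"):
        s = fx[name]
        enc = str(encode_dotbracket(s))
        cv = complexity_value(enc, cal["range_bits"], cal["scale_min"], cal["scale_max"])
        out[name] = dict(
            dotbracket=s.dotbracket,
            encoding=enc,
            n_words_forward=cv.n_words_forward,
            n_words_reverse=cv.n_words_reverse,
            c_lz=cv.c_lz,
            k_scaled=cv.k_scaled,
        )
    if catalog_tsv is not None:
        cat = pd.read_csv(catalog_tsv, sep="\t", dtype={"output": str})
        lut = cat.set_index("output")
        for name in ("s1", "s2"):
            db = out[name]["dotbracket"]
            if db in lut.index:
                out[name]["neutral_set_size"] = int(lut.loc[db, "neutral_set_size"])
                out[name]["probability"] = float(lut.loc[db, "probability"])
        if "probability" in out["s1"] and "probability" in out["s2"]:
            out["probability_ratio_s2_over_s1"] = (
                out["s2"]["probability"] / out["s1"]["probability"])
    return out
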