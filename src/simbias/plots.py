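"""Optional rendering of the three standard figure families.

Axes mirror the analysis conventions: probabilities on a log2 scale,
complexities and deviations in bits.  matplotlib is imported lazily so
the rest of the package works without it.
"""

from __future__ import annotations

from pathlib import Path

__all__ = ["render_figures"]


def render_figures(figs: dict, outdir, prefix: str = "") -> list:
    """Render fig1/fig2/fig3 tables to PNG files; returns the written paths."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("plot rendering requires matplotlib") from exc

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    if "fig1" in figs:
        f1 = figs["fig1"]
        fig, ax = plt.subplots(figsize=(5, 4))
        sc = ax.scatter(f1["k_out"], f1["log2_probability"], c=f1["k_max_input"],
                        s=14, cmap="viridis")
        fig.colorbar(sc, ax=ax, label="K_max(p|n) (bits)")
        ax.set_xlabel("output complexity K~(x) (bits)")
        ax.set_ylabel("log2 P(x)")
        path = outdir / f"{prefix}fig1.png"
        fig.tight_layout(); fig.savefig(path, dpi=150); plt.close(fig)
        written.append(path)

    if "fig2" in figs:
        f2 = figs["fig2"]
        fig, ax = plt.subplots(figsize=(5, 4))
        sc = ax.scatter(f2["delta_max"], f2["deviation_bits"], c=f2["k_out"],
                        s=14, cmap="viridis")
        fig.colorbar(sc, ax=ax, label="K~(x) (bits)")
        lim = max(float(f2["delta_max"].max()), float(f2["deviation_bits"].max()), 1.0)
        ax.plot([0, lim], [0, lim], "k-", lw=1)  # slope-1 prediction
        ax.set_xlabel("randomness deficit delta_max(x) (bits)")
        ax.set_ylabel("deviation Delta(x) (bits)")
        path = outdir / f"{prefix}fig2.png"
        fig.tight_layout(); fig.savefig(path, dpi=150); plt.close(fig)
        written.append(path)

    if "fig3" in figs:
        f3 = figs["fig3"]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.semilogy(f3["delta_grid"], f3["cumulative_prob"], "o-", ms=3,
                    label="cumulative P")
        ax.semilogy(f3["delta_grid"], f3["bound_curve"], "r-", lw=1,
                    label="2^(-Delta+1)")
        ax.axhline(0.1, ls="--", c="gray", lw=1)
        ax.set_xlabel("Delta (bits)")
        ax.set_ylabel("cumulative probability")
        ax.legend()
        path = outdir / f"{prefix}fig3.png"
        fig.tight_layout(); fig.savefig(path, dpi=150); plt.close(fig)
        written.append(path)

    return written
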