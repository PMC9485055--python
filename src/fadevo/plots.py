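"""Optional diagnostic plots (matplotlib).  Import is deferred so the core
library does not require a plotting backend."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def plot_hgt_screen(cub_table: pd.DataFrame, out_dir: Path) -> list[Path]:
    """ENc-GC3s plot with Wright's curve and a PR2 plot; returns written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .codon_usage import enc_expected

    written = []
    fig, ax = plt.subplots(figsize=(5, 4))
    s = np.linspace(0.01, 0.99, 200)
    ax.plot(s, [enc_expected(x) for x in s], "k-", lw=1, label="mutation-only expectation")
    for label, marker in (("background", "."), ("family", "^")):
        sub = cub_table[cub_table["set"] == label]
        ax.scatter(sub["gc3s"], sub["enc"], marker=marker, s=18, label=label)
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENc")
    ax.legend(fontsize=8)
    path = out_dir / "enc_gc3s.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(4.2, 4))
    for label, marker in (("background", "."), ("family", "^")):
        sub = cub_table[cub_table["set"] == label]
        ax.scatter(sub["pr2_gc_bias"], sub["pr2_at_bias"], marker=marker, s=18, label=label)
    ax.axhline(0.5, color="k", lw=0.5)
    ax.axvline(0.5, color="k", lw=0.5)
    ax.set_xlabel("G3 / (G3 + C3)")
    ax.set_ylabel("A3 / (A3 + T3)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    path = out_dir / "pr2.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(path)
    return written
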