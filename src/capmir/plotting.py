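"""Optional plot exports mirroring the standard report figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_length_distribution", "plot_expression_scatter"]

_SCATTER_COLORS = {"fold>2": "red", "1/2<fold<=2": "blue", "fold<=1/2": "green"}


def plot_length_distribution(dist: dict, path: str | Path) -> None:
    """Bar plot of the read-length distribution."""
    items = sorted(dist.items(), key=lambda kv: str(kv[0]))
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar([str(k) for k, _ in items], [v for _, v in items], color="steelblue")
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("fraction of reads")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_expression_scatter(de_frame: pd.DataFrame, path: str | Path) -> None:
    """log-log NE scatter coloured by fold-change class."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for cls, color in _SCATTER_COLORS.items():
        sub = de_frame[de_frame.scatter_class == cls]
        ax.scatter(sub.ne2, sub.ne1, s=6, c=color, label=cls, alpha=0.6)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("NE, six-month library (TPM)")
    ax.set_ylabel("NE, fetal library (TPM)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
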