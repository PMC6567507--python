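"""Optional figure output (matplotlib, Agg backend): expression heat map
and degradome t-plots."""
from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def heatmap(log_expr, path, title="miRNA expression (log2 RPM + 1)") -> None:
    """Simple miRNA x library heat map of log2(RPM+1) values."""
    plt = _plt()
    data = np.asarray(log_expr, dtype=float)
    fig, ax = plt.subplots(
        figsize=(max(6, 0.25 * data.shape[1]), max(4, 0.12 * data.shape[0]))
    )
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r", interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.6)
    ax.set_title(title)
    ax.set_xlabel("library")
    ax.set_ylabel("miRNA")
    try:
        ax.set_xticks(range(data.shape[1]))
        ax.set_xticklabels(list(log_expr.columns), rotation=90, fontsize=5)
    except AttributeError:
        pass
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def tplot(profile, cleavage_pos_1based: int, path, mirna: str = "") -> None:
    """Target plot: degradome 5'-end abundance by transcript position with
    the predicted cleavage site highlighted."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(7, 3))
    pos = np.arange(1, profile.length + 1)
    ax.vlines(pos, 0, profile.abundance, color="grey", lw=1)
    c = cleavage_pos_1based
    ax.vlines([c], 0, [profile.abundance[c - 1]], color="red", lw=2)
    ax.plot([c], [profile.abundance[c - 1]], "rv")
    ax.set_xlabel(f"position on {profile.transcript_id}")
    ax.set_ylabel("degradome 5'-end reads")
    if mirna:
        ax.set_title(f"{mirna} -> {profile.transcript_id} (cleavage at {c})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
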