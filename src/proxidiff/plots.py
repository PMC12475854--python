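"""Optional plot helpers (volcano). Requires matplotlib (``proxidiff[plot]``)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def volcano(table: pd.DataFrame, ax=None, label_top: int = 0):
    """t-test difference vs -log10(p), hits highlighted.

    Returns the matplotlib Axes.  Presentation only; no statistics here.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = table["diff_log2"].to_numpy()
    y = -np.log10(np.clip(table["p_welch"].to_numpy(), 1e-300, None))
    hit = table["hit"].to_numpy(dtype=bool)
    ax.scatter(x[~hit], y[~hit], s=6, c="0.6", alpha=0.5, linewidths=0)
    ax.scatter(x[hit], y[hit], s=8, c="crimson", alpha=0.8, linewidths=0)
    ax.set_xlabel("t-test difference (log2 bait - control)")
    ax.set_ylabel("-log10 Welch p")
    if label_top:
        top = table[hit].nlargest(label_top, "z")
        for _, row in top.iterrows():
            ax.annotate(row["gene"] or row["protein_id"], (row["diff_log2"],
                        -np.log10(max(row["p_welch"], 1e-300))), fontsize=6)
    return ax
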