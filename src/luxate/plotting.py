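"""Diagnostic plots for extracted features."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_torque_scatter(features: pd.DataFrame, path: str | Path | None = None):
    """Summed vs. average combined torque, one point per experiment.

    The classic two-feature view of a dataset: posterior teeth sit at
    high summed torque, lower-jaw dorsal teeth at high average torque.
    Returns the matplotlib Axes; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for label, group in features.groupby("label"):
        ax.scatter(
            group["torque_auc_all"], group["torque_avg_all"], label=str(label), s=18
        )
    ax.set_xlabel("summed combined torque (Nms)")
    ax.set_ylabel("average combined torque (Nm)")
    ax.legend(title="label", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
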