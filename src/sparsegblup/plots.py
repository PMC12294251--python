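"""Bar-chart panels of prediction accuracy by testing proportion."""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_summary"]

_METRICS = [("COR", "COR"), ("PM_10", "PM$_{10}$ (%)"), ("PM_20", "PM$_{20}$ (%)")]


def plot_summary(
    summary: pd.DataFrame,
    dataset: str,
    out_path: str | os.PathLike,
    env_or_across: str = "across_envs",
) -> str:
    """One three-panel figure (COR, PM_10, PM_20 vs testing proportion) for a
    dataset, grouped bars per model with standard-error bars."""
    sub = summary[
        (summary["dataset"] == dataset)
        & (summary["env_or_across"] == env_or_across)
    ]
    if sub.empty:
        raise ValueError(f"no summary rows for dataset {dataset!r}")
    models = sorted(sub["model"].unique())
    props = sorted(sub["tst_prop"].unique())
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    width = 0.8 / len(models)
    x = np.arange(len(props))
    for ax, (metric, label) in zip(axes, _METRICS):
        for k, model in enumerate(models):
            rows = sub[sub["model"] == model].set_index("tst_prop")
            means = [rows[f"{metric}_mean"].get(p, np.nan) for p in props]
            ses = [rows.get(f"{metric}_se", pd.Series(dtype=float)).get(p, np.nan)
                   for p in props]
            ax.bar(x + k * width, means, width, yerr=ses, capsize=3, label=model)
        ax.set_xticks(x + width * (len(models) - 1) / 2)
        ax.set_xticklabels([f"{p:g}" for p in props])
        ax.set_xlabel("Testing proportion (Tst)")
        ax.set_ylabel(label)
    axes[0].legend(frameon=False, fontsize=8)
    fig.suptitle(dataset)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return str(out_path)
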