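"""Figure helpers: OCCC / C-index heat maps and Kaplan-Meier curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def occc_heatmap(occc_report: pd.DataFrame, path: str | Path) -> None:
    """Feature x test heat map of OCCC values (high-order battery)."""
    ho = occc_report[occc_report["family"] != "firstorder"]
    if ho.empty:
        return
    pivot = ho.pivot_table(index="feature",
                           columns=["varied_parameter", "fixed_setting"],
                           values="occc")
    fig, ax = plt.subplots(figsize=(10, max(4, 0.02 * len(pivot))))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="RdYlGn_r",
                   vmin=-1, vmax=1)
    ax.set_xlabel("OCCC test (varied parameter x fixed setting)")
    ax.set_ylabel("high-order feature")
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="OCCC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def km_plot(result, path: str | Path, title: str = "") -> None:
    """Kaplan-Meier curves of the low-/high-risk groups of one cohort."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, (t, s) in result.km_curves.items():
        ax.step(t, s, where="post", label=f"{name} risk")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    txt = f"G-rho p = {result.logrank_p:.3g}, HR = {result.hazard_ratio:.2f}"
    ax.set_title(f"{title}\n{txt}" if title else txt)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
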