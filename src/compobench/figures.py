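"""Optional heatmap rendering over the summary TSVs.

Thin plotting layer: effect size x proportion grids of scenario-mean
error rates, their deltas against relative abundance, and R² deltas
against the log-Pearson distance. The TSVs are the numerical contract;
these panels only visualize them.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns


def _grid(sub: pd.DataFrame, value: str) -> pd.DataFrame:
    wide = sub.pivot_table(index="effect_size", columns="proportion", values=value)
    return wide.sort_index(ascending=False)


def _heatmap_panels(df: pd.DataFrame, value: str, title: str, path: Path, center=None) -> None:
    methods = sorted(df["method"].unique())
    fig, axes = plt.subplots(1, len(methods), figsize=(4 * len(methods), 3.2), squeeze=False)
    for ax, method in zip(axes[0], methods):
        sns.heatmap(
            _grid(df[df["method"] == method], value),
            ax=ax,
            annot=True,
            fmt=".2f",
            cbar=False,
            center=center,
            cmap="vlag" if center is not None else "rocket_r",
        )
        ax.set_title(method)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_all(in_dir: str | Path, out_dir: str | Path) -> list[Path]:
    """Render every available summary grid; returns the written paths."""
    in_dir = Path(in_dir)
    out = Path(out_dir) / "figures"
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary = in_dir / "summary"

    scen = pd.read_csv(summary / "scenario_error_means.tsv", sep="\t")
    for value, label in (("fp_rate", "false positives"), ("fn_rate", "false negatives")):
        path = out / f"{value}_grid.png"
        _heatmap_panels(scen, value, f"Scenario-mean {label}", path)
        written.append(path)

    delta = pd.read_csv(summary / "delta_vs_relative.tsv", sep="\t")
    if not delta.empty:
        for value in ("delta_fp", "delta_fn"):
            path = out / f"{value}_vs_relative.png"
            _heatmap_panels(delta, value, f"{value} vs relative abundance", path, center=0.0)
            written.append(path)

    dr2 = pd.read_csv(summary / "delta_r2.tsv", sep="\t")
    if not dr2.empty:
        path = out / "delta_r2_vs_log_pearson.png"
        _heatmap_panels(dr2, "delta_r2", "R² minus log-Pearson R²", path, center=0.0)
        written.append(path)
    return written
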