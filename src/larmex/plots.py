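"""Optional matplotlib views of recovery results (CI ladders, REE curves)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_ci_ladder(report, params: list[str] | None = None, path=None):
    """Confidence-interval ladders: one panel per parameter, one rung per
    number of days, line styles by noise level."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = report.table
    params = params or sorted(t["param"].unique())
    fig, axes = plt.subplots(1, len(params), figsize=(2.4 * len(params), 3.2),
                             sharey=True, squeeze=False)
    for ax, param in zip(axes[0], params):
        sub = t[t["param"] == param]
        for i, (sigma2, grp) in enumerate(sub.groupby("sigma2")):
            grp = grp.sort_values("n_days")
            y = grp["n_days"] + 0.5 * i
            ax.hlines(y, grp["lo"], grp["hi"], label=f"sigma2={sigma2}")
            ax.plot(grp["median"], y, "x", color="k", ms=4)
        ax.set_title(param, fontsize=9)
        ax.set_xlabel("estimate")
    axes[0][0].set_ylabel("number of days")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(Path(path))
        plt.close(fig)
    return fig


def plot_ree_curves(summary: pd.DataFrame, columns=("fixed_all", "blup_all"),
                    by: str = "k", path=None):
    """Relative-estimation-error curves against the number of days."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.4))
    styles = {"fixed_all": "-", "blup_all": "--"}
    for key, grp in summary.groupby(by):
        grp = grp.sort_values("n_days")
        for col in columns:
            ax.plot(grp["n_days"], grp[col], styles.get(col, "-"),
                    marker="o", ms=3, label=f"{by}={key} {col}")
    ax.set_xlabel("number of days")
    ax.set_ylabel("median REE")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(Path(path))
        plt.close(fig)
    return fig
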