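"""QQ and power plots for simulation studies (matplotlib is optional)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def qq_plot(pvalues: pd.DataFrame, path) -> None:
    """Uniform QQ plot of -log10 p-values, one series per method column."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name in pvalues.columns:
        p = np.sort(pvalues[name].dropna().to_numpy())
        if p.size == 0:
            continue
        exp = -np.log10((np.arange(p.size) + 0.5) / p.size)
        ax.plot(exp, -np.log10(np.clip(p, 1e-300, 1)), ".", ms=3, label=name)
    lim = ax.get_xlim()[1]
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def power_plot(power_table: pd.DataFrame, path) -> None:
    """Grouped bar chart of power per scenario and method with binomial SE."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scenarios = list(dict.fromkeys(power_table["scenario"]))
    methods = list(dict.fromkeys(power_table["method"]))
    width = 0.8 / len(methods)
    fig, ax = plt.subplots(figsize=(1.2 + 1.2 * len(scenarios), 3.5))
    for j, m in enumerate(methods):
        sub = power_table[power_table["method"] == m].set_index("scenario")
        x = np.arange(len(scenarios)) + j * width
        ax.bar(x, sub.loc[scenarios, "power"], width, yerr=sub.loc[scenarios, "se"], label=m)
    ax.set_xticks(np.arange(len(scenarios)) + 0.4 - width / 2)
    ax.set_xticklabels(scenarios)
    ax.set_ylabel("power")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
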