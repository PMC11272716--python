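"""Optional plotting helpers (requires matplotlib, `pip install grouprax[plots]`)."""

from __future__ import annotations

import pandas as pd


def plot_percent_significant(summaries: dict[str, pd.DataFrame], ax=None):
    """Grouped bar chart of percent-significant features per treatment.

    ``summaries`` maps layer name to the tidy frame returned by
    :func:`grouprax.perturbation.percent_significant`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 4))
    tidy = pd.concat(summaries.values(), ignore_index=True)
    tidy["group"] = (
        tidy["substance"] + "/" + tidy["dose_level"] + "/" + tidy["time_point"].fillna("")
    )
    layers = list(summaries)
    width = 0.8 / len(layers)
    groups = tidy["group"].unique()
    pos = {g: i for i, g in enumerate(groups)}
    for k, layer in enumerate(layers):
        sub = tidy[tidy["layer"] == layer]
        ax.bar(
            [pos[g] + k * width for g in sub["group"]],
            sub["percent"],
            width=width,
            label=layer,
        )
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels(groups, rotation=90, fontsize=6)
    ax.set_ylabel("% features with p < alpha")
    ax.legend()
    return ax
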