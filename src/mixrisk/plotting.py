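"""Percent-of-control bar plots with significance marks.

Optional: requires matplotlib (``pip install mixrisk[plot]``).
"""

from __future__ import annotations


def plot_percent_of_control(reports: dict, endpoint: str = "reproduction", ax=None):
    """Bar plot of one endpoint's percent-of-control per treatment.

    ``reports`` is the output of :func:`mixrisk.stats.analyze_test`;
    significant treatments are marked with an asterisk.  Returns the axis.
    """
    import matplotlib.pyplot as plt

    rep = reports[endpoint]
    table = rep.table
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(table), 3.2))
    bars = ax.bar(table["treatment"], table["percent_of_control"], color="#4878a8")
    for bar, sig in zip(bars, table["significant"]):
        if sig:
            ax.annotate("*", (bar.get_x() + bar.get_width() / 2, bar.get_height()),
                        ha="center", va="bottom", fontsize=14)
    ax.axhline(100.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel(f"{endpoint} (% of {rep.control_used} control)")
    ax.set_ylim(bottom=0)
    return ax
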