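"""Cumulative-failure chart rendering (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_cusum_chart"]


def plot_cusum_chart(chart: pd.DataFrame, trainee_id: str, ax=None):
    """Plot one trainee's cumulative failures with the two control lines.

    ``chart`` is the table produced by ``chart_table``: columns
    attempt_no, cum_failures, h0, h1.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.step(
        chart["attempt_no"],
        chart["cum_failures"],
        where="post",
        label="cumulative failures",
        color="black",
    )
    ax.plot(chart["attempt_no"], chart["h0"], "--", color="tab:green",
            label="h0 (acceptable)")
    ax.plot(chart["attempt_no"], chart["h1"], "--", color="tab:red",
            label="h1 (unacceptable)")
    ax.set_xlabel("attempt number")
    ax.set_ylabel("cumulative failures")
    ax.set_title(f"CUSUM chart — trainee {trainee_id}")
    ax.legend(loc="upper left", fontsize=8)
    return ax
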