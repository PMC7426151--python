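"""Optional figures: TD distributions, resampling nulls, threshold sweeps."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .td import ResamplingNull  # noqa: E402

__all__ = ["plot_td_by_class", "plot_resampling_null", "plot_sweep"]


def plot_td_by_class(td_tables: dict, ax=None):
    """Violin plot of log2 TD ratio by duplicate class for one or more
    backgrounds (keys label the panels/groups)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 + 1.5 * len(td_tables) * 2, 4))
    data, labels = [], []
    for name, tdt in td_tables.items():
        for cls, sub in tdt.groupby("class"):
            vals = np.log2(sub["td_ratio"].to_numpy())
            vals = vals[np.isfinite(vals)]
            if len(vals):
                data.append(vals)
                labels.append(f"{name}\n{cls}")
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(labels) + 1), labels, fontsize=8)
    ax.set_ylabel("log2 TD ratio")
    return ax


def plot_resampling_null(null: ResamplingNull, ax=None):
    """Null histogram with a normal overlay and the observed mean marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.hist(null.null, bins=40, density=True, alpha=0.6)
    mu, sd = null.null_mean, null.null_sd
    if sd > 0:
        x = np.linspace(mu - 4 * sd, mu + 4 * sd, 200)
        ax.plot(x, np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi)))
    ax.axvline(null.observed, color="red", label=f"observed (p={null.p:.3g})")
    ax.set_xlabel("null mean")
    ax.legend()
    return ax


def plot_sweep(sweep, ax=None, direction: str = "up"):
    """Enrichment p against the TD threshold tau, one line per duplicate class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sub = sweep[(sweep["direction"] == direction) & ~sweep["undefined"]]
    for cls, grp in sub.groupby("class"):
        ax.plot(grp["tau"], -np.log10(grp["p"].clip(lower=1e-300)), marker="o", label=cls)
    ax.set_xlabel("TD threshold tau")
    ax.set_ylabel("-log10 enrichment p")
    ax.legend()
    return ax
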