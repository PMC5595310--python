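"""Minimal optional plotting helpers (requires matplotlib, extra ``plot``)."""

from __future__ import annotations

from .diagnostics import loess_trend
from .index import CTISeries

__all__ = ["plot_cti_trend"]

_COLORS = {
    "original": "tab:green",
    "modelled": "tab:blue",
    "modelled_uncorrected": "tab:gray",
    "presence_absence": "tab:purple",
    "true": "tab:red",
}


def plot_cti_trend(*series: CTISeries, span: float = 0.75, degree: int = 2, ax=None):
    """Scatter each CTI series with its loess trend and 95% band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for s in series:
        color = _COLORS.get(s.variant)
        ax.plot(s.values.index, s.values, "o", ms=3, color=color, alpha=0.6)
        sm = loess_trend(s, span=span, degree=degree)
        ax.plot(sm["year"], sm["fit"], color=color, label=s.variant)
        ax.fill_between(sm["year"], sm["lo"], sm["hi"], color=color, alpha=0.15, lw=0)
    ax.set_xlabel("year")
    ax.set_ylabel("CTI (°C)")
    ax.legend(frameon=False)
    return ax
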