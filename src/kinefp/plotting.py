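"""Quick-look plots for traces, idealizations and Fano curves.

Matplotlib is imported lazily so headless pipelines pay no import cost.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_trace", "plot_fano"]


def plot_trace(trace, ideal=None, ax=None):
    """Intensity versus time, optionally overlaid with the idealized path."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    ax.plot(trace.time, trace.intensity, lw=0.5, color="0.4", label="intensity")
    if ideal is not None:
        ax.plot(
            trace.time, ideal.means[ideal.states], lw=1.2, color="crimson",
            label="idealization",
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("counts")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_fano(results, ax=None, label=None, **kwargs):
    """Fano factor versus window length with the 95% Poisson band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    T = [r.T for r in results]
    ax.plot(T, [r.fano for r in results], "s-", label=label, **kwargs)
    ax.fill_between(
        T, [r.ci_low for r in results], [r.ci_high for r in results],
        alpha=0.15, color="0.3", label="95% Poisson band",
    )
    ax.axhline(1.0, color="0.5", ls="--", lw=0.8)
    ax.set_xlabel("window T (s)")
    ax.set_ylabel("Fano factor")
    if label:
        ax.legend()
    return ax
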