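"""Planning and screening figures (matplotlib)."""
from __future__ import annotations

import numpy as np

from .design import cycles_vs_size_curve
from .screening import DoseResponseResults


def plot_cycles_vs_size(rates=(3.4e-5, 1.0e-4), n_range=(100, 3000), p: float = 1.0,
                        ax=None, labels=None):
    """Cycles required to reach p mutations per copy, versus target-gene size.

    One curve per rate; slower rates sit strictly above faster ones for every
    size. Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    n_values = np.linspace(n_range[0], n_range[1], 200)
    styles = ["--", "-", "-.", ":"]
    for i, m in enumerate(sorted(rates)):
        label = labels[i] if labels else f"m = {m:.2g}/nt/cycle"
        ax.plot(n_values, cycles_vs_size_curve(m, n_values, p),
                styles[i % len(styles)], label=label)
    ax.set_xlabel("target gene size (nt)")
    ax.set_ylabel(f"cycles to {p:g} mutation(s) per copy")
    ax.legend()
    return ax


def plot_dose_response(results: dict[str, DoseResponseResults], ax=None):
    """Fitted viability curves with the observed points, log-x."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, res in results.items():
        conc = res.model.conc
        pos = conc[conc > 0]
        grid = np.geomspace(pos.min(), pos.max(), 200)
        line, = ax.plot(grid, res.predict(grid), label=name)
        ax.plot(conc[conc > 0], res.model.viability[conc > 0], "o",
                color=line.get_color(), ms=4)
        if res.converged:
            ax.axvline(res.ic50, color=line.get_color(), lw=0.8, ls=":")
    ax.set_xscale("log")
    ax.set_xlabel("Gemcitabine (nM)")
    ax.set_ylabel("viability fraction")
    ax.legend()
    return ax
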