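"""Plot prior, likelihood and posterior densities with the interval shaded."""

from __future__ import annotations

import numpy as np


def plot_distributions(results, ax=None, shade_ci: bool = True):
    """Overlay the prior, likelihood and posterior of a fitted result.

    Masses are rescaled to densities (mass / grid step) so curves are
    comparable across grid resolutions.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    grid = results.posterior.grid
    x = grid.tmb_values
    step = grid.step
    if results.prior.kind != "flat":
        ax.plot(x, results.prior.probs / step, label="prior", color="tab:blue", lw=1)
    ax.plot(
        x, results.likelihood.probs / step,
        label="likelihood", color="tab:orange", lw=1, ls="--",
    )
    ax.plot(x, results.posterior.probs / step, label="posterior", color="tab:red", lw=1.5)
    if shade_ci:
        lo, hi = results.ci_low, results.ci_high
        mask = (x >= lo) & (x <= hi)
        ax.fill_between(
            x[mask], 0, results.posterior.probs[mask] / step,
            alpha=0.3, color="tab:red",
            label=f"central {results.report.ci_level:.0%} interval",
        )
    ax.axvline(results.report.threshold, color="gray", ls=":", lw=1)
    # focus on where the posterior lives, not the full 0-200 support
    support = x[results.posterior.probs > 1e-6]
    if len(support):
        ax.set_xlim(0, min(grid.max_tmb, float(support.max()) * 1.3 + 1))
    ax.set_xlabel("true TMB (mut/Mb)")
    ax.set_ylabel("density (per mut/Mb)")
    ax.legend(frameon=False)
    return ax
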