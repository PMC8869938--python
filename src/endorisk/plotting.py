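"""Plain matplotlib renders of the evaluation results.

The JSON report is the data of record; these plots are optional views.
"""

from __future__ import annotations

import numpy as np

from .model import RiskStratificationResults

__all__ = ["plot_km"]


def plot_km(results: RiskStratificationResults, ax=None, ci: bool = True):
    """Step-function Kaplan–Meier panel, one line per risk group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    for group, curve in results.km_curves.items():
        t = np.concatenate([[0.0], curve.event_times, [curve.max_time]])
        s = np.concatenate([[1.0], curve.survival, [curve.survival[-1] if len(curve.survival) else 1.0]])
        (line,) = ax.step(t, s, where="post", label=f"{group} (n={curve.n})")
        if ci and len(curve.event_times):
            ax.fill_between(
                np.concatenate([[0.0], curve.event_times]),
                np.concatenate([[1.0], curve.ci_low]),
                np.concatenate([[1.0], curve.ci_high]),
                step="post",
                alpha=0.12,
                color=line.get_color(),
            )
    ax.set_xlabel("months since surgery")
    ax.set_ylabel(f"{results.endpoint.upper()} probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"{results.scheme} risk groups")
    ax.legend(loc="lower left", fontsize=8)
    return ax
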