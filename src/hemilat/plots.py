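"""Diagnostic plots: Bland-Altman agreement and the cutoff-sweep curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .reliability import BlandAltmanResult

__all__ = ["bland_altman_plot", "cutoff_sweep_plot"]


def bland_altman_plot(result: BlandAltmanResult, path, title="Bland-Altman"):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, s=18, alpha=0.7)
    ax.axhline(result.mean_diff, color="k", lw=1.2)
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="k", ls=":", lw=1.0)
    ax.set_xlabel("Mean LI of the two sessions (Δ%)")
    ax.set_ylabel("LI difference, session 1 − session 2 (Δ%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def cutoff_sweep_plot(sweep, path):
    """``sweep`` is the DataFrame returned by
    :func:`hemilat.reliability.cutoff_sweep`."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(sweep["cutoff"], sweep["prop_bilateral_session1"],
            "o-", label="bilateral in session 1")
    ax.plot(sweep["cutoff"], sweep["prop_bilateral_replicated"],
            "s--", label="replicated in session 2")
    ax.set_xlabel("|LI| cutoff (Δ%)")
    ax.set_ylabel("Proportion")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
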