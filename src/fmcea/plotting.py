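"""Plot helpers: efficiency frontier, CEAC, tornado. Matplotlib is imported
lazily so the library core stays import-light."""

from __future__ import annotations

from typing import Sequence


def _get_ax(ax):
    import matplotlib.pyplot as plt

    return plt.gca() if ax is None else ax


def plot_frontier(results, ax=None):
    """Scatter of (QALY, cost) per strategy with the frontier polyline."""
    ax = _get_ax(ax)
    for o in results.outcomes:
        on = results.frontier.status[o.strategy] == "on_frontier"
        ax.scatter(
            o.expected_qaly,
            o.expected_cost,
            color="tab:green" if on else "tab:gray",
            zorder=3,
        )
        ax.annotate(o.strategy, (o.expected_qaly, o.expected_cost), fontsize=7)
    pts = sorted(
        (results.outcome(s) for s in results.frontier.frontier),
        key=lambda o: o.expected_cost,
    )
    ax.plot(
        [o.expected_qaly for o in pts],
        [o.expected_cost for o in pts],
        color="tab:green",
        label="efficient frontier",
    )
    ax.set_xlabel("Expected QALYs")
    ax.set_ylabel("Expected cost ($)")
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_ceac(curve, ax=None):
    """One line per strategy: probability cost-effective vs WTP."""
    ax = _get_ax(ax)
    for j, s in enumerate(curve.strategies):
        ax.plot(curve.wtp, curve.probabilities[:, j], label=s)
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend(loc="best", fontsize=7)
    return ax


def plot_tornado(entries: Sequence, base_inmb: float = 0.0, ax=None):
    """Horizontal iNMB swing bars, widest at the top."""
    ax = _get_ax(ax)
    entries = list(entries)
    y = range(len(entries))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.inmb_at_low, e.inmb_at_high))
        ax.barh(i, hi - lo, left=lo, color="tab:blue", alpha=0.7)
    ax.axvline(base_inmb, color="k", lw=1)
    ax.set_yticks(list(y), [e.parameter for e in entries], fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("iNMB ($)")
    return ax
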