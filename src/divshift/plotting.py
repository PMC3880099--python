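"""Minimal figures: LTT curve over its pure-birth envelope, and a chronogram
painted with reconstructed state probabilities."""

from __future__ import annotations

import numpy as np

from .trees import Chronogram


def plot_ltt(curve, envelope=None, ax=None):
    """Observed LTT (dots, log-scale y) over the null envelope (mean + 95% CI)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if envelope is not None:
        ax.plot(envelope.grid, np.exp(envelope.mean_log), "k-", lw=1.2,
                label="pure-birth mean")
        ax.plot(envelope.grid, np.exp(envelope.lo), "k:", lw=1)
        ax.plot(envelope.grid, np.exp(envelope.hi), "k:", lw=1,
                label="95% envelope")
    ax.plot(curve.times, curve.counts, "ko", ms=3, label="observed")
    ax.set_yscale("log")
    ax.set_xlabel("age (Ma)")
    ax.set_ylabel("lineages")
    ax.invert_xaxis()
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_asr(tree: Chronogram, node_prob: dict, tip_states: dict | None = None,
             ax=None, cmap=("#b5651d", "#1f77b4")):
    """Rectangular tree with internal nodes coloured by P(pelagic)."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.12 * tree.n + 1))
    cm = LinearSegmentedColormap.from_list("bp", list(cmap))

    ys = {}
    for i, label in enumerate(tree.tip_labels):
        ys[label] = i

    def y_of(node):
        if node.is_leaf():
            return ys[node.taxon.label]
        return np.mean([y_of(c) for c in node.child_nodes()])

    for node in tree.root.postorder_iter():
        y = y_of(node)
        if node is not tree.root:
            ax.hlines(y, node.parent_node.age, node.age, color="0.3", lw=0.8)
        if not node.is_leaf():
            kid_ys = [y_of(c) for c in node.child_nodes()]
            ax.vlines(node.age, min(kid_ys), max(kid_ys), color="0.3", lw=0.8)
            p1 = node_prob.get(node.cindex)
            if p1 is not None:
                ax.plot(node.age, y, "o", ms=4, color=cm(p1), zorder=3)
        else:
            if tip_states is not None:
                s = tip_states.get(node.taxon.label)
                if s is not None:
                    ax.plot(0, y, "s", ms=3, color=cmap[int(s)], zorder=3)
    ax.set_xlabel("age (Ma)")
    ax.set_yticks([])
    ax.invert_xaxis()
    return ax
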