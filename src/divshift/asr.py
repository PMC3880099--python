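"""Equal-rates binary Markov (Mk1) ancestral-state reconstruction.

The habitat trait is binary (0 = benthic, 1 = pelagic) and evolves under a
single symmetric rate q (events/Ma), so the edge transition probabilities have
the closed form P_same(t) = (1 + exp(-2qt))/2, P_diff(t) = (1 - exp(-2qt))/2.
The likelihood is computed by Felsenstein's pruning algorithm with a flat
(0.5, 0.5) root prior (which is also the stationary distribution of the
equal-rates chain); marginal node probabilities come from the standard
two-pass (down + up) computation.  The "transition node" is the most
ancestral node whose marginal probability of being pelagic exceeds 0.5.

The statsmodels-flavoured entry point is :class:`Mk1` / :class:`Mk1Results`;
the lower-level functions (`mk_fit`, `marginal_states`, ...) are the pieces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .trees import Chronogram

__all__ = [
    "Mk1",
    "Mk1Results",
    "mk_transition_prob",
    "mk_fit",
    "marginal_states",
    "find_transition_node",
    "count_transitions",
]

_Q_LOWER = 1e-6   # bounds on q * root_age for the 1-D ML search
_Q_UPPER = 1e3


def mk_transition_prob(q: float, t: float) -> np.ndarray:
    """2x2 transition matrix of the symmetric binary chain over time t."""
    if q < 0 or t < 0:
        raise ValueError("q and t must be >= 0")
    e = np.exp(-2.0 * q * t)
    same = 0.5 * (1.0 + e)
    diff = 0.5 * (1.0 - e)
    return np.array([[same, diff], [diff, same]])


def _check_traits(tree: Chronogram, tips: dict) -> dict:
    missing = [lb for lb in tree.tip_labels if lb not in tips]
    if missing:
        raise KeyError(
            f"{len(missing)} tips lack a trait state (e.g. {missing[:3]}); "
            "prune untyped taxa before reconstruction"
        )
    out = {}
    for lb in tree.tip_labels:
        s = int(tips[lb])
        if s not in (0, 1):
            raise ValueError(f"state of {lb!r} must be 0 or 1, got {tips[lb]!r}")
        out[lb] = s
    return out


def _down_partials(tree: Chronogram, states: dict, q: float):
    """Pruning pass: F[node][s] = P(tip data below node | node in state s).

    Partials are renormalised per node; the dropped factor is accumulated in
    log scale so the likelihood survives hundreds of tips.
    """
    F = {}
    logscale = 0.0
    for node in tree.root.postorder_iter():
        if node.is_leaf():
            f = np.zeros(2)
            f[states[node.taxon.label]] = 1.0
            F[node] = f
            continue
        f = np.ones(2)
        for c in node.child_nodes():
            P = mk_transition_prob(q, node.age - c.age)
            f = f * (P @ F[c])
        m = f.max()
        if m <= 0:
            raise FloatingPointError("zero likelihood; inconsistent data")
        logscale += np.log(m)
        F[node] = f / m
    return F, logscale


def _loglik(tree: Chronogram, states: dict, q: float) -> float:
    F, logscale = _down_partials(tree, states, q)
    return float(np.log(0.5 * F[tree.root].sum()) + logscale)


def mk_fit(tree: Chronogram, tips: dict) -> dict:
    """ML estimate of the single rate q by bounded 1-D search on log(q).

    The search interval is q * root_age in [1e-6, 1e3] so the bounds are
    scale-free.  Monomorphic tip data leave q unidentified: the lower bound is
    returned with a warning.
    """
    states = _check_traits(tree, tips)
    vals = set(states.values())
    ra = tree.root_age
    if len(vals) < 2:
        warnings.warn(
            "all tips share one state; q is unidentified and reported at the "
            "search lower bound"
        )
        q = _Q_LOWER / ra
        return {"q_hat": q, "loglik": _loglik(tree, states, q)}

    def neg(x):
        return -_loglik(tree, states, np.exp(x) / ra)

    res = minimize_scalar(
        neg,
        bounds=(np.log(_Q_LOWER), np.log(_Q_UPPER)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    q_hat = float(np.exp(res.x) / ra)
    return {"q_hat": q_hat, "loglik": float(-res.fun)}


def marginal_states(tree: Chronogram, tips: dict, q: float) -> dict:
    """Marginal P(state = 1) at every internal node (flat root prior).

    Down pass: subtree partials F.  Up pass: G[node][s] = P(data outside the
    node's subtree | node in state s) built from the parent's G and the
    siblings' partials; the marginal at a node is proportional to F * G.
    Returns {internal-node index: P(pelagic)}.
    """
    states = _check_traits(tree, tips)
    F, _ = _down_partials(tree, states, q)
    G = {tree.root: np.array([0.5, 0.5])}
    out = {}
    for node in tree.root.preorder_iter():
        if node.is_leaf():
            continue
        kids = node.child_nodes()
        # sibling messages S_c(s_parent) = sum_s P(s_parent -> s; t_c) F_c(s)
        msgs = []
        for c in kids:
            P = mk_transition_prob(q, node.age - c.age)
            msgs.append(P @ F[c])
        for i, c in enumerate(kids):
            others = G[node].copy()
            for j, m in enumerate(msgs):
                if j != i:
                    others = others * m
            P = mk_transition_prob(q, node.age - c.age)
            g = P.T @ others
            s = g.sum()
            G[c] = g / s if s > 0 else g
        post = F[node] * G[node]
        out[node.cindex] = float(post[1] / post.sum())
    return out


def find_transition_node(tree: Chronogram, node_prob: dict, threshold: float = 0.5):
    """Most ancestral node with P(pelagic) > threshold.

    Ties in age break toward the larger descendant count, then the
    lexicographically smallest tip set.  Returns the node object, or None.
    """
    best = None
    best_key = None
    for nd in tree.internal_nodes:
        p1 = node_prob.get(nd.cindex)
        if p1 is None or not p1 > threshold:
            continue
        key = (-nd.age, -len(nd.tipset), sorted(nd.tipset))
        if best is None or key < best_key:
            best, best_key = nd, key
    return best


def _assign_states(tree: Chronogram, node_prob: dict, tol: float = 1e-9) -> dict:
    """Argmax-marginal state per internal node; exact ties take the parent's
    state (the root's tie resolves to benthic)."""
    assigned = {}
    for nd in tree.root.preorder_iter():
        if nd.is_leaf():
            continue
        p1 = node_prob[nd.cindex]
        if abs(p1 - 0.5) <= tol:
            parent = nd.parent_node
            assigned[nd.cindex] = (
                assigned[parent.cindex] if (parent is not None and nd is not tree.root) else 0
            )
        else:
            assigned[nd.cindex] = int(p1 > 0.5)
    return assigned


def count_transitions(tree: Chronogram, node_state: dict, tip_states: dict) -> dict:
    """Count state changes along edges, by direction.

    ``node_state`` maps internal-node index -> assigned state; tip edges use
    the observed tip states.  Returns {"n_0to1": ..., "n_1to0": ...}.
    """
    n01 = n10 = 0
    for nd in tree.root.preorder_iter():
        if nd is tree.root:
            continue
        parent_s = node_state[nd.parent_node.cindex]
        child_s = (
            tip_states[nd.taxon.label] if nd.is_leaf() else node_state[nd.cindex]
        )
        if parent_s == 0 and child_s == 1:
            n01 += 1
        elif parent_s == 1 and child_s == 0:
            n10 += 1
    return {"n_0to1": n01, "n_1to0": n10}


# ------------------------------------------------------- model-style facade


@dataclass
class Mk1Results:
    """Fitted Mk1 reconstruction."""

    model: "Mk1"
    q_hat: float
    loglik: float
    node_prob: dict           # internal-node index -> P(pelagic)
    node_state: dict          # internal-node index -> argmax state
    transition_node: object   # node object or None
    n_0to1: int
    n_1to0: int

    @property
    def transition_node_tips(self):
        if self.transition_node is None:
            return None
        return self.model.tree.clade_tips(self.transition_node)

    @property
    def transition_node_age(self):
        return None if self.transition_node is None else float(self.transition_node.age)

    def summary(self) -> str:
        tree = self.model.tree
        lines = [
            "Mk1 (equal-rates binary Markov) ancestral state reconstruction",
            f"  tips: {tree.n}   root age: {tree.root_age:.4g} Ma",
            f"  q_hat: {self.q_hat:.6g} /Ma   loglik: {self.loglik:.4f}",
            f"  transitions 0->1 (benthic->pelagic): {self.n_0to1}",
            f"  transitions 1->0 (pelagic->benthic): {self.n_1to0}",
        ]
        if self.transition_node is None:
            lines.append("  transition node: none (no node exceeds the threshold)")
        else:
            nd = self.transition_node
            lines.append(
                f"  transition node: age {nd.age:.4g} Ma, "
                f"{len(nd.tipset)} descendant tips, "
                f"P(pelagic) = {self.node_prob[nd.cindex]:.3f}"
            )
        return "\n".join(lines)

    def node_table(self) -> str:
        lines = ["node\tage\tn_tips\tP_benthic\tP_pelagic\tstate"]
        for nd in self.model.tree.internal_nodes:
            p1 = self.node_prob[nd.cindex]
            lines.append(
                f"{nd.cindex}\t{nd.age:.6g}\t{len(nd.tipset)}\t"
                f"{1 - p1:.6g}\t{p1:.6g}\t{self.node_state[nd.cindex]}"
            )
        return "\n".join(lines)


class Mk1:
    """Equal-rates binary Markov model of a trait on a chronogram.

    Parameters
    ----------
    tree : Chronogram
    traits : mapping taxon -> {0, 1}; every tip must be present (extra taxa
        are ignored).
    threshold : marginal probability of state 1 above which a node counts as
        pelagic when locating the transition node.
    """

    def __init__(self, tree: Chronogram, traits: dict, threshold: float = 0.5):
        self.tree = tree
        self.traits = _check_traits(tree, traits)
        self.threshold = threshold

    def fit(self) -> Mk1Results:
        fitted = mk_fit(self.tree, self.traits)
        q = fitted["q_hat"]
        probs = marginal_states(self.tree, self.traits, q)
        assigned = _assign_states(self.tree, probs)
        trans = find_transition_node(self.tree, probs, self.threshold)
        counts = count_transitions(self.tree, assigned, self.traits)
        return Mk1Results(
            model=self,
            q_hat=q,
            loglik=fitted["loglik"],
            node_prob=probs,
            node_state=assigned,
            transition_node=trans,
            n_0to1=counts["n_0to1"],
            n_1to0=counts["n_1to0"],
        )
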