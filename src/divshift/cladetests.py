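"""Node-level diversity tests: relative cladogenesis (RC) and the parametric
rates comparison (PRC) subtree scan.

Under the equal-rates Markov (ERM, pure-birth) model, if a lineages are alive
at some time in the past, the number of present-day descendants of one
particular lineage, out of n total, follows

    P(exactly r) = C(n - r - 1, a - 2) / C(n - 1, a - 1),   r = 1..n-a+1,

and the RC test reports the tail P(>= b) for each node's observed descendant
count b.  The PRC scan asks, for every subtree with at least ``min_edges``
edges, whether its branch lengths look like draws from a different exponential
distribution than the rest of the tree (likelihood-ratio chi-square, 1 df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

from .trees import Chronogram

__all__ = [
    "RCRecord",
    "PRCRecord",
    "rc_tail_probability",
    "rc_test_tree",
    "prc_scan",
]


@dataclass(frozen=True)
class RCRecord:
    node: int                  # Chronogram internal-node index
    tips: tuple                # the node's descendant tip labels, sorted
    a: int                     # lineages alive just before the node
    b: int                     # extant descendants of the node's lineage
    n_at_present: int
    p: float
    significant: bool          # raw p < alpha (the mode matching published usage)
    significant_bonferroni: bool


@dataclass(frozen=True)
class PRCRecord:
    node: int
    tips: tuple
    n_edges_sub: int
    rate_sub: float
    rate_rest: float
    lr: float
    p: float
    faster: bool               # subtree rate exceeds the rest of the tree
    significant: bool


# -------------------------------------------------------------------- RC


def rc_tail_probability(a: int, n: int, b: int) -> float:
    """P(one of a ancestral lineages leaves >= b of n extant descendants).

    Exact under ERM.  The tail sum telescopes (hockey-stick identity) to
    C(n - b, a - 1) / C(n - 1, a - 1); exact integer arithmetic is used.
    """
    a, n, b = int(a), int(n), int(b)
    if a < 2:
        raise ValueError("a must be >= 2 (at least two coexisting lineages)")
    if not 1 <= b <= n - a + 1:
        raise ValueError(f"b must lie in [1, n - a + 1] = [1, {n - a + 1}]")
    return comb(n - b, a - 1) / comb(n - 1, a - 1)


def rc_test_tree(tree: Chronogram, alpha: float = 0.05) -> list:
    """RC test at every internal node except the root.

    ``a`` is the number of lineages alive just before the node's age (an
    epsilon of 1e-9 x root age above it, which resolves simultaneous nodes
    deterministically) and ``b`` the node's descendant tip count.  Intended
    for trees already truncated of their most recent history when tip-level
    sampling artifacts are a concern.
    """
    tree.require_binary("the RC test")
    n = tree.n
    bt = tree.branching_times()
    asc = np.sort(bt)
    eps = 1e-9 * tree.root_age
    internal = tree.internal_nodes
    tested = [nd for nd in internal if nd is not tree.root]
    m = len(tested)
    records = []
    for nd in tested:
        age = nd.age + eps
        a = int(asc.size - np.searchsorted(asc, age, side="left")) + 1
        b = len(nd.tipset)
        p = rc_tail_probability(a, n, b)
        records.append(
            RCRecord(
                node=nd.cindex,
                tips=tree.clade_tips(nd),
                a=a,
                b=b,
                n_at_present=n,
                p=p,
                significant=p < alpha,
                significant_bonferroni=p < alpha / max(m, 1),
            )
        )
    return records


# ------------------------------------------------------------------- PRC


def _exp_loglik(total: float, k: int) -> float:
    """Max log-likelihood of k exponential draws with sum ``total``."""
    if k == 0:
        return 0.0
    rate = k / total
    return k * np.log(rate) - rate * total  # = k (log(k/total) - 1)


def prc_scan(tree, min_edges: int = 6, alpha: float = 0.1) -> list:
    """Parametric rates comparison over all subtrees with >= min_edges edges.

    For each internal node (the root excluded: its complement is empty), the
    branch lengths inside the subtree and those in the remainder of the tree
    each get an exponential MLE (rate = 1/mean); the one-rate fit on the
    pooled lengths is compared by a likelihood-ratio chi-square with 1 df.
    Records come back sorted by p.  Accepts a Chronogram or any rooted
    dendropy tree with branch lengths (the scan uses lengths only, so trees
    need not be ultrametric).
    """
    if isinstance(tree, Chronogram):
        root = tree.root
        get_len = lambda nd: nd.parent_node.age - nd.age
        node_index = {nd: nd.cindex for nd in tree.internal_nodes}
    else:
        root = tree.seed_node
        while len(root.child_nodes()) == 1:
            root = root.child_nodes()[0]
        get_len = lambda nd: nd.edge.length
        node_index = None

    # postorder subtree sums / counts / tip sets
    stats_by_node = {}
    order = []
    for nd in root.postorder_iter():
        if nd.is_leaf():
            stats_by_node[nd] = (0.0, 0, frozenset(
                [nd.taxon.label if nd.taxon else str(id(nd))]))
            continue
        tot, cnt = 0.0, 0
        tips = frozenset()
        for c in nd.child_nodes():
            ct, cc, cs = stats_by_node[c]
            blen = get_len(c)
            if blen is None:
                raise ValueError("branch length missing")
            tot += ct + blen
            cnt += cc + 1
            tips = tips | cs
        stats_by_node[nd] = (tot, cnt, tips)
        order.append(nd)

    total_sum, total_cnt, _ = stats_by_node[root]
    if total_cnt < min_edges + 2:
        raise ValueError(f"tree has only {total_cnt} edges; need >= {min_edges + 2}")

    records = []
    idx_counter = 0
    for nd in order:
        if nd is root:
            continue
        sub_sum, sub_cnt, tips = stats_by_node[nd]
        if sub_cnt < min_edges:
            continue
        rest_sum = total_sum - sub_sum
        rest_cnt = total_cnt - sub_cnt
        if rest_cnt < 1:
            continue
        if sub_sum <= 0 or rest_sum <= 0:
            warnings.warn("zero-length partition mean; PRC record skipped")
            continue
        ll_two = _exp_loglik(sub_sum, sub_cnt) + _exp_loglik(rest_sum, rest_cnt)
        ll_one = _exp_loglik(total_sum, total_cnt)
        lr = max(0.0, 2.0 * (ll_two - ll_one))
        p = float(stats.chi2.sf(lr, df=1))
        rate_sub = sub_cnt / sub_sum
        rate_rest = rest_cnt / rest_sum
        if node_index is not None:
            node_id = node_index[nd]
        else:
            node_id = idx_counter
            idx_counter += 1
        records.append(
            PRCRecord(
                node=node_id,
                tips=tuple(sorted(tips)),
                n_edges_sub=sub_cnt,
                rate_sub=float(rate_sub),
                rate_rest=float(rate_rest),
                lr=float(lr),
                p=p,
                faster=rate_sub > rate_rest,
                significant=p < alpha,
            )
        )
    records.sort(key=lambda r: r.p)
    return records
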