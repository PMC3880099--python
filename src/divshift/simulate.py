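"""Tree and trait simulators: the null and alternative worlds of the rate tests.

Pure-birth (Yule) trees conditioned on tip count are generated by the exact
interval construction: with k lineages the waiting time to the next split is
Exponential(k*lam), the splitting lineage is chosen uniformly, and a final
Exponential(n*lam) interval separates the last split from the present.  This
is the conditioned process itself, so no stop-at-nth-birth bias arises.

Birth-death trees use forward simulation with a general-sampling-approach
correction: the process runs well past n extant lineages and the present is
drawn uniformly (duration-weighted) over the periods during which exactly n
lineages were alive; extinct lineages are then pruned.

State-dependent trees are the alternative-hypothesis world: a binary trait
flips at rates q01/q10 and sets the per-lineage speciation rate (lambda0 vs
lambda1), so a single early 0->1 shift that elevates speciation produces the
early-burst signature the downstream tests look for.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field

import numpy as np

from .trees import Chronogram

__all__ = [
    "SimParams",
    "SimTree",
    "simulate_pure_birth",
    "simulate_birth_death",
    "simulate_state_dependent",
    "simulate_rate_shift",
    "simulate_mk_trait",
    "pure_birth_branching_times",
    "pruned_pure_birth_branching_times",
]

# Default speciation rate: with lam ~ 0.19/Ma a 192-tip pure-birth tree has an
# expected root age near 30 Ma, matching a ~30-Ma-old clade of ~200 species.
DEFAULT_LAMBDA = 0.19


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimParams:
    """Parameters of the state-dependent simulator (rates per lineage per Ma)."""

    lambda0: float
    lambda1: float
    mu: float = 0.0
    q01: float = 0.0
    q10: float = 0.0
    n_target: int = 100
    seed: int | None = None

    def __post_init__(self):
        for name in ("lambda0", "lambda1", "mu", "q01", "q10"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lambda0 <= 0 and self.lambda1 <= 0:
            raise ValueError("at least one speciation rate must be positive")
        if self.n_target < 3:
            raise ValueError("n_target must be >= 3")


@dataclass
class SimTree:
    """A simulated tree plus its ground truth.

    ``true_transition_events`` holds (clade_tipset, age, from_state, to_state)
    for every trait flip on a reconstructed edge, youngest clade first by age,
    so recovery tests can score an inferred transition node against truth.
    ``true_node_state`` maps each internal node's tip set to its true state.
    """

    tree: Chronogram
    tip_state: dict
    true_node_state: dict
    true_transition_events: list = field(default_factory=list)

    def manifest(self, params: SimParams | None = None) -> str:
        rec = {
            "n": self.tree.n,
            "root_age": self.tree.root_age,
            "tip_state": dict(sorted(self.tip_state.items())),
            "transition_events": [
                {"clade": sorted(c), "age": a, "from": f, "to": t}
                for c, a, f, t in self.true_transition_events
            ],
        }
        if params is not None:
            rec["params"] = {
                k: getattr(params, k)
                for k in ("lambda0", "lambda1", "mu", "q01", "q10", "n_target", "seed")
            }
        return json.dumps(rec, indent=1)


# ------------------------------------------------------------------ fast core


def _sim_yule(n, rates, rng):
    """Conditioned Yule tree via the interval construction.

    ``rates[k-2]`` is the per-lineage speciation rate while k lineages exist
    (k = 2..n).  Returns (parent, node_age, is_tip) over 2n-1 nodes; node 0 is
    the root and children always carry larger ids than their parent.
    """
    n = int(n)
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=np.int64)
    waits = rng.exponential(1.0 / (np.arange(2, n + 1, dtype=float) * rates))
    split_time = np.zeros(total)
    is_tip = np.ones(total, dtype=bool)
    is_tip[0] = False
    parent[1] = parent[2] = 0
    active = [1, 2]
    next_id = 3
    t = 0.0
    for k in range(2, n):  # k lineages currently alive
        t += waits[k - 2]
        i = int(rng.integers(k))
        node = active[i]
        split_time[node] = t
        is_tip[node] = False
        parent[next_id] = node
        parent[next_id + 1] = node
        active[i] = next_id
        active.append(next_id + 1)
        next_id += 2
    depth = t + waits[n - 2]  # final interval with n lineages
    node_age = np.where(is_tip, 0.0, depth - split_time)
    return parent, node_age, is_tip


def _induced_branching_times(parent, node_age, is_tip, keep_tips):
    """Internal-node ages of the subtree induced on ``keep_tips`` (node ids)."""
    total = parent.size
    cnt = np.zeros(total, dtype=np.int64)
    cnt[keep_tips] = 1
    for node in range(total - 1, 0, -1):  # ids are topologically ordered
        cnt[parent[node]] += cnt[node]
    kid_kept = np.zeros(total, dtype=np.int64)
    np.add.at(kid_kept, parent[1:], (cnt[1:] > 0).astype(np.int64))
    retained = (~is_tip) & (kid_kept >= 2)
    return np.sort(node_age[retained])[::-1]


def _newick_from_arrays(parent, node_age, is_tip, prefix="t"):
    total = parent.size
    children = [[] for _ in range(total)]
    for node in range(1, total):
        children[parent[node]].append(node)
    tip_ids = np.where(is_tip)[0]
    label = {int(t): f"{prefix}{i + 1}" for i, t in enumerate(tip_ids)}

    def rec(node):
        if is_tip[node]:
            return label[node], 0.0
        parts = [
            f"{s}:{node_age[node] - a:.17g}"
            for s, a in (rec(c) for c in children[node])
        ]
        return "(" + ",".join(parts) + ")", node_age[node]

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * total + 100))
    try:
        s, _ = rec(0)
    finally:
        sys.setrecursionlimit(old)
    return s + ";"


def pure_birth_branching_times(n, lam, rng) -> np.ndarray:
    """Branching times of one conditioned Yule tree (no tree object built)."""
    waits = rng.exponential(1.0 / (np.arange(2, n + 1, dtype=float) * lam))
    depth = waits.sum()
    return depth - np.concatenate([[0.0], np.cumsum(waits[:-1])])


def pruned_pure_birth_branching_times(n, m, lam, rng) -> np.ndarray:
    """Branching times after pruning m random tips from a Yule(n) tree.

    The null construction of the incomplete-sampling tests; pruning needs the
    topology, so the full interval construction is used when m > 0.
    """
    if m == 0:
        return pure_birth_branching_times(n, lam, rng)
    parent, node_age, is_tip = _sim_yule(n, np.full(n - 1, float(lam)), rng)
    tip_ids = np.where(is_tip)[0]
    keep = rng.choice(tip_ids, size=n - m, replace=False)
    return _induced_branching_times(parent, node_age, is_tip, keep)


# ----------------------------------------------------------------- public API


def simulate_pure_birth(n: int, lam: float = DEFAULT_LAMBDA, seed=None) -> Chronogram:
    """Pure-birth (Yule) ultrametric tree conditioned on exactly n tips."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    rng = _as_rng(seed)
    parent, node_age, is_tip = _sim_yule(n, np.full(n - 1, float(lam)), rng)
    return Chronogram.from_newick(_newick_from_arrays(parent, node_age, is_tip))


def simulate_rate_shift(n: int, lam1: float, lam2: float, k_shift: int,
                        seed=None) -> Chronogram:
    """Yule tree whose per-lineage rate jumps from lam1 to lam2 once the
    standing lineage count exceeds ``k_shift`` (a Yule-2-rate world)."""
    if n < 3 or not (2 <= k_shift <= n):
        raise ValueError("need n >= 3 and 2 <= k_shift <= n")
    rng = _as_rng(seed)
    rates = np.where(np.arange(2, n + 1) <= k_shift, float(lam1), float(lam2))
    parent, node_age, is_tip = _sim_yule(n, rates, rng)
    return Chronogram.from_newick(_newick_from_arrays(parent, node_age, is_tip))


# ------------------------------------------------------------- birth-death


def simulate_birth_death(n: int, lam: float, mu: float, seed=None,
                         gsa_factor: int = 4) -> Chronogram:
    """Reconstructed constant-rate birth-death tree with n extant tips,
    conditioned on survival (restarts on extinction)."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if not lam > mu >= 0:
        raise ValueError("need lam > mu >= 0 (supercritical process)")
    rng = _as_rng(seed)
    n_stop = max(gsa_factor * n, n + 5)
    for _ in range(1000):
        run = _forward_bd(n_stop, lam, mu, rng, windows_at=n)
        if run is None:
            continue
        tree = _reconstruct_at_sampled_present(*run, n=n, rng=rng)
        if tree is not None:
            return tree
    raise RuntimeError("birth-death simulation failed to reach the target size")


def _forward_bd(n_stop, lam, mu, rng, windows_at):
    """Forward birth-death from 2 lineages; None on extinction.

    Records the forward-time windows during which exactly ``windows_at``
    lineages were alive (the GSA sampling set).
    """
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]
    death = [0.0, np.inf, np.inf]  # the root splits into 1 and 2 at t = 0
    alive = [1, 2]
    t = 0.0
    windows = []
    win_start = t if len(alive) == windows_at else None
    while alive:
        k = len(alive)
        t += rng.exponential(1.0 / (k * (lam + mu)))
        if win_start is not None:
            windows.append((win_start, t))
            win_start = None
        i = int(rng.integers(k))
        node = alive[i]
        if rng.random() < lam / (lam + mu):  # speciation
            a, b = len(parent), len(parent) + 1
            parent += [node, node]
            birth += [t, t]
            death += [np.inf, np.inf]
            death[node] = t
            alive[i] = a
            alive.append(b)
        else:  # extinction
            death[node] = t
            alive[i] = alive[-1]
            alive.pop()
        if len(alive) == windows_at:
            win_start = t
        if len(alive) >= n_stop:
            break
    if not alive or not windows:
        return None
    return np.array(parent), np.array(birth), np.array(death), windows


def _reconstruct_at_sampled_present(parent, birth, death, windows, n, rng):
    durations = np.array([e - s for s, e in windows])
    if durations.sum() <= 0:
        return None
    wi = int(rng.choice(len(windows), p=durations / durations.sum()))
    present = rng.uniform(*windows[wi])
    alive_mask = (birth < present) & (death > present)
    tips = np.where(alive_mask)[0]
    if tips.size != n:
        return None

    total = parent.size
    cnt = np.zeros(total, dtype=np.int64)
    cnt[tips] = 1
    for node in range(total - 1, 0, -1):
        cnt[parent[node]] += cnt[node]
    children = [[] for _ in range(total)]
    for node in range(1, total):
        if cnt[node] > 0:
            children[parent[node]].append(node)

    counter = [0]

    def rec(node):
        while True:
            kids = children[node]
            if alive_mask[node]:
                counter[0] += 1
                return f"t{counter[0]}", 0.0
            if len(kids) == 1:  # pass-through lineage (other daughter extinct)
                node = kids[0]
                continue
            age = present - death[node]
            parts = [f"{s}:{age - a:.17g}" for s, a in (rec(c) for c in kids)]
            return "(" + ",".join(parts) + ")", age

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * total + 100))
    try:
        s, _ = rec(0)
    finally:
        sys.setrecursionlimit(old)
    return Chronogram.from_newick(s + ";")


# --------------------------------------------------------- state-dependent


def simulate_state_dependent(p: SimParams, max_attempts: int = 1000) -> SimTree:
    """Forward binary-state-dependent speciation simulation.

    Starts from a single state-0 lineage; each lineage speciates at
    lambda(state), goes extinct at mu and flips state at q01/q10.  The run
    stops when n_target lineages are simultaneously extant (the present is
    placed inside the following inter-event gap so terminal branches have
    positive length); extinct runs restart, up to ``max_attempts``.
    """
    rng = _as_rng(p.seed)
    for _ in range(max_attempts):
        res = _forward_sds(p, rng)
        if res is not None:
            return res
    raise RuntimeError(
        f"state-dependent simulation went extinct {max_attempts} times; "
        "raise the speciation rates or max_attempts"
    )


def _forward_sds(p, rng):
    lam = (p.lambda0, p.lambda1)
    parent = [-1]
    birth = [0.0]
    death = [np.inf]
    start_state = [0]       # state at the start of each node's edge
    flips = [[]]            # (forward time, from, to) on each node's edge
    cur_state = [0]
    alive = [0]
    t = 0.0
    while alive:
        k = len(alive)
        per = np.array(
            [lam[cur_state[i]] + p.mu + (p.q01 if cur_state[i] == 0 else p.q10)
             for i in alive]
        )
        total_rate = per.sum()
        dt = rng.exponential(1.0 / total_rate)
        if k >= p.n_target:
            present = t + rng.uniform(0.0, dt)
            return _finish_sds(parent, death, start_state, flips, alive, present)
        t += dt
        i = int(rng.choice(k, p=per / total_rate))
        node = alive[i]
        s = cur_state[node]
        u = rng.random() * per[i]
        if u < lam[s]:  # speciation
            a, b = len(parent), len(parent) + 1
            parent += [node, node]
            birth += [t, t]
            death += [np.inf, np.inf]
            start_state += [s, s]
            cur_state += [s, s]
            flips += [[], []]
            death[node] = t
            alive[i] = a
            alive.append(b)
        elif u < lam[s] + p.mu:  # extinction
            death[node] = t
            alive[i] = alive[-1]
            alive.pop()
        else:  # trait flip
            flips[node].append((t, s, 1 - s))
            cur_state[node] = 1 - s
    return None


def _finish_sds(parent, death, start_state, flips, alive, present):
    total = len(parent)
    parent_a = np.array(parent)
    death_a = np.array(death)
    alive_mask = np.zeros(total, dtype=bool)
    alive_mask[alive] = True

    cnt = np.zeros(total, dtype=np.int64)
    cnt[alive] = 1
    for node in range(total - 1, 0, -1):
        cnt[parent_a[node]] += cnt[node]
    if cnt[0] < 3:
        return None
    children = [[] for _ in range(total)]
    for node in range(1, total):
        if cnt[node] > 0:
            children[parent_a[node]].append(node)

    counter = [0]
    tip_state = {}
    node_state = {}
    events = []

    def rec(node, acc_flips, state0):
        """Walk a reconstructed edge (collapsing pass-through lineages)."""
        while True:
            acc_flips = acc_flips + flips[node]
            kids = children[node]
            if alive_mask[node] or len(kids) >= 2:
                break
            node = kids[0]
        end_state = acc_flips[-1][2] if acc_flips else state0
        if alive_mask[node]:
            counter[0] += 1
            lbl = f"t{counter[0]}"
            ts = frozenset([lbl])
            tip_state[lbl] = end_state
        else:
            parts, sets = [], []
            age = present - death_a[node]
            for c in kids:
                s, a, cts = rec(c, [], end_state)
                parts.append(f"{s}:{age - a:.17g}")
                sets.append(cts)
            ts = frozenset().union(*sets)
            node_state[ts] = end_state
            lbl = "(" + ",".join(parts) + ")"
        for ftime, fa, fb in acc_flips:
            events.append((ts, present - ftime, fa, fb))
        return lbl, (0.0 if alive_mask[node] else present - death_a[node]), ts

    # descend to the MRCA of the survivors; flips above it are outside the
    # reconstructed tree and only set the root state
    node = 0
    pre_flips = []
    while True:
        pre_flips += flips[node]
        kids = children[node]
        if alive_mask[node] or len(kids) >= 2:
            break
        node = kids[0]
    root_state = pre_flips[-1][2] if pre_flips else 0

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * total + 100))
    try:
        age = present - death_a[node]
        parts, sets = [], []
        for c in children[node]:
            s, a, cts = rec(c, [], root_state)
            parts.append(f"{s}:{age - a:.17g}")
            sets.append(cts)
        node_state[frozenset().union(*sets)] = root_state
        nwk = "(" + ",".join(parts) + ");"
    finally:
        sys.setrecursionlimit(old)

    tree = Chronogram.from_newick(nwk)
    return SimTree(tree=tree, tip_state=tip_state, true_node_state=node_state,
                   true_transition_events=sorted(events, key=lambda e: -e[1]))


# ----------------------------------------------------------------- Mk trait


def simulate_mk_trait(tree: Chronogram, q: float, root_state: int = 0,
                      seed=None) -> dict:
    """Evolve a symmetric binary Markov trait along the chronogram.

    With rate q in both directions, an edge of length t ends in the other
    state with probability (1 - exp(-2 q t)) / 2.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    if root_state not in (0, 1):
        raise ValueError("root_state must be 0 or 1")
    rng = _as_rng(seed)
    states = {}
    stack = [(tree.root, int(root_state))]
    while stack:
        node, s = stack.pop()
        for child in node.child_nodes():
            t = node.age - child.age
            p_diff = 0.5 * (1.0 - np.exp(-2.0 * q * t))
            cs = 1 - s if rng.random() < p_diff else s
            if child.is_leaf():
                states[child.taxon.label] = cs
            else:
                stack.append((child, cs))
    return states


def write_trait_table(states: dict, path):
    """Two-column delimited text: taxon <tab> state."""
    with open(path, "w") as fh:
        for k in sorted(states):
            fh.write(f"{k}\t{states[k]}\n")


def read_trait_table(path) -> dict:
    states = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            taxon, state = line.split("\t") if "\t" in line else line.split(",")
            states[taxon] = int(state)
    return states
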