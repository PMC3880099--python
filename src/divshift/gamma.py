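"""The gamma statistic and its Monte-Carlo relatives.

gamma (Pybus & Harvey's constant-rates statistic) measures whether internal
nodes sit earlier (gamma < 0) or later (gamma > 0) in a reconstructed tree
than a pure-birth process predicts; under pure birth it is standard normal.
Incomplete taxon sampling pushes gamma negative even under constant rates, so
the MCCR test recalibrates the critical value against pure-birth trees with
the observed number of tips randomly pruned away.  The tree-deviation
statistic sums the log excess of the observed lineage-through-time (LTT)
curve over the null mean, which can have more power when the burst is
concentrated at the base of the tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import _as_rng, pruned_pure_birth_branching_times
from .trees import Chronogram, InternodeIntervals, internode_intervals

__all__ = [
    "GammaResult",
    "MCCRResult",
    "TreeDeviationResult",
    "LTTCurve",
    "LTTEnvelope",
    "gamma_statistic",
    "mccr_test",
    "tree_deviation",
    "ltt_curve",
    "ltt_envelope",
]


@dataclass(frozen=True)
class GammaResult:
    gamma: float
    n: int
    p_normal: float  # one-sided (left tail: early burst) under N(0,1)


@dataclass(frozen=True)
class MCCRResult:
    gamma_obs: float
    null_gammas: np.ndarray
    crit_05: float  # 5th percentile of the null
    p: float        # rank p-value (1 + #{null <= obs}) / (reps + 1)


@dataclass(frozen=True)
class TreeDeviationResult:
    td_obs: float
    null_td: np.ndarray
    p: float  # (1 + #{null >= obs}) / (reps + 1)


@dataclass(frozen=True)
class LTTCurve:
    times: np.ndarray       # descending node ages, length n-1
    counts: np.ndarray      # lineage counts 2..n (count k holds on (t_{k-1}, t_k])
    log_counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts[-1])

    def count_at(self, age) -> np.ndarray:
        """Number of lineages alive at the given age(s) before present."""
        age = np.asarray(age, dtype=float)
        asc = self.times[::-1]  # ascending ages
        n_older = asc.size - np.searchsorted(asc, age, side="left")
        return n_older + 1

    def to_table(self) -> str:
        lines = ["age\tcount\tlog_count"]
        for t, c, lc in zip(self.times, self.counts, self.log_counts):
            lines.append(f"{t:.6g}\t{c}\t{lc:.6g}")
        return "\n".join(lines)


@dataclass(frozen=True)
class LTTEnvelope:
    grid: np.ndarray      # ages, root depth -> 0
    mean_log: np.ndarray  # mean log lineage count of the null
    lo: np.ndarray        # 2.5th percentile of log counts
    hi: np.ndarray        # 97.5th percentile

    def to_table(self) -> str:
        lines = ["age\tmean_log\tlo2.5\thi97.5"]
        for g, m, lo, hi in zip(self.grid, self.mean_log, self.lo, self.hi):
            lines.append(f"{g:.6g}\t{m:.6g}\t{lo:.6g}\t{hi:.6g}")
        return "\n".join(lines)


# ---------------------------------------------------------------- gamma


def _gamma_from_g(g: np.ndarray) -> float:
    """gamma from internode intervals g_2..g_n."""
    n = g.size + 1
    k = np.arange(2, n + 1, dtype=float)
    cum = np.cumsum(k * g)       # cum[i-2] = T_i = sum_{k<=i} k g_k
    T = cum[-1]
    if T <= 0:
        raise ValueError("total lineage-time T must be > 0")
    mean_Ti = cum[:-1].mean()    # i = 2..n-1
    return float((mean_Ti - T / 2.0) / (T * np.sqrt(1.0 / (12.0 * (n - 2)))))


def gamma_statistic(x) -> GammaResult:
    """Constant-rates statistic gamma with its left-tail normal p-value.

    Accepts a Chronogram, InternodeIntervals, or a descending vector of
    branching times.  Needs n >= 3 (gamma is undefined on a 2-tip tree).
    """
    iv = internode_intervals(x)
    if iv.n < 3:
        raise ValueError("gamma is undefined for n < 3")
    gam = _gamma_from_g(iv.g)
    return GammaResult(gamma=gam, n=iv.n, p_normal=float(stats.norm.cdf(gam)))


def _gamma_from_bt(t: np.ndarray) -> float:
    g = np.empty(t.size)
    g[:-1] = t[:-1] - t[1:]
    g[-1] = t[-1]
    return _gamma_from_g(g)


def null_gamma_sample(n_total, n_missing, lam, reps, rng) -> np.ndarray:
    """gamma values of pure-birth trees with n_missing tips randomly pruned."""
    out = np.empty(reps)
    for r in range(reps):
        bt = pruned_pure_birth_branching_times(n_total, n_missing, lam, rng)
        out[r] = _gamma_from_bt(bt)
    return out


def mccr_test(gamma_obs: float, n_total: int, n_missing: int, lam: float = 1.0,
              reps: int = 999, seed=None) -> MCCRResult:
    """Monte-Carlo constant-rates test under incomplete taxon sampling.

    The null is gamma computed on pure-birth trees of ``n_total`` tips (the
    described diversity) from which ``n_missing`` random tips were pruned
    (the unsampled species).  gamma is scale-free, so ``lam`` only sets the
    simulated time scale.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if n_total - n_missing < 3:
        raise ValueError("need at least 3 sampled taxa")
    rng = _as_rng(seed)
    null = null_gamma_sample(n_total, n_missing, lam, reps, rng)
    p = (1.0 + np.count_nonzero(null <= gamma_obs)) / (reps + 1.0)
    return MCCRResult(gamma_obs=float(gamma_obs), null_gammas=null,
                      crit_05=float(np.quantile(null, 0.05)), p=float(p))


# ----------------------------------------------------------- tree deviation


_REL_GRID = 100


def _log_ltt_on_grid(bt: np.ndarray, grid_rel: np.ndarray) -> np.ndarray:
    """ln N at relative times since the root (tree rescaled to unit depth)."""
    depth = bt[0]
    rel_ages = 1.0 - grid_rel          # age / depth
    asc = np.sort(bt) / depth          # ascending relative node ages
    counts = asc.size - np.searchsorted(asc, rel_ages, side="left") + 1
    return np.log(counts)


def tree_deviation(tree, n_total: int, n_missing: int, reps: int = 999,
                   seed=None, lam: float = 1.0,
                   grid_size: int = _REL_GRID) -> TreeDeviationResult:
    """Excess of observed lineages over the pure-birth null LTT.

    Observed and null trees are rescaled to unit depth; on a uniform grid of
    relative times, td = sum over the grid of ln N_obs(t) - mean_null ln N(t).
    Each null tree's td is computed against the same null mean, and the
    p-value is the right-tail rank of the observed td.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = _as_rng(seed)
    bt_obs = tree.branching_times() if isinstance(tree, Chronogram) else np.asarray(tree)
    grid = np.linspace(0.0, 1.0, grid_size)
    obs = _log_ltt_on_grid(bt_obs, grid)
    null_mat = np.empty((reps, grid_size))
    for r in range(reps):
        bt = pruned_pure_birth_branching_times(n_total, n_missing, lam, rng)
        null_mat[r] = _log_ltt_on_grid(bt, grid)
    mean_null = null_mat.mean(axis=0)
    td_obs = float(np.sum(obs - mean_null))
    null_td = (null_mat - mean_null).sum(axis=1)
    p = (1.0 + np.count_nonzero(null_td >= td_obs)) / (reps + 1.0)
    return TreeDeviationResult(td_obs=td_obs, null_td=null_td, p=float(p))


# ----------------------------------------------------------------- LTT


def ltt_curve(tree) -> LTTCurve:
    """Step curve of lineage count against age (2 at the root split, n at 0)."""
    bt = tree.branching_times() if isinstance(tree, Chronogram) else np.asarray(tree)
    n = bt.size + 1
    counts = np.arange(2, n + 1)
    return LTTCurve(times=bt, counts=counts, log_counts=np.log(counts))


def ltt_envelope(n: int, n_missing: int, depth: float, reps: int = 1000,
                 seed=None, lam: float = 1.0,
                 grid_size: int = _REL_GRID) -> LTTEnvelope:
    """Pointwise pure-birth envelope of the log LTT.

    Null trees of ``n`` tips are pruned of ``n_missing`` tips and rescaled to
    the stated depth; the envelope is the pointwise mean and 2.5/97.5
    percentiles of the log lineage count on a uniform age grid from the root
    (age = depth) to the present.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = _as_rng(seed)
    grid_rel = np.linspace(0.0, 1.0, grid_size)
    logs = np.empty((reps, grid_size))
    for r in range(reps):
        bt = pruned_pure_birth_branching_times(n, n_missing, lam, rng)
        logs[r] = _log_ltt_on_grid(bt, grid_rel)
    return LTTEnvelope(
        grid=depth * (1.0 - grid_rel),
        mean_log=logs.mean(axis=0),
        lo=np.quantile(logs, 0.025, axis=0),
        hi=np.quantile(logs, 0.975, axis=0),
    )
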