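# Methods

## Scope and conventions

`divshift` analyses rooted ultrametric chronograms whose branch lengths are
in units of time (Ma). Ages are measured before the present (present = 0);
the root age is the tree depth. Ultrametricity is checked with a relative
tolerance (default 1e-6 × root age, configurable) because chronograms
summarised from MCMC output carry rounding error. Polytomies are accepted
on input, but every statistic that requires a binary tree (γ, the model
likelihoods, RC) refuses polytomous trees with an explicit error rather
than resolving them silently.

The substrate of all rate statistics is the vector of internode intervals
g₂…gₙ, where gₖ is the time spent with exactly k reconstructed lineages
(gₙ runs from the last split to the present). Σgₖ equals the root age and
T = Σ k·gₖ is the total lineage-time.

## Ancestral state reconstruction (Mk1)

The habitat trait is binary (0 = benthic, 1 = pelagic) and evolves under a
single symmetric rate q (events/Ma); edge transition probabilities have the
closed form P_same = (1 + e^{−2qt})/2. The likelihood is computed by the
pruning algorithm with per-node renormalisation (log-scale accumulation),
so trees with hundreds of tips do not underflow. The root prior is flat
(0.5, 0.5) — for the equal-rates model this coincides with the stationary
distribution; it is stated explicitly for determinism.

q is estimated by bounded one-dimensional maximization of the log
likelihood over log(q·root age) ∈ [log 1e−6, log 1e3] with tolerance 1e-8,
which makes the bounds scale-free. Monomorphic tip data leave q
unidentified; the lower bound is returned with a warning. Marginal node
probabilities use the standard two-pass computation (subtree partials down,
outside-subtree messages up); they were verified against brute-force
summation over all internal-state assignments for small trees, and the rate
and likelihood against `ape` in R.

The *transition node* is the most ancestral node with P(pelagic) > 0.5
(threshold configurable); age ties break toward the larger descendant
count, then the lexicographically smallest tip set. Transition counting
assigns each internal node its argmax-marginal state (exact ties inherit
the parent's state; a root tie resolves to benthic) and counts
state-discordant edges by direction, using observed states on tip edges.
Stochastic mapping is deliberately out of scope: the argmax assignment is
the simplest deterministic reading of a pie-chart reconstruction.
Ambiguous or missing tip states are not supported — taxa without a coded
state must be pruned first.

## γ, MCCR, and tree deviation

γ follows Pybus & Harvey: with Tᵢ = Σ_{k≤i} k·gₖ,
γ = [mean(T₂…T_{n−1}) − T/2] / [T·√(1/(12(n−2)))]. It is standard normal
under pure birth; the early-burst alternative is the left tail, and the
pipeline tests one-sided (γ < −1.645 at α = 0.05). Incomplete sampling
biases γ downward, so the MCCR test recalibrates: the null is γ on
pure-birth trees of the described species richness from which the
unsampled number of tips is randomly pruned. All Monte-Carlo p-values use
the add-one rank estimator (1+r)/(R+1), which never returns zero.

The tree-deviation statistic rescales observed and null trees to unit
depth and sums, over a 100-point uniform grid of relative times,
ln N_obs(t) − mean_null ln N(t). Each null tree's statistic is computed
against the same overall null mean (not leave-one-out: at the replicate
counts used the difference is O(1/R) and the test calibrates itself against
its own null). The upper tail is the early-burst direction.

LTT envelopes are pointwise means and 2.5/97.5 percentiles of the log
lineage count of pruned pure-birth trees rescaled to the observed depth, on
the same 100-point grid. At the present the envelope collapses exactly to
log(sampled tip count).

## Node scans (RC, PRC)

Under the equal-rates Markov model, one of *a* coexisting ancestral
lineages leaves r of n extant descendants with probability
C(n−r−1, a−2)/C(n−1, a−1); the RC tail P(≥ b) telescopes to
C(n−b, a−1)/C(n−1, a−1) and is computed in exact integer arithmetic.
"Lineages alive just before a node" is the LTT count at the node's age plus
an epsilon of 1e-9 × root age, which resolves simultaneous nodes
deterministically. The root is skipped (a = 1 there). Raw p-values are
reported with significance flags at raw α (the mode that matches published
usage) and under a Bonferroni correction by the number of tested nodes —
both, because published RC analyses typically report raw counts.

The PRC scan visits every internal node whose subtree holds at least 6
edges (root excluded — its complement is empty), fits exponential rates
(1/mean) to the branch lengths inside the subtree and in the remainder,
and compares the two-rate to the one-rate fit by a likelihood-ratio χ²(1).
The LRT was chosen over the original tool's partially documented internals
because it is fully specified and calibrates correctly (false-positive
fraction ≈ α on homogeneous trees). The scan uses branch lengths only and
therefore also accepts non-ultrametric trees.

Both scans are intended for trees first truncated of their recent past
(default 5 Ma in the pipeline): sampling one specimen per species and
taxonomic over-splitting distort apparent cladogenesis near the tips, and
truncation removes that zone. Truncation cuts every lineage crossing the
time plane and collapses it to a terminal labeled by the lexicographically
first descendant tip — a documented, deterministic choice where the
original tooling leaves the rule unstated.

## Diversification models and the ΔAIC test

Five models are fitted to the internode intervals. Waiting-time models use
density k·λₖ·exp(−k·λₖ·gₖ) for k = 2..n−1 plus, by default, the survival
factor exp(−n·λₙ·gₙ) for the final interval; published implementations
differ on that factor and `condition_on_survival=False` drops it, changing
the effective lineage-time from T to T − n·gₙ.

* **PB**: λₖ = λ; closed-form MLE λ̂ = (n−2)/T.
* **DDL**: λₖ = λ0(1 − k/K); K is profiled (λ0 has a closed-form profile
  MLE) on a 41-point log grid with bounded local refinement; K must exceed
  the largest lineage count with a live rate. A boundary solution
  (K → ∞) is reported as pure-birth-equivalent with a warning.
* **DDX**: λₖ = λ0·k^{−x}, x ∈ [0, 10] profiled the same way; x = 0
  recovers PB exactly, and the implementation guards that nesting against
  optimizer slack.
* **Y2R**: λ(t) = λ1 for ages older than t_s, else λ2; t_s is profiled
  over the midpoints of consecutive branching times (a finite candidate
  set — the continuum in between is unidentifiable), and each segment's
  rate has a closed-form MLE (events/exposure). A segment with no events
  takes its supremum at rate → 0 and is reported at 1e-10.
* **BD**: the reconstructed-process likelihood conditioned on the root age
  and survival of both root lineages (Nee et al.), parameterised by r = λ−μ
  and a = μ/λ ∈ [0, 0.999], optimised by bounded quasi-Newton from five
  fixed starts. At a = 0 it equals the PB waiting-time likelihood exactly
  (survival factor included), so the constant-rate pair is properly
  nested; the fit was verified against `ape::birthdeath`. BD always uses
  this conditioned form regardless of the survival-factor flag.

The rate-shift statistic is ΔAIC = AIC(best of PB, BD) − AIC(best of DDL,
DDX, Y2R), compared against the same statistic on pure-birth trees with the
observed degree of incomplete sampling. ΔAIC is scale-free, so the null
simulation rate defaults to the observed PB MLE. Replicates whose fits fail
are dropped and counted; more than 5% failures aborts the test.

## Synthetic data

* **Pure birth conditioned on n** uses the exact interval construction
  (waiting time Exponential(k·λ) with k lineages, uniform choice of the
  splitting lineage, final Exponential(n·λ) interval) — the conditioned
  process itself, avoiding the stop-at-nth-birth bias of naive forward
  simulation.
* **Birth-death** runs forward well past n extant lineages and samples the
  present uniformly (duration-weighted) over the periods with exactly n
  alive, then prunes extinct lineages; extinct runs restart.
* **State-dependent speciation** runs a forward Gillespie simulation from a
  single state-0 lineage (speciation λ(state), extinction μ, flips
  q01/q10) until n lineages are simultaneously extant, placing the present
  inside the following inter-event gap so terminal branches are positive;
  it returns the reconstructed tree with true tip/node states and every
  flip on a reconstructed edge. Restarts on extinction are capped (default
  1000).
* **Two-rate Yule** (`simulate_rate_shift`) switches the per-lineage rate
  when the standing lineage count passes a threshold — the generator for
  rate-shift recovery experiments and for genuine early-burst worlds
  (fast-then-slow).
* **Mk traits** evolve along a fixed chronogram with the closed-form flip
  probability per edge.

Default speciation rate 0.19/Ma puts the expected root age of a 192-tip
pure-birth tree near 30 Ma, matching the scale of a ~30-Ma-old clade of
~200 species; γ-based statistics are scale-free, so this choice only sets
the simulated time axis.

What the generators do *not* emulate: phylogenetic uncertainty (a single
true tree is analysed, not a posterior), non-uniform taxon sampling,
rate variation among contemporaneous lineages beyond the binary state, and
diversification slowdowns *within* a state. The last point matters for
interpretation: a state-dependent shift to a constant fourfold-higher rate
concentrates nodes toward the present (γ ≥ 0, a "late burst"), and the
focal clade itself is internally pure-birth (γ ≈ 0) — so passing
transition-node-recovery tests on this world says nothing about γ-test
power, and the left-tail MCCR has essentially no power against it. One
acceptance test asserts high MCCR power under exactly this scenario and
therefore fails; it is kept as an honest record of that measured property.
Power against a *genuine* early burst (fourfold deceleration) is ~100% and
is tested separately.

## Pipeline

`run_analysis` chains: (1) Mk1 fit, marginals, transition node; (2) focal
clade extraction (fallback to the whole tree, with a prominent flag, when
no node passes the threshold or the focal clade has fewer than 5 tips);
(3) γ / MCCR / tree deviation / ΔAIC on the untruncated focal clade, with
n_missing = user-supplied described richness − sampled focal tips (never
guessed from the tree; negative values flag and disable the correction);
(4) RC and PRC on the whole tree truncated of `truncation_depth` Ma
(default 5). All stage seeds derive deterministically from the config seed
combined with a content hash of the tree, so batch results are invariant
to the order of trees in the input file. Batch mode reports per-tree rows
plus percentile summaries of γ, tree deviation and ΔAIC.

## Problem sizes used by the test suite and acceptance script

Null calibrations: 5,000 pure-birth trees (γ moments, n = 50); 100,000 to
200,000 (MCCR critical value, n = 192); 200 × 99 (MCCR p uniformity,
n = 60, 6 pruned); 60–80 × 100 (ΔAIC type-I, n = 60); 150–200 trees of 60
tips (PRC calibration). Recoveries: 40 replicates each (Mk q at n = 120;
Y2R ratio at n = 150; transition node at n = 160 with ≥ 30-tip shifted
clades). Power: 20–25 replicates at n = 192 with 18 pruned, 199 MCCR
nulls. These sizes put Monte-Carlo error comfortably inside the asserted
tolerances while keeping a full desk run in minutes.

## Known limitations

Asymmetric (two-rate) Mk, stochastic mapping, joint state-dependent
diversification inference (BiSSE-style), Bayesian shift models and
continuous rate-through-time models are out of scope. The RC test assumes
complete sampling (hence its pairing with truncation rather than a
sampling correction). Y2R's shift-time profile makes its AIC slightly
optimistic (t_s is counted as one free parameter, as is conventional).
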