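# divshift

Diversification-rate shift detection and binary-habitat ancestral state
reconstruction on time-calibrated phylogenies.

## The problem

Clades that invade a sparsely occupied adaptive zone — for example a
bottom-dwelling (benthic) fish lineage shifting into the open water column
(pelagic) — are expected to show a burst of lineage accumulation after the
shift. Testing that idea from a dated molecular phylogeny takes two steps:

1. **Locate the habitat transition.** Tips are coded benthic (0) or pelagic
   (1) and an equal-rates binary Markov model (Mk1, symmetric rate *q*) is
   fitted by maximum likelihood; marginal state probabilities at every node
   come from Felsenstein's pruning algorithm with a flat root prior. The
   *transition node* is the most ancestral node with P(pelagic) > 0.5, and
   the clade it subtends is the *focal clade*.
2. **Test for accelerated cladogenesis.** On the focal clade:
   the γ statistic of Pybus & Harvey (standard normal under pure birth;
   γ < −1.645 indicates an early burst), its Monte-Carlo recalibration under
   incomplete taxon sampling (the MCCR test: pure-birth trees of the
   described richness with the unsampled tips randomly pruned), a
   tree-deviation statistic (summed log excess of the observed
   lineage-through-time curve over the null mean), lineage-through-time
   envelopes, and simulation-calibrated ΔAIC model selection between
   constant-rate (pure-birth, birth-death) and variable-rate
   (density-dependent logistic/exponential, Yule-2-rate) diversification
   models. On the whole tree (truncated of its most recent history, where
   single-specimen sampling distorts apparent cladogenesis): the relative
   cladogenesis (RC) test with its exact equal-rates-Markov tail
   probabilities, and the parametric rates comparison (PRC), an
   exponential-rate likelihood-ratio scan over all subtrees.

All likelihoods operate on the internode intervals g₂…gₙ (the durations
spent with exactly *k* lineages): while *k* lineages exist the per-lineage
speciation rate is λₖ, each interval contributes
*k*·λₖ·exp(−*k*·λₖ·gₖ), and a final survival factor
exp(−*n*·λₙ·gₙ) covers the interval between the last split and the present.

## Worked example

```python
import divshift as ds

# a 120-tip state-dependent tree: benthic ancestor, one early shift to a
# fourfold-faster pelagic state, 10% of tips pruned to mimic sampling
p = ds.SimParams(lambda0=0.08, lambda1=0.32, q01=0.006, q10=0.0,
                 n_target=120, seed=77)
sim = ds.simulate_state_dependent(p)
tree = sim.tree.prune_random(12, seed=78)

cfg = ds.AnalysisConfig(truncation_depth=1.0, reps=100, seed=5)
report = ds.run_analysis(tree, sim.tip_state, cfg)
print(report.table1_row().to_string(index=False))
```

prints

```
    gamma   mccr_p    td_p   daic_p best_model
-0.066725 0.534653 0.49505 0.811881         PB
```

Read: the reconstructed transition node is found (the report also carries
its age and tip set — here a 43-tip clade at 8.9 Ma), but the focal clade
itself diversified
at a *constant* elevated rate, so γ is near zero-to-positive and none of
the rate-shift tests fire — exactly the expected behaviour for this
generator. Against a genuine early burst (a fourfold rate *drop* partway
through, `ds.simulate_rate_shift(192, 0.4, 0.1, k_shift=64, seed=0)`), γ
falls below −5 and the MCCR and ΔAIC tests reject essentially always.

A thin CLI mirrors the library: `divshift simulate|asr|gamma|mccr|td|rc|
prc|fit|run|batch` (see `divshift --help`).

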