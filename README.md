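# assemblypath

Integrative spatiotemporal modeling of macromolecular assembly pathways.

Large complexes such as the nuclear pore complex (NPC) assemble over minutes
from tens of subcomplexes. No single experiment watches that process at
molecular resolution: quantitative fluorescence imaging (FCS-calibrated)
gives per-protein copy numbers over time, and correlated electron tomography
gives low-resolution density maps of the growing structure at a few time
points. `assemblypath` combines both into a *pathway model*: a weighted set
of assembly trajectories, each an ordered series of static "snapshot" models
of the partially assembled complex.

The package is aimed at structural/computational biologists who want to infer
and validate assembly pathways from such time-resolved data, or to benchmark
the approach on fully synthetic systems.

## The model

At each modeled time point *t*, a **snapshot model** fixes the copy numbers
`N_t` of each subcomplex, the location assignment of each copy to a site of
the mature complex, and a coarse bead-level structure `X_{N,t}`. Snapshots are
scored independently,

    P(X_{N,t}, N_t | D_t)  ∝  P(D_t | X_{N,t}, N_t) · P(X_{N,t}, N_t),

where the data term combines independent Gaussian likelihoods of the measured
copy numbers and a density-fit term against the time point's map, and the
prior contains excluded-volume, native-biased (Gō-like) and site-anchor
restraints toward the mature structure.

Snapshots at adjacent time points become nodes of a layered directed acyclic
graph. A **trajectory** 𝒳 picks one snapshot per time point; for a Markovian
process its weight is

    W(𝒳)  ∝  ∏_t P(X_{N,t}, N_t | D_t) · ∏_t W(X_{N,t+1}, N_{t+1} | X_{N,t}, N_t),

with weights normalized to sum to one. The transition score is binary: a
transition is allowed iff every subcomplex present earlier is still present,
at the same site, later (subunits are unlikely to dissociate). Validation
uses:

* **temporal precision** `P_temp = 1 − ½ Σ_i |W_A(𝒳_i) − W_B(𝒳_i)|` between
  two independent samplings (1 = perfect agreement, 0 = disjoint);
* **model precision** `γ = Σ_i W(𝒳_i)²`, from 1/d (uniform over d
  trajectories) to 1 (a single dominant trajectory);
* trajectory-weighted copy-number curves against scored *and* held-out
  proteins, per-snapshot map correlation, and RMSD to the mature structure;
* a two-sample Kolmogorov–Smirnov check (pass: p > 0.05 and D < 0.3) that two
  samplings of a snapshot drew from the same score distribution.

A synthetic-data generator produces complete, self-consistent studies — an
NPC-like 8-fold-symmetric system with five subcomplex types, a ground-truth
monotone pathway, noisy copy-number series and rendered density volumes — so
the whole pipeline is testable end to end without any external data.

## Worked example

Simulate an NPC-like study, then run the pipeline stage by stage:

```sh
assemblypath simulate --out demo --seed 7 --preset npc
assemblypath enumerate --system demo/system.yaml --data demo/copy_numbers.csv \
    --out demo/snapshots.json
assemblypath score-snapshots --system demo/system.yaml --data demo/copy_numbers.csv \
    --snapshots demo/snapshots.json --maps-dir demo/maps --out demo/scored.json \
    --mc-seed 1 --mc-steps 80 --mc-models 3
assemblypath build-graph --snapshots demo/scored.json --out demo/graph.json
assemblypath weight --graph demo/graph.json --out demo/weights.json --dot demo/graph.dot
assemblypath analyze --system demo/system.yaml --data demo/copy_numbers.csv \
    --graph demo/graph.json --out demo/report.json
```

This prints (abridged):

```
71 snapshots -> demo/snapshots.json
71 nodes, 217 edges, 576 trajectories -> demo/graph.json
gamma=1.0000, top weight=1.0000 -> demo/weights.json
Assembly-pathway validation report
----------------------------------
trajectories (nonzero weight universe): 576
model precision gamma:   1.0000
top trajectory: t0_5_000>t1_6_000>t2_8_002>t3_10_001>t4_15_001>t5_mature_000 (weight 100.0%)

held-out protein agreement (z-like discrepancy):
        Seh1 @      8: model    8.00 vs data    8.06 (discrepancy 0.10)
      Nup188 @     10: model    8.00 vs data    7.77 (discrepancy 1.44)
      ...
```

Reading the numbers: 71 snapshot models across the six time points were
connected by 217 allowed transitions into 576 candidate trajectories. The
model precision γ = 1.0 says a single trajectory carries essentially all the
weight (its id lists the winning snapshot at each time point), i.e. the data
identify one assembly order. The held-out table compares model copy numbers
for the two proteins deliberately excluded from scoring (Nup188, Seh1) with
their simulated measurements; discrepancies are in pooled standard
deviations, so values around 1 are consistent with noise.

The same workflow is available as a library (`assemblypath.pipeline.run_pipeline`),
and `assemblypath.benchmark.run_recovery_study` runs the full
simulate–infer–validate replicate used in the tests.

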