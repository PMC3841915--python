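# otunet

**AIC-guided selection of an OTU clustering threshold from bipartite
sequence–plot networks.**

Amplicon surveys of marker genes must collapse similar sequences into
operational taxonomic units (OTUs) before any ecology can be done, and for
protein-coding genes (e.g. the *nirS* nitrite reductase gene of denitrifying
bacteria) there is no conventional similarity cutoff to borrow. `otunet`
chooses the cutoff from the data itself: each candidate clustering is scored
as a statistical model of the observed sequence-type × plot occurrence and
abundance pattern, and the clustering with the lowest AIC wins.

For S sequence types grouped into k OTUs across r plots, with OTU i holding
S_i types of which L_iq occur in plot q (cell abundance total a_·iq):

    p(iq)   = L_iq / S_i
    LL(iq)  = L_iq·log p(iq) + (S_i − L_iq)·log(1 − p(iq)),   0·log 0 ≡ 0
    AIC_bin = 2kr + 2S − 2·ΣΣ LL(iq)
    AIC_w   = 4kr + 2S − 2·ΣΣ [ LL(iq) + Σ_j log Poisson(a_jiq; λ = a_·iq/S_i) ]

Over-lumping mixes unlike occupancy/abundance profiles and loses likelihood;
over-splitting pays the parameter penalty for nothing. Scanning similarity
thresholds 74–99% and minimising AIC_w picks the coarsest, most parsimonious
OTU definition that still reproduces the ecological structure. Downstream,
the package computes the standard occupancy statistics on the selected
network: generalists (≥ 6 of 8 plots by default), specialists/endemics
(single-plot OTUs), singletons, per-plot summary tables, plot co-occurrence
with complete-linkage clustering, dose–specialist gradients, and bipartite
graph exports. A fully seeded synthetic-community generator with planted OTU
structure makes every claim testable end to end. See `docs/methods.md` for
the model details and design choices.

## Worked example

Simulate a planted community (8 plots on a nitrogen-dose gradient, 5 core
OTUs with a 3%-within / 25%-between divergence gap, dose-scaled endemic
OTUs), then fit:

```python
from otunet import OtuThresholdModel
from otunet.synthetic import SimConfig, simulate_community, write_community

cfg = SimConfig(seed=1)
records, truth = simulate_community(cfg)
write_community(records, truth, "demo")

model = OtuThresholdModel.from_fasta("demo/reads.fasta", sample_map="demo/mapping.tsv")
res = model.fit()
print(res.summary())
```

```
          OTU threshold selection (bipartite network AIC)
==================================================================
Sequence types:           30    Plots:                   8
Total reads:            2475    Grid:               74..99
Abundance model:     poisson    Selection:    aic_weighted
------------------------------------------------------------------
Optimal threshold:       76%    OTUs at optimum:        10
AIC (binary):            220.000    AIC (weighted):     1245.566
log L (binary):            0.000    log L (abund.):     -432.783
------------------------------------------------------------------
Generalist OTUs:           4    Specialist OTUs:         5
Singleton OTUs:            3    Links (L):             168
==================================================================
```

The 2 475 reads collapse to 30 sequence types; the weighted AIC bottoms out
at 76% similarity, the first grid level that separates the five planted core
OTUs (exactly 25% apart by construction) — together with five injected
endemics that is 10 OTUs, and the recovered partition matches the planted
one (adjusted Rand index 1.0, `truth` vs `res.optimal_partition`). The AIC
curve shows why:

```python
print(res.curve_frame().iloc[[0, 2, 24, 25]].to_string(index=False))
```

```
 threshold_pct  k  ll_binary    ll_abund  aic_binary  aic_weighted   model
            74  6 -54.056558 -823.619174  264.113116   2007.351465 poisson
            76 10   0.000000 -432.783193  220.000000   1245.566386 poisson
            98 13   0.000000 -427.591422  268.000000   1331.182843 poisson
            99 23   0.000000 -399.638319  428.000000   1595.276638 poisson
```

At 74–75% the core OTUs merge (k = 6) and both likelihood layers collapse;
from 98% the clusters start splitting, gaining almost no likelihood while
paying 32 AIC points per extra OTU. Ecology views hang off the results
object — `res.plot_summaries()`, `res.cooccurrence()`,
`res.plot_dendrogram().to_newick()`, `res.export_network("edges.tsv")`, and
the dose gradient:

```python
print(res.specialist_gradient(cfg.doses).tail(2).to_string(index=False))
```

```
  plot  dose  proportion_generalist_sequences  proportion_specialist_sequences
plot_7  7.56                         0.990881                         0.009119
plot_8  7.56                         0.745358                         0.005305
```

Specialist (plot-endemic) reads concentrate in the dosed plots — zero in
both controls here — reproducing the expected positive dose–specialist
relationship.

The same workflow is scriptable via the `otunet` CLI
(`simulate`, `derep`, `scan-aic`, `ecology`, `run-all`):

```sh
otunet simulate --seed 1 --out-dir demo
otunet run-all --fasta demo/reads.fasta --mapping demo/mapping.tsv \
    --doses 0,0,0.85,0.85,2.52,2.52,7.56,7.56 --out-dir demo/out
```

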