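# Methods

## Problem and model

Amplicon surveys of marker genes (the motivating case is the *nirS* nitrite
reductase gene of denitrifying bacteria, sequenced from replicated,
fertilisation-gradient salt-marsh plots) must group similar sequences into
operational taxonomic units (OTUs) before any community analysis. The
similarity cutoff used for that grouping is usually taken from convention
(e.g. 97% for 16S rRNA), but for protein-coding genes no convention exists
and the choice materially changes every downstream statistic. `otunet`
selects the cutoff from the data: it treats each candidate clustering as a
statistical model of the observed sequence-by-plot incidence and abundance
pattern and picks the clustering whose model minimises AIC.

Given S dereplicated sequence types observed across r plots and a partition
of the types into k OTUs, the bipartite OTU-plot network is scored in two
layers:

* **Binary layer.** For OTU i with S_i member types, of which L_iq occur
  (abundance > 0) in plot q, the link probability is p(iq) = L_iq / S_i and
  the cell log-likelihood is

      LL(iq) = L_iq·log p(iq) + (S_i − L_iq)·log(1 − p(iq)),   0·log 0 ≡ 0,

  summed over all k·r cells. The binary AIC is

      AIC_bin = 2kr + 2S − 2·ΣΣ LL(iq).

* **Abundance layer.** Within cell (i, q), member read counts a_jiq are
  modelled as i.i.d. Poisson with mean λ = a_·iq / S_i (the cell total
  spread evenly over all members, zero-count members included), or
  alternatively Binomial(size = a_·iq, p = 1/S_i). The weighted AIC adds
  2kr parameters:

      AIC_w = 4kr + 2S − 2·ΣΣ [LL(iq) + LL_abund(iq)].

A partition that lumps ecologically distinct lineages mixes unlike occupancy
and abundance profiles and loses likelihood; a partition that splits them
pays the 2kr/4kr parameter penalty with no likelihood gain. Scanning integer
similarity thresholds (default 74–99%) and minimising AIC_w (Poisson) yields
the coarsest clustering that still reproduces the ecological structure. The
selection column and abundance model are configurable (`weighted=False`
selects on AIC_bin; `abundance_model="binomial"` swaps the count model).

Since S is fixed by dereplication, the 2S term is a constant offset across
thresholds and cannot change the argmin; it is computed anyway so reported
AIC values are on the conventional scale.

### Sign convention

Some presentations of the binary layer write the second exponent as
(L_iq − S_i), which makes that term positive and the "likelihood" exceed 1
whenever 0 < L_iq < S_i. The default here is the standard binomial sign
(S_i − L_iq); `verbatim_sign=True` reproduces the flipped form for audit
purposes. All tests and defaults use the standard sign.

### Numerical choices

* Natural logarithms throughout; the argmin is base-invariant.
* `0·log 0 = 0` is implemented with `scipy.special.xlogy`.
* Degenerate cells: λ = 0 (Poisson) or a_·iq = 0 / S_i = 1 (Binomial)
  contribute exactly 0.
* Ties in the AIC curve resolve toward the **lower** threshold (fewer OTUs,
  the more parsimonious model); `numpy.argmin` over a grid stored in
  increasing threshold order implements this directly.

## Sequence identity and clustering

Pairwise identity comes from a global Needleman–Wunsch alignment with match
+1, mismatch −1 and a linear gap penalty −2 per gap column:

    identity = matched columns / alignment length (gap columns counted).

Among co-optimal alignments the tie rule is explicit and total: maximise
matched columns, then minimise alignment length — i.e. prefer
match/mismatch moves over gaps. The implementation packs
(score, matches, −length) into one 64-bit key whose per-move increments are
constant, so a single max-plus dynamic programme (JIT-compiled with numba)
computes the lexicographic optimum without traceback; a brute-force
enumeration over all alignments of short sequences serves as the test
oracle. Sequences up to 2000 bases are supported.

OTUs at similarity s% are flat clusters of one average-linkage tree
(`scipy.cluster.hierarchy`) cut at distance (100 − s)/100 with an
**inclusive** cut (a pair at exactly the cut distance co-clusters). Cutting
one tree at every grid level guarantees the partitions are nested and the
OTU count is non-decreasing in s. This in-repo clustering deliberately
replaces the heuristic, scalability-oriented engines used in large amplicon
pipelines: at the package's intended scale (thousands of reads, tens to
hundreds of sequence types) the exact method is deterministic and fully
testable, which matters more than throughput. OTU ids are assigned by
decreasing OTU total abundance (ties by smallest member row index);
representatives are the most abundant member (ties lexicographic), so runs
are reproducible without seeds.

## Ecology statistics

On the network at the selected threshold:

* **Classes.** generalist ⇔ occupancy ≥ `generalist_min` (default 6,
  mirroring an eight-plot design; `fractional_generalist_min(r)` gives
  ⌈0.75·r⌉ for other designs); specialist (endemic) ⇔ occupancy = 1;
  everything else intermediate. Singleton ⇔ total abundance 1 (hence
  occupancy 1). The three classes partition the OTU set.
* **Per-plot summaries.** Total reads, distinct OTUs, endemic OTUs,
  singletons, and the reads carried by generalist and by endemic OTUs —
  with the conservation laws (endemics ≤ OTUs, singletons ≤ endemics,
  generalist + endemic reads ≤ total) enforced by construction and retested
  on simulations.
* **Co-occurrence.** The fraction of OTUs shared between two plots. The
  denominator is not uniquely determined by that phrase, so both readings
  are implemented: Jaccard (shared/union, the default — the standard
  symmetric choice) and shared/min. Plots are grouped by complete-linkage
  clustering of 1 − co-occurrence; the dendrogram is exported as newick.
* **Dose gradient.** Per-plot generalist and specialist read proportions
  against an external covariate (nitrogen dose in the motivating design),
  sorted by dose.
* **Network export.** The weighted bipartite graph (edge weight = OTU
  abundance in plot, OTU nodes tagged with their class) as an edge-list TSV
  or GML; layout/rendering is left to the consumer.

## Synthetic communities

The generator emulates the motivating study design: r = 8 plots, two
replicates at each of four nitrogen doses (0, 0.85, 2.52, 7.56 g N m⁻²
wk⁻¹), k_true = 5 core OTUs of 432-bp sequences with 4–6 members each, a 3%
within- vs 25% between-OTU divergence gap, per-OTU plot-occupancy
probabilities drawn uniformly from [0.6, 1], and a per-cell expected OTU
depth of 72 reads (members Poisson with mean 72/S_i, matching the abundance
layer's model) — roughly 300 reads per plot. Plot-endemic OTUs are injected
at Poisson(`specialist_rate`·dose) per plot (default rate 0.5 per unit
dose) with 1–2 members of small abundance (1 + Poisson(0.5) reads), which
also produces singletons.

**Block-substitution design.** Core ancestors derive from one random root by
substituting *disjoint* blocks of round(0.125·L) positions; member variants
substitute only inside their own block, to bases distinct from both the
ancestor's and the root's base at that position. Consequently every
between-OTU member pair differs at exactly 2·round(0.125·L) positions —
alignment distance exactly 0.25 — while within-OTU pairs stay below 0.03.
The planted identity gap is therefore exact, not approximate: with the
inclusive cut, core OTUs merge at thresholds ≤ 75% and separate at ≥ 76%,
so the tie-toward-lower rule lands the selected threshold at 76–77%,
strictly inside the (75, 97) gap, and recovery claims (adjusted Rand index
1 versus the planted partition) are sharp rather than probabilistic
near-misses. Endemic ancestors are independent random sequences
(rejection-sampled to stay ≤ 75% identity to everything), far from all
clusters at any grid threshold.

What the generator does **not** emulate: sequencing error (homopolymer
miscalls, chimeras), length variation (an `indels` option introduces single
deletions to exercise the aligner, but no realistic indel process),
phylogenetic correlation among OTUs, or uneven sequencing depth beyond
occupancy draws. Passing the recovery tests therefore shows the method is
correct and well-behaved when its model assumptions hold; it does not show
robustness to real 454/Illumina artefacts, which upstream pipelines are
expected to remove.

Mutation is substitution-only by default so identities are
Hamming-predictable; `mutate()` substitutes exactly round(divergence·length)
positions chosen without replacement.

## Problem sizes

Defaults throughout target desk scale: ~2 500 reads collapsing to ~30–60
sequence types per simulated community, full 74–99 scans in a few seconds.
The validation suite uses 10 communities for recovery, 20 for the dose
gradient, and 200 random networks (k ≤ 10, r ≤ 8, S ≤ 40, counts ≤ 20) for
the likelihood oracle comparison at 1e-9 absolute tolerance.

## Known limitations

* O(S²) alignments and O(S³)-ish linkage limit the exact clustering to a
  few thousand sequence types; precomputed tables from heavier clustering
  tools can be fed in through `OtuThresholdModel.from_table` instead.
* The abundance layer conditions on cell totals and assumes members are
  exchangeable within an OTU-plot cell; systematic within-OTU abundance
  structure (e.g. a dominant variant) is evidence *against* merging under
  this model, which is intended behaviour but worth knowing.
* With a single plot (r = 1) the binary layer is nearly uninformative and
  selection rests on the abundance layer alone.
* The no-gap regime (within-divergence ≥ between/2) is detectable but not
  recoverable; `recovery_check` reports `gap_detectable=False` rather than
  asserting success.
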