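# Methods

## Overview

`rnadivide` splits a long RNA into fragments short enough for any
short-RNA secondary structure predictor, applies the predictor per
fragment, and recombines the fragment structures at their original
coordinates.  The scientific content is in three places: how safe cut
points are defined and learned, how fragments are built so long-range
stems survive, and how partition quality and pseudoknot prediction are
scored.

## Cut points, the outer merge, and ideal labels

A cut at index c separates positions c−1 and c.  Cutting at
c₁ < … < c_k yields parts [0,c₁), …, [c_k,n); with three or more parts
the first and last are merged into one discontinuous fragment.  The
merge is what makes the method work on real RNA architectures: a stem
pairing the 5' and 3' ends would otherwise be broken by *any* partition.

Ideal (label) cut points are derived from a reference structure:

1. Pseudoknots are removed with the IR (incremental, range) criterion:
   while crossings remain, helix groups are formed from mutually nested
   pairs sharing the same crossing partners, and the conflicting group
   with the smallest range (max j − min i) is deleted; ties delete the
   3'-most group.  Long-range stems therefore survive.
2. Helices that enclose the entire remaining structure (a single
   top-level pair chain) are peeled: cuts placed between their arms and
   the inner content are safe *because of* the outer merge.  If the
   structure was peeled, at least two cuts (one per arm gap) are
   required, otherwise no cuts are emitted — a two-part split has no
   merge and would break the enclosing stem.
3. One cut is emitted at the midpoint of each maximal run of safe
   boundaries (boundaries b with no remaining pair i < b ≤ j) between
   consecutive top-level blocks.  Midpoints maximize the margin to both
   flanking stems.  Unpaired 5'/3' tails generate no cuts.

This construction guarantees a break rate of exactly zero on the
depseudoknotted structure, which the test suite asserts over a
500-structure synthetic suite.  Structures with a single minimally
nested stem are not divisible and produce no label.

Label generation recurses: each fragment longer than the maximum
fragment length re-derives its induced sub-structure (pairs wholly
inside the fragment, reindexed to the concatenated fragment sequence)
and contributes its own example, so one long structure yields one
observation per partition iteration.

## Features

Each position is encoded as 4 one-hot channels plus one channel per
motif pattern.  A motif is an IUPAC string with `*` wildcards, each `*`
matching 1–`gap_cap` (default 30) arbitrary nucleotides.  For every
motif, all match configurations are enumerated (a left/right
placement-count dynamic program equivalent to explicit enumeration) and
each position covered by a literal character accumulates the number of
configurations covering it; counts are log1p-scaled so they stay bounded
on long sequences.  Wildcard gap positions are not counted, and merged
discontinuous fragments are featurized on their plain concatenation, so
matches may span the junction.

The shipped default motif set is small and synthetic: tetraloop and
purine-pattern motifs, two gapped two-part motifs, and two composition
runs — `KKKKK` (keto, G/U) and `MMMMM` (amino, A/C).  The composition
runs matter: every canonical pair (AU, GC, GU) places a G or U on at
least one strand, so paired regions are keto-enriched relative to
unpaired linkers, and these channels give the divide model a direct,
first-order view of local pairedness.  The motif file is a runtime input
(`name<TAB>pattern` lines); users with a curated structural motif set
should supply their own.

## The divide model

A 10-layer dilated 1D convolutional encoder, kernel size 3, dilations
decreasing 512, 256, …, 1, ReLU activations, 64 hidden channels,
followed by a per-position linear head with a sigmoid.  The receptive
field is 2·(2¹⁰−1)+1 = 2047 positions, larger than the default maximum
fragment length, and the cost is linear in sequence length.  The network
and its training loop are implemented directly on NumPy arrays (a layer
is three matrix products per direction), with analytic gradients checked
against finite differences in the tests.

Two wiring choices were made where the published architecture leaves the
stack unspecified, both forced by optimization behaviour at desk scale:

- **Gated identity skips.** Same-width layers compute
  h ← h + α·relu(z) with a learnable scalar α initialized to 0.  A plain
  stack collapses: the regression target is near zero almost everywhere,
  the sigmoid saturates at the base rate, the ReLUs die and the output
  becomes a position-independent constant with no gradient path back.
  Ungated skips instead blow up the activation scale into saturation.
  The zero-initialized gate starts as the identity and opens gradually.
- **Zero-initialized head on a prior bias.** The head weights start at 0
  with bias −3 (≈ the base rate on the logit scale).  The constant part
  of the target is then fitted immediately and encoder gradients only
  grow along directions correlated with the residual, rather than an
  initial phase that indiscriminately crushes all features.

Training: loss per example is the plain sum of squared errors against
the exponential-decay target (λ = 0.5); minibatches average example
gradients (sequences are processed one at a time, so no padding enters
the loss); optimizer Adam with learning rate 1e-2 (at 1e-3 the model
cannot escape the saturated constant solution — the single-example
overfit sanity check fails), batch size 8, early stopping on validation
loss with patience 10, best-validation checkpoint returned.  Mutation
augmentation (fraction f ~ U(0, 0.1) of pairs re-drawn as canonical
pairs, per example per epoch) is applied to the training split only.
Training is bit-reproducible given the seed.

## Peak detection and partitioning

Cut points are strict local maxima of the predicted score vector found
with `scipy.signal.find_peaks` (plateaus contribute their first index),
filtered by a minimum height, a minimum separation (higher peaks kept
first) and an end margin; if fewer than two survive, the highest-scoring
admissible positions at least the minimum separation apart are forced,
so every divisible node yields at least two cuts and the outer merge
always applies.  A node too short to host two admissible cuts raises a
"not divisible" error; during recursion such fragments are returned
oversized with a warning rather than failing the run.

The defaults (height 0.02, distance 120, margin 20) were calibrated on a
synthetic validation set disjoint from all test sets, with a model
trained at the package's desk scale.  Three effects drove them: (i) a
desk-scale model's informative local maxima live at ~0.01–0.06, so a
large absolute height disables the peak path entirely; (ii) a small
minimum separation lets the two forced cuts cluster inside one
inter-domain gap, wasting a partition round on a sliver fragment;
(iii) scores show artifacts within ~20 positions of the sequence ends,
where no label cut ever lies.  A fully trained large-scale model with
confident probabilities would warrant a higher threshold; the parameters
are exposed in `PeakParams` and in the CLI config.

Recursion maps every fragment-local cut back through the fragment's
interval map, guarantees progress (each child is strictly shorter), and
stops when all fragments are at most the maximum fragment length
(default 1,000 nt, matching the published operating point; the floor is
100 nt).  The final fragments always partition [0, n) exactly — asserted
on every run.

## Metrics

- Base-pair P/R/F on exact (i, j) matches; empty denominators are
  reported as 0 and flagged rather than raising, so dataset aggregation
  never crashes.  Aggregation reports the mean of per-sequence metrics.
- Pseudoknot P/R/F: pseudoknots are enumerated as ordered pairs of
  crossing nested groups (the first group holds the smaller minimum left
  index).  A predicted pseudoknot is a true positive when some reference
  pseudoknot shares at least one pair with its first group and at least
  one with its second group; matching is many-to-many as the rule
  states — no assignment problem is solved.
- Compression rate 1 − Σ (nᵢ/n)²: 0 for a single fragment, maximized by
  equal fragment lengths.
- Break rate: non-pseudoknot pairs (IR-depseudoknotted reference) whose
  endpoints fall in different fragments, over all such pairs.

## Synthetic data

The generator emulates the gross architecture of structured RNAs:
2–6 top-level domains (stem-loops, or two-way multiloops with
probability 0.35), stems of 4–12 pairs, loops of 3–8 nt, unpaired
linkers of at least 4 nt (so safe-boundary runs between domains are
never empty and labels always exist), 5'/3' tails of 0–8 nt, lengths
200–1,200 nt by default (surplus length is distributed over the
unpaired runs).  With probability 0.3 a long-range outer stem wraps all
domains, separated from them by unpaired spacers of at least 4 nt; with
probability 0.3 one H-type pseudoknot is inserted by pairing a hairpin
loop with a downstream unpaired run.  Paired letters are drawn as
canonical pairs in random orientation; unpaired letters are uniform.
Generation is reproducible via spawned seed sequences.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: non-canonical and lone pairs, bulges and
internal loops inside stems, kissing-hairpin and higher-order
pseudoknots, family-specific architectures, and realistic sequence
composition beyond the canonical-pair constraint (real stems are
GC-biased; synthetic unpaired regions are uniform).  Numbers measured on
this generator (break rates, compression) characterize the machinery,
not expected performance on bpRNA-scale data.

## Problem sizes and experiment design

The validation experiments use 500 synthetic structures (lengths
200–1,200) for the label and oracle checks, 1,000 random pair sets for
the pseudoknot brute-force cross-check, and a training run of 300
labeled examples for 20 epochs evaluated on 100 held-out structures with
a maximum fragment length of 500 nt (so that most of the suite actually
gets partitioned).  The random baseline is matched for cut count per
recursion node: at each node it asks the trained cutter how many cuts it
would place on that node's sequence and places that many uniform-random
admissible cuts under the same margin and separation constraints.  The
two recursions necessarily diverge after the first random draw, so
matching is per node rather than per tree.

## Known limitations

- The desk-scale trained model learns a composition/context heuristic,
  not full structure awareness; its break-rate advantage over matched
  random cuts is real but far from the zero-breakage ideal labels.
- Pseudoknots spanning what become different fragments are
  unrecoverable by construction; only a pseudoknot-capable fragment
  predictor can recover the rest.
- The IR tie-break (equal ranges delete the 3'-most group) and the
  per-group range definition (max j − min i) are one consistent reading
  of the incremental-range criterion; implementations differ in the
  literature.
- Merged discontinuous fragments are presented to predictors as plain
  concatenations with no junction marker; a predictor may pair across
  the junction, and such pairs are kept and mapped back.
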