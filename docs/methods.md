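# Methods

This note records the models, parameter choices and numerical decisions
behind `ehmmalign`, in the order the pipeline uses them.

## Backbone/query split

With a single mixed-length input, sequences are split by ungapped
length: either an absolute threshold (`length >= t` → backbone) or a
fraction-of-median policy (backbone = lengths within `f·median` of the
median, default `f = 0.25`). Curated biological datasets usually get an
absolute threshold read off the length histogram; the fraction policy
is the sensible default for simulated data. An empty backbone is a
configuration error, reported with a hint to loosen the policy.

## Centroid-edge decomposition

The backbone tree (newick; multifurcations allowed, branch lengths and
support values ignored) is cut recursively at the edge minimising
`max(|A|, |B|)` over the two leaf sides. Ties are broken by the
lexicographically smallest sorted label list of the smaller side, which
makes the decomposition fully deterministic; the tree's arbitrary
rooting is normalised away by deduplicating complementary bipartitions.
Recursion stops when a subset has at most `max_subset_size` leaves
(default 50). Every subset touched is recorded, so the three ensemble
variants are all views of one decomposition: the disjoint minimal
subsets (default), those plus the full set, or the whole laminar
family. Single-sequence subsets are permitted with a logged warning —
their profile HMM is degenerate but well defined.

## Profile HMMs

Each ensemble subset induces a sub-alignment (all backbone columns
retained, including all-gap ones). A column becomes a match state when
its non-gap occupancy is at least `symfrac` (default 0.5, the common
profile-construction default). Every row then traces a unique state
path — letter in a match column → M, letter elsewhere → I anchored at
the preceding match state, gap in a match column → D — and transitions
are Laplace-smoothed path counts over the *full* 9-transition profile
topology (M/I/D each to M/I/D, so I→D and D→I are allowed). The full
edge set is deliberate: it guarantees every observed path has nonzero
probability under the counted model, at the cost of exact parity with
tools that forbid I↔D transitions. Parity with any external profile-HMM
builder is explicitly not claimed; only the model's own consistency and
the comparability of its bit scores matter downstream.

Pseudocounts: 1.0 on match emissions, 0.1 on transitions. The match
emission for letter `a` is `(count_a + pc) / (unambiguous + pc·K)` with
`K` the alphabet size; the denominator counts unambiguous letters only,
because including ambiguity codes in the denominator while excluding
them from the numerator would break normalisation. Ambiguity codes
(N, R, …, X) add no counts and emit at the background probability during
scoring. Insert states emit the uniform background. RNA `U` is mapped to
`T` internally; stored sequences are never mutated, so the original
letters reappear on output.

Bit scores use a null model with uniform background and a geometric
length term with extension probability `n/(n+1)` at query length `n` —
a transparent stand-in for the usual R-type null. Only score
*differences* across the ensemble matter for the weights, so the null's
absolute calibration is immaterial.

## Merged model

Profile states map into backbone coordinates via each HMM's column map
(M_k and D_k to their column; I_k to the insert state anchored after
its column, I_0 to the shared before-first anchor). The merged topology
is the exact union of the mapped edge sets, with bookkeeping of which
HMMs support each edge and each emitting state. Merged match states are
the union of the mapped match columns — not restricted to any single
HMM's match set — because the default disjoint ensemble need not
contain a full-backbone HMM at all.

Per query, HMM `i` receives weight `w_i ∝ 2^{b_i}·s_i` (bit score
`b_i`, subset size `s_i` as a prior), computed by a log-domain softmax
so extreme scores cannot overflow; if every score is `-inf` the weights
fall back to uniform with a warning. The same size-prior formula is
applied to hierarchical (`upp`) ensembles, each subset with its own
size. Edge and emission values are weight-averaged over supporters
*without* renormalising the weights over supporters; the per-state
outgoing renormalisation absorbs the missing mass. Insert-state
emissions are merged by the same rule as match emissions (the least
surprising completion; merging affects them only where subsets
disagree, and insert emissions are background anyway). A state whose
supporters all carry zero weight would have zero outgoing mass; this is
asserted as a model error rather than silently patched.

## Glocal edges

To let an entire short query align to an interior backbone window, the
merged model receives entry edges Start→M_c with probability `0.1/S`
each (`S` = number of merged match states, total entry mass 0.1) and
exit edges M_c→End and D_c→End with probability 0.1. These *set* the
named edges — including any pre-existing Start→M or M→End edge — so the
pre-normalisation constants are exact; every state's outgoing
distribution is then renormalised. The equal-entry reading (total 0.1
split equally) is the only one that keeps the entry mass a probability
for S > 10. One knowable consequence: after renormalisation, exiting at
the *last* match state is cheaper than exiting mid-model (the last
state has fewer competing outgoing edges), so on weak-signal toys the
Viterbi path can prefer a terminal window over an interior one with
slightly better emissions. With realistic column signal the emissions
dominate and fragments land in their true window.

## Dynamic programming

All DP runs in natural-log space over a state ordering in which every
silent-to-silent edge advances the backbone column, so one sweep per
sequence position suffices (delete chains are acyclic; insert
self-loops consume a letter). Forward uses log-sum-exp; Viterbi
tie-breaks deterministically by preferring predecessor M over D over I,
then the lower state index, and returns the path including the End
state. An empty query is legal and takes the pure-deletion path.

## Transitivity merge and output conventions

Backbone columns are preserved in order; each query letter placed by a
match state goes uppercase into its column; each insertion segment
opens fresh columns after its anchor, lowercase and private to its
query, with blocks at a shared anchor laid out in query input order.
Any layout that keeps insertion letters unshared is equivalent under
sum-of-pairs scoring, since lowercase letters participate in no
homologies by definition.

## Sum-of-pairs scoring

A homology is an unordered pair of residues (id, ungapped index)
sharing a column; lowercase letters yield no pairs but still advance
the residue index. SPFN = reference-only pairs / reference pairs;
SPFP = estimate-only pairs / estimate pairs; a side with no pairs
scores 0 by convention. `spfn(est, ref) == spfp(ref, est)` holds by
construction. Query-only mode keeps pairs touching at least one query
id. The average error `(SPFN+SPFP)/2` is the single-number summary.

## Synthetic data

The simulator evolves a root sequence down a random binary tree
(uniform joins, unit branch lengths) with per-site substitution
probability, per-site deletion and per-gap insertion probability
`indel_prob/2` each, and geometric indel lengths. Residues carry
globally ordered site ids, so the emitted alignment is the exact true
alignment. It deliberately omits rate heterogeneity across sites,
selection, and realistic gap-length mixtures — enough signal for
placement-recovery experiments, not a substitute for biological
benchmarks; passing tests therefore demonstrate correctness of the
machinery and recoverability under honest but simplified conditions.

The fragmenter selects a seeded subset of sequences (default half) and
trims each to a substring whose length is drawn from Normal(mean, sd),
rounded and clamped to `[1, source length]` (the protocol's handling of
out-of-range draws is unstated; clamping is the documented choice),
with a uniform start offset. The high-fragmentary (HF) preset targets a
mean of 25% of the median length; the ultra-high-fragmentary (UHF)
preset exactly half that; sd is 60 at benchmark scale (medians ≈1550).

## Desk-scale experiment sizes

The placement-recovery experiment (tests and `scripts/acceptance.py`)
uses a 20-taxon backbone of root length 300 (per-branch substitution
0.05, indel 0.01, mean indel length 2), 10 held-in fragments at mean
25% of the median with sd 12 (sd 60 scaled by the ratio of the fixture
median to the benchmark median, ≈75/388), and decomposition subset size
10 — at 20 backbone sequences the benchmark default of 50 would leave a
single subset and no ensemble structure to merge. These sizes are the
package's standing desk-scale study conditions. Under them the
query-only average error is ~0.005–0.023 across seeds, and the
regression test pins a frozen threshold of 0.03, initialised from the
first verified run (0.0055) with headroom for the stochastic fragment
draw; the no-glocal control on the same fixture measures 0.05–0.29 and
must be strictly worse.

## Known limitations

- Per-query parameterisation makes the merged model expensive on large
  ensembles; a `top_k` truncation and a merged-edge-count guardrail are
  provided, but no sparse/compiled DP.
- No posterior-decoding alignment, Stockholm/PHYLIP I/O, or alignment
  masking; tree and backbone-alignment estimation are inputs, not
  features.
- The adjusted-weight prior for hierarchical ensembles reuses the
  subset-size formula; alternative priors are plausible and the choice
  is isolated in `compute_adjusted_weights`.
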