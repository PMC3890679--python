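# Methods

This note documents the models, conventions and numerical choices behind
`barcodekit`, in the spirit of the methods documentation of packages like
msprime or statsmodels: what is computed, under which assumptions, with
which defaults, and where the design was genuinely open.

## Distances

**K2P.** Pairwise distances use the Kimura two-parameter model,
`d = -1/2 ln[(1-2P-Q)√(1-2Q)]`, with `P = transitions / n_sites` and
`Q = transversions / n_sites` counted over the *comparable* columns of a
pair. Comparable means both sequences carry an unambiguous `A/C/G/T`:
gaps, `N` and all IUPAC ambiguity codes are excluded per pair (**pairwise
deletion**). This is the standard convention for barcode libraries and is
what lets heavily degraded queries participate — they simply contribute
fewer sites. Treating ambiguity codes as missing rather than fractionally
matched is conservative and only matters for badly damaged sequences.

**MISSING semantics.** A pair yields MISSING (NaN) when fewer than
`min_overlap` sites are comparable (default **100 sites**, configurable)
or when the logarithm's argument is non-positive (`1-2P-Q ≤ 0` or
`1-2Q ≤ 0`, i.e. saturation). MISSING propagates: summaries skip such
pairs and report their count; the tree builder refuses incomplete
matrices outright rather than imputing silently. The 100-site floor is a
declared default, not an inference — it corresponds to the shortest
fragments one would trust for a distance at all.

**Tajima's K.** Reported as the mean number of substitutions per
nucleotide over all unordered pairs, i.e. the mean of the *p*-distance
(uncorrected) upper triangle — the statistic's literal definition — not
the K2P-corrected mean.

## Barcode gap

Distances partition exhaustively and exclusively into intraspecific
(conspecific pairs) and interspecific sets. The two sets are compared
with a Wilcoxon rank-sum test: exact when both samples are small
(min *n* ≤ 20) and tie-free, otherwise the normal approximation with the
standard tie-corrected variance (delegated to
`scipy.stats.mannwhitneyu`; an enumeration oracle in the test suite
verifies the exact branch). Because published summaries report medians
in text and means in tables, the per-locus summary emits both.

Per individual, the barcode gap holds when the nearest heterospecific is
farther than the furthest conspecific. Singletons (species with one
representative) have no conspecific distances: their `max_intra` and
`has_gap` are undefined rather than zero, they are excluded from intra
statistics, and their count is reported so either convention can be
reconstructed.

## Identification estimators

All three estimators are leave-one-out: the focal record is removed from
the library before being identified (the standard convention; retaining
it would trivially self-match).

- **Near neighbour** — true iff any tied nearest non-self neighbour is
  conspecific.
- **Best close match** — the tied nearest neighbour(s) *within a
  threshold* decide: all conspecific → correct; all heterospecific →
  incorrect; mixed → ambiguous; none within the threshold → no ID.
- **Threshold (BOLD-style) identification** — as above but over *all*
  neighbours within the cutoff (default 1%), not only the nearest.

Singletons are retained and necessarily score false / incorrect / no-ID;
their count is reported separately. Records with no usable (non-MISSING)
distances are excluded and logged.

**Threshold optimisation.** The optimiser scans a grid (default
0.1%–5% in 0.01% steps) and scores each candidate *t* per record:
a *false negative* when the record's furthest conspecific lies beyond
*t* (the cutoff splits a species), a *false positive* when its nearest
heterospecific lies within *t* (the cutoff admits a wrong species).
Cumulative error is their sum; ties break toward the smallest *t*. This
per-record furthest-conspecific / nearest-heterospecific bookkeeping is
the established optimisation used for barcode libraries (it is how the
R package spider's `threshOpt` scores thresholds) and it guarantees
that under a clean barcode gap the optimum lands just above the largest
intraspecific distance. Scoring the BOLD-style classifier's verdicts
instead would let the zero-error region begin *below* the largest
intraspecific pair whenever species have more than two representatives
(the nearest conspecific saturates first), which contradicts the
intended "threshold inside the gap" behaviour; the full error profile is
emitted so users can apply any alternative rule. Whether best close
match should use this optimised threshold or the fixed 1% is left
explicit in the interface; the pipeline defaults to the optimised value.

## Query matching

Queries are matched by Needleman–Wunsch alignment with free end gaps
(match +1, mismatch −1, gap −2, terminal gaps 0; delegated to
`Bio.Align.PairwiseAligner`), so a short degraded fragment aligns inside
a full-length reference without penalty. Percent identity is computed
over the aligned columns excluding terminal overhangs; hits below
`min_identity` (default **90%**, low enough to represent poor but real
hits while flagging them) are dropped, and ranking is by identity, then
aligned sites, then hit id. E-values are deliberately not computed: a
local matcher has no database-size statistics, and percent identity is
the headline number read off such searches anyway.

Adjudication compares the best hit's species with the species expected
from the sample's vernacular name (exact string over the lookup's listed
synonyms; no fuzzy matching). A vernacular that is absent from the
lookup, or documented without a scientific name, yields status
`unverifiable` — reported distinctly from a true mismatch. The match
percentage uses **all** queries as denominator, amplification failures
included (11 matches among 18 queries is reported as 61%, not 11/16).

## Trees

Query placement uses neighbour joining rather than a maximum-parsimony
heuristic search: the tree is corroborative (where does a query attach?),
and NJ answers that deterministically at desk scale. The agglomeration
breaks Q-criterion ties toward the lexicographically smallest pair of
subtree labels, making the topology independent of taxon input order;
negative limb estimates are clamped to zero; the final three lineages
join at a trifurcating root, which represents the unrooted topology
exactly (additive matrices are reproduced to numerical precision).

Bootstrap support resamples alignment columns with replacement, rebuilds
the distance matrix and tree per replicate, and reports the percentage
of replicates containing each internal bipartition. Replicate *r* uses
RNG seed `seed + r` so any single replicate can be reproduced. Supports
are read as weak at 50–74% and strong at 75–100%.

For each query tip the placement report gives the species set of its
sister group and the support of the smallest clade joining the query to
a reference. The sister group is chosen rooting-independently: among the
neighbour subtrees at the query's attachment node (the other children
plus, when applicable, the complement through the parent), the smallest
one containing a reference tip. A placement is *resolved* when that set
is monospecific.

## Synthetic data

The generator emulates the study design the analyses assume: ~108
species (1–3 individuals each, drawn uniformly) whose intraspecific
divergence is far below interspecific divergence. Sequences evolve on a
**star phylogeny** — a uniform-random root, a branch of expected length
`inter_target/2` substitutions/site to each species ancestor, and
`intra_target/2` to each individual — under a K2P process with
transition/transversion rate ratio κ (default **2.0**). Branch lengths
are parameterised directly as expected K2P distances via the exact
per-site transition probabilities, so realized distances are unbiased
for the targets (conspecific pairs ≈ `intra_target`; heterospecific
pairs ≈ `inter_target + intra_target`). The star between species makes
expected distances analytically controllable and matches the analyses'
assumptions (no rate heterogeneity, no tree structure between species);
it deliberately does *not* emulate phylogenetic clustering of species,
indels, codon structure or mixed-material samples, so passing tests
demonstrate correctness of the machinery under the stated divergence
structure, not robustness to every feature of real herbarium data.

Per-locus pipeline defaults mirror the two plastid barcodes: 552 bp
with inter/intra targets 0.080/0.0002 and 915 bp with 0.220/0.0008;
their concatenation (1467 bp) keeps per-locus column spans.

**Degradation** removes a contiguous terminal fraction (5′ or 3′ at
random; default 30%) — represented as gaps so alignment coordinates
survive — and masks random surviving positions to `N` (default 2%).
A query left with fewer than **50 bases** is an amplification failure
and carries no sequence. **Vernacular mislabels** reassign
`round(rate × n_queries)` queries (default rate 5/18) the name of a
random other species; only amplifiable queries are mislabelled, since a
wrong name on a sample with no sequence is unobservable downstream —
this makes the expected market outcome exact: 18 queries − 2 failures −
5 mislabels = 11 matches (61%).

## Problem sizes

The test suite and the acceptance script exercise: per-locus statistics
at the full design scale (108 species, ~220 sequences); estimator/oracle
equivalence on 200 random 20-record matrices; threshold and
identification recovery on a 50-seed panel of 20 species × 3 individuals
at 600 bp; and 100-replicate bootstraps on a 5-seed subset of that panel
— sizes at which every check completes in seconds while the statistics
of interest (realized divergences, gap fractions, clade supports) are
stable.

## Known limitations

- Only K2P and *p*-distances; no JC/F84/GTR or maximum-likelihood
  distances.
- The local percent-identity matcher is not BLAST: no seeding, no
  E-values, no database statistics.
- NJ placement is not a parsimony or likelihood phylogeny; supports on
  deep inter-species structure of star-simulated data are essentially
  noise (only species-level clades are meaningful there).
- Name adjudication is exact-string; orthographic variants of vernacular
  names must be listed as synonyms to match.
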