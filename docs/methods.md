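# Methods

## Index: the k-truncated generalized suffix tree

For sequences S₁,…,Sₙ (each genome contributes a forward and a
reverse-complement entry) the index stores every substring up to length
*k* plus the sentinel-terminated suffixes shorter than *k*: for each start
position the window `S[p : p+k]`, or `S[p:] + "$"` when fewer than *k*
symbols remain.  Each node's `count` is the exact number of window start
positions whose window carries the node's path label as a prefix, which for
labels of length ≤ the remaining sequence equals the plain substring
occurrence count.  A single shared sentinel suffices because leaves carry
counts rather than one suffix each.

Construction is offline: all windows are extracted, sorted, and
de-duplicated as fixed-width byte rows (numpy), and the sorted unique words
are folded into the compressed tree with a stack over longest-common-prefix
values — the standard suffix-array-to-suffix-tree transformation, linear in
the number of unique words.  The by-product is, per node, a contiguous
interval of sorted occurrence positions, which serves as the occurrence
index: locating a pattern is one root-to-node walk and occurrence listing is
a slice.  The resulting tree is node-for-node the one an online
(Ukkonen-style, depth-frozen) construction would produce; suffix links are
not required by this route and are left unset.

Coordinates are 0-based half-open throughout (BED-native).  Windows
containing an IUPAC ambiguity symbol are not indexed: markers must be
exact-matchable over {A,C,G,T}.  Genomes are treated as linear; an optional
wrap-by-k−1 extension exists for circular chromosomes but is off by default,
and annotations must be pre-split linear intervals (features spanning the
circular origin are out of scope).  Labels ending in the sentinel are
excluded from all marker logic — they cannot occur as general genomic
substrings.

## Annotation-guided detection

Genes on opposite strands are distinct keys (g+, g−).  Annotations are
projected onto the reverse-complement copy with mirrored coordinates
(pos → L − pos) and flipped strand, so an occurrence on the RC copy over a
g+ region scores toward g−.  Leaf scores are exact integer nucleotide
overlaps of *window* intervals (length up to k) with annotated intervals;
inner nodes sum their children, implemented as interval sums over a leaf
prefix-sum matrix (genes × leaves), which makes the conservation property
(parent = Σ children) exact by construction and cheap to verify.

The DFS dismisses, with their subtrees, nodes whose labels occur once or
already contain a disqualifying repeat; a node with no annotation overlap is
*not* pruned (a deeper word may still gain dominance).  At the shallowest
node whose dominance ratio strictly exceeds the threshold (default 0.95) the
marker — parent label plus one edge symbol — is emitted; since edges carry no
branching, the marker has exactly the node's occurrences and support.  The
threshold comparison is performed on the ratio (`best/total > t`), so integer
score tables behave as the rational inequality dictates at boundary cases
like 95/100.  A tie for the argmax can never dominate at thresholds ≥ 0.5,
so no tie-break is needed.

## Probability-based detection

The order-3 Markov model is fitted from {1,2,3,4}-mer counts over the same
indexed text the tree counts (forward plus reverse complements — observed
and expected counts must share a sample space), with additive smoothing
(pseudocount 1 by default; on genome-scale data every 4-mer is observed and
the smoothing is inert).  Contexts at sequence ends without a successor do
not contribute.  The chi-square statistic uses the closed two-category form
`U² = (n − N·P(w))² / (N·P(w)(1 − P(w)))` with N the summed length of all
indexed sequences; the threshold z is applied to U² directly, with an
additional one-sidedness requirement n > N·P(w) (the statistic alone would
also flag under-represented words) and a minimum support of 2 (a word seen
once is never a marker).

Word probabilities for every prefix of every unique word are precomputed as
a cumulative product matrix, so the DFS only consults per-node flags; at an
emitted node the shortest significant prefix of the incoming edge word is
found by scanning the cumulative products.  Probabilities are ordinary
doubles: the smallest relevant value (4⁻³⁰ ≈ 10⁻¹⁸) is far above underflow.

Expected false-positive behaviour is a design property worth stating: a
chance-repeated word with n = 2 has U² ≈ 4/(N·P(w)), so every ℓ-mer that
recurs by chance with 4^−ℓ < 4/(zN) is significant, and uniform random text
of N symbols yields on the order of 2N/z such words.  At z = 50 000 this is
a handful per 100 kb — the threshold controls over-representation relative
to expectation, not a family-wise error rate over all words.  Raising z
removes these first (they are the shortest, most probable words).

## Repeat filter and marker-set reduction

A word is rejected when it contains a unit of at most l = 4 symbols repeated
more than r = 3 times, detected by a sliding-window scan that counts
completed periods; `ATATATA` (three full AT periods) passes, `ATATATAT`
does not.  Equivalently: a run of at least r·u consecutive positions i with
w[i] = w[i−u]; the vectorized form computes, per unique word, the shortest
prefix length at which such a run completes, letting the DFS prune a
repetitive subtree the moment the repeat is complete.  The final reduction
walks every suffix of each candidate through a trie of all candidates and
drops any word containing a shorter candidate, keeping the shorter word;
the result is a substring antichain independent of input order.

## Classification, rough annotation, evaluation

A marker's target is the gene key with the largest summed overlap over all
its occurrences, after mapping RC-copy occurrences back to forward
coordinates with flipped strand; argmax ties break lexicographically and
are flagged.  Occurrences of targeted markers merge into fragments per
(genome, gene, strand) under strict positional overlap (book-ended
intervals stay separate; a merge-gap parameter is exposed, default 0).
Each fragment pairs with the reference annotation sharing the most
positions, if that is at least 25 % of the fragment length; categories are
equal / Δ± / different, with unpaired fragments FP and never-chosen
references FN.  A reference may partner several fragments.  Because the
denominator of such category percentages is a reporting choice, reports
carry both normalizations explicitly (share of all five categories, and
share of fragments) plus counts per reference annotation.  Fragment categories are
tallied under the fragment's own gene class (protein / rRNA / tRNA /
control region via a configurable name-pattern table); FN under the missed
reference's class — this keeps per-class counts a partition of the totals.
Gene coverage divides the summed marker–annotation overlap of a gene key by
its summed annotated length; the optional 100-bin relative-position
histogram distributes each overlap proportionally, so bins sum to the total.

## Synthetic data

The generator emulates the structure that matters to the method: one random
ancestral sequence per gene family; per genome an independently point-mutated
copy of every gene (default 5 % per site — a moderate divergence under which
a 30-mer stays intact in ~21 % of copies, so conserved words recur tens of
times in 100 genomes); AT-rich composition (default 70 %, as in metazoan
mitogenomes); per-genome gene-order shuffling (mitogenomes rearrange, so no
test may assume colinearity); short random spacers (2–20 nt, mitogenomes
are dense); minus-strand genes (nad6 and six tRNAs in the default 37-gene
≈16.5 kb complement).  A reduced ~3 kb, 10-gene preset keeps every
structural feature at a fraction of the cost.  The "observed" annotation
layer injects strand flips, renames, drops, and spurious intervals at
configurable per-annotation rates, with an error table as ground truth.
Everything derives from one seeded generator, so identical seeds give
byte-identical datasets.

What the generator does **not** model: transition/transversion bias, indels,
rate heterogeneity along genes, tRNA secondary structure, genes spanning the
circular origin, and real control-region hypervariability (the control
region here evolves like any other feature).  Passing tests therefore
demonstrate algorithmic correctness and the method's statistical behaviour
under controlled conditions, not annotation accuracy on real database
records.

## Problem sizes and defaults

Package defaults: k = 30 (the vast majority of useful markers is shorter),
repeat parameters l = 4 and r = 3 (tuned to short words), dominance
threshold 0.95, z = 50 000, minimum support 2, pseudocount 1.  The test suite and the
acceptance script run on synthetic datasets between 8 and 100 genomes
(reduced preset, ~3 kb) plus a 10 × 16.5 kb planted-cassette fixture and
100 kb uniform-random negative controls; these sizes keep full brute-force
oracle verification (every node count, every marker's dominance recount)
tractable while preserving every qualitative contrast the method exhibits
at corpus scale: probability-based detection finds more and longer markers
than guided detection, stricter z lengthens and rarefies markers, rRNAs are
covered most densely, and the guided method trades recall for a higher
false-positive share.

## Known limitations

- The guided score of an inner node aggregates window overlaps of its
  *extensions*, an approximation the DFS inherits: dominance describes the
  k-length neighbourhood of a word, so short guided markers can have
  additional occurrences touching no annotation at all.
- Classification assigns exactly one target; conserved words spanning a
  conserved gene boundary are attributed to the single argmax gene.
- Memory is dominated by dense per-leaf matrices (words, prefix
  probabilities, gene scores); hundreds of genomes are comfortable on a
  workstation, but corpus-scale runs (thousands of mitogenomes) would want
  the planned compressed representations rather than this reference
  implementation.
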