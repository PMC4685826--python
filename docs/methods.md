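# Methods

## The problem and the model

Environmental V4 SSU rRNA amplicon surveys of coastal marine sites recover
fungal sequences whose provenance is ambiguous: a resident marine community
is mixed with terrestrial spores and other propagules washed or blown in
from land. The package's analytical core is an occurrence-based decision
rule that uses two independent kinds of evidence — recurrence across
libraries and nucleic-acid template — to separate the two. An OTU cluster is
retained as putatively resident iff it occurs in at least two libraries with
at least one RNA-template library among them, or in at least three libraries
of any template. RNA evidence is privileged because rRNA decays quickly
outside living cells, so RNA-derived reads indicate ribosomally active
organisms rather than preserved DNA. One "sample" is one nucleic-acid
library: the DNA and RNA libraries prepared from the same water are two
samples, which is exactly what lets the RNA clause bind. The rule is read
literally as `(n_samples >= 2 AND n_rna >= 1) OR (n_samples >= 3)`, so a
DNA-only cluster seen in three or more libraries is retained. The RNA
library must itself be among the occurrences (not merely exist at the
site). Occurrence counts presence (>= 1 read), never abundance.

## Clustering hierarchy

Reads are dereplicated into amplicons (unique sequence + read multiset).
Stage one is single-linkage clustering at Levenshtein radius `d` (default
1): an OTU is a connected component of the <= d edit-distance graph, grown
breadth-first from abundance-ranked seeds; the representative is the most
abundant member. Ties in abundance are broken lexicographically by sequence
everywhere, making both stages order-independent. Stage two greedily merges
OTU representatives into OTU clusters: candidates, in (total reads desc,
sequence asc) order, join the first cluster whose *founder* is within
`max_diff` (default 1) edits, else found a new cluster — founder-only
comparison mirrors greedy centroid clusterers and keeps the stage
deterministic. For d = 1 the neighbour search uses a symmetric-deletion
index (a sequence and all its single-character deletions share a hash key
with any sequence one edit away) with exact verification, giving near-linear
candidate generation; other radii fall back to a length-bucketed pairwise
scan. The contract is the partition, not the algorithm: the test suite
checks equality with brute-force connected components on hundreds of random
instances.

Masking before re-clustering is *not* applied: re-clustering operates on
full-length unmasked representatives, with the 1-nt tolerance standing in
for mask-equivalence. Column masking exists in the phylogenetics module,
where it belongs to the alignment workflow.

## Percent identity and the marine flag

Identity is computed on an optimal semi-global alignment with match +1,
mismatch −1, internal gap −2 and terminal gaps at −1 per base; identity is
100 × matches / columns with terminal-gap columns excluded, so a perfect
fragment of a longer reference scores 100. Terminal gaps carry a reduced —
but deliberately non-zero — cost: with fully free end gaps the maximum-score
alignment of two *unrelated* sequences degenerates into a few-column perfect
terminal overlap (score +2 beats the full-length alignment's ≈ 0), which
would report ~100% "identity" for arbitrary pairs and make every identity
threshold vacuous. The half-cost leaves all fragment/containment cases
unchanged (every alignment of such a pair carries the same end-gap total)
while forcing unrelated pairs to their true ~50–65% identity. Alignment is
done by Biopython's `PairwiseAligner` (C implementation); a pure-Python DP
oracle with identical scoring verifies optimal scores exactly in the tests.

Best-hit search ranks references by a cheap edit-distance screen (top 8
within 20 edits of the closest) and aligns only those candidates exactly —
the same screening idea word-based amplicon search tools use. Passing
`n_candidates=None` gives the exhaustive search; with a reference collection
no larger than the candidate cap the two are identical. Assignment succeeds
at >= `min_identity` (default 80, a phylum-level screen); the marine flag is
strict: best identity to a marine-annotated reference must *exceed* 99.

## Synthetic community

`SynthConfig` defaults define the study conditions: 6 sites, water column in
3 size fractions × {DNA, RNA} plus sediment {DNA, RNA} per site (48
libraries), 20 resident marine fungal taxa, 200 terrestrial transients, 20
non-fungal background taxa (other eukaryotes, half marine-annotated, so
fungal-fraction statistics have a denominator), per-base substitution rate
ε = 0.002, resident occupancy Bernoulli(p_occ = 0.6) per library, seed 42.
Reference sequences are independent random 380-mers (typical V4 length)
with pairwise edit distance >= 10 enforced, so cluster-to-taxon attribution
is unambiguous. Read depth of an occupied taxon is log-normal (σ = 1.0)
with the median scaled so a library's expected total is `reads_per_sample`
(default 150 — the survey this emulates does not state per-library depths,
so this is a desk-scale convention chosen once). Each transient taxon lands
in exactly one DNA library with 1–3 reads. The error channel is
substitution-only by default — it keeps d = 1 behaviour analysable — with an
optional indel channel for stress tests emulating homopolymer-type errors.

What the generator does *not* emulate: chimeras, PCR bias, substrate- or
depth-structured community composition (fungal fractions per substrate are
therefore ~40% here, not the strong sediment/water contrast of real data),
phylogenetic relatedness among taxa (references are independent, so the NJ
tree of retained clusters has no true clades and uniformly low bootstrap
support is the correct result), and realistic taxonomy strings. Passing
tests therefore demonstrate the *machinery* — partition correctness, rule
arithmetic, recovery under the stated noise model — not performance on real
454 data.

## Distance phylogenetics

LogDet/paralinear distance per pair: joint 4×4 base-frequency matrix F over
pairwise-gap-deleted sites, pseudocount c = 0.1 added to every cell before
normalization (V4-length alignments routinely produce zero cells), then
`d = -¼[ln det F − ½ Σₐ(ln fₐ⁽ⁱ⁾ + ln fₐ⁽ʲ⁾)]`. The pseudocount biases d
upward by O(c / sites): ~0.003 at 400 sites, but ~0.14 on an 8-nt toy pair —
"zero on identical rows" holds only asymptotically, which is why near-zero
assertions in the tests use realistic lengths. Non-positive determinants
(saturated pairs) return the sentinel 50.0, and computed distances are
capped there so the sentinel stays maximal; pair orientation is
canonicalized before the determinant so the guard cannot fire asymmetrically
at the numerical boundary. Neighbour joining uses the Q criterion with
Studier–Keppler updates; ties in Q break on the lowest (node id, node id)
pair in creation order; a negative branch length from a join is clamped to
zero with the deficit moved to the sister edge, preserving the joined
distance. Bootstrap resamples alignment columns with replacement, rebuilds
the LogDet/NJ tree per replicate, and maps bipartition frequencies onto the
full-data tree (not a consensus), matching how support is conventionally
displayed on a single topology.

## Cell counts and concordance

Replicate filter counts give mean and sample standard deviation (n−1
denominator; a single replicate reports sd = 0 and is flagged). The
staining-method comparison (double WGA+CFW vs single WGA) is represented as
these replicate statistics for two labelled sets with a difference of means
and no hypothesis test, because none is part of the analysis being
reproduced. Concordance is ordinary least squares of percent chitin-walled
cells on percent RNA fungal reads with the two-sided t-test p-value (n−2
df) for the slope — `scipy.stats.linregress`, cross-checked in tests against
direct numerical integration of the t density. The synthetic cell-count
generator draws chitin fractions uniformly in the 0.15–1.75% band observed
in real water-column samples and makes the RNA-read percentage a noisy
affine function of it, so R² parameter recovery is testable with a known
analytic value.

## Pipeline and reproducibility

`run_pipeline` executes simulate → cluster → assign → filter → biogeo →
phylo → cellcounts from one flat config; all randomness derives from one
root seed expanded per stage (`numpy.random.SeedSequence`), outputs are
plain text (FASTA/TSV/JSON/newick), and a manifest records parameters and
SHA-256 of every artifact — reruns are byte-identical. Defaults follow the
analysis being reproduced where it states them (d = 1, 1-nt re-clustering,
>99% marine flag, >= 3 sites, 1000 bootstrap replicates, mask threshold
0.5). The pipeline's phylo stage stacks the equal-length representatives
produced by the substitution-only channel directly into an alignment;
real (indel-containing) data must come through the `phylo` subcommand with
an externally aligned FASTA, since alignment construction is outside the
package's scope.

Error handling is fail-loud throughout: ambiguity codes in reads, unknown
sample ids, malformed size annotations, negative counts, asymmetric
distance matrices and all-gap maskings raise immediately with the offending
record named; the CLI distinguishes config (exit 2), data (exit 3) and
internal (exit 1) errors.

## Known limitations

- The identity convention reports the identity of *one* optimal alignment;
  co-optimal alignments can differ slightly (a fraction of a percent of
  random related pairs in the tests).
- The occurrence filter is presence-based by design and cannot use
  abundance evidence; prevalence-vs-depth modelling is out of scope.
- LogDet distances with the fixed pseudocount are biased on very short
  alignments; the pseudocount is exposed in the config.
- The greedy re-clustering stage is order-dependent in principle; the
  canonical (abundance, sequence) ordering makes it reproducible but, like
  the tool it mirrors, not invariant to abundance perturbations.
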