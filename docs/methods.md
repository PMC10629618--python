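# Methods

This note documents the models and procedures implemented in `cggtools`,
the defaults and why they were chosen, the numerical details, and what the
synthetic test data does and does not establish.

## Sequence admission and formats

Residue strings are canonicalized before any analysis: uppercased,
whitespace removed, one trailing stop `*` stripped; internal stops, empty
results and letters outside the 20 standard amino acids plus B, Z, J, U,
O, X are rejected. Canonicalization is idempotent, and everything
downstream (fingerprints, alignment, masking) sees only canonical strings.
The rare/ambiguous letters are passed through unchanged rather than
recoded; they score through a flat matrix fallback (below) so that real
data is tolerated without inventing chemistry for it.

File interfaces use 1-based inclusive coordinates throughout (matching
BLAST tabular); 0-based arithmetic is confined inside modules, with the
conversion at the reader/writer boundary only — one conversion point, no
off-by-one drift. FASTA is written with a 60-column wrap so outputs are
byte-stable. Duplicate FASTA ids are admitted with a warning at read time;
operations that index by id fail fast instead, which puts the failure
where it matters.

## Fingerprinting

The digest input is exactly the ASCII bytes of the canonical residue
string — no header, no terminator — rendered as 32 lowercase hex
characters of MD5. MD5 is retained deliberately: the task is identity
mapping, not security, and the digest is the established convention for
this protocol. Because a cryptographic collision is nevertheless possible
in principle, the index builder keeps one witness sequence per digest and
raises loudly if two unequal sequences ever share one; collisions are
never silently merged. Stripping the trailing `*` before digesting means
fingerprints of otherwise identical entries with and without a stop agree;
collections digested by tools that keep the stop would differ — a known
interoperability caveat.

## Low-complexity detection and selective masking

With infinite gap penalties, the optimal local alignment of a sequence
against an unbounded homopolymer of residue *r* cannot contain a gap, so
it is exactly the maximum-scoring contiguous segment of position scores
s_i = M(a_i, r). The implementation is the linear-time running-sum scan;
ties are resolved to the leftmost start, then the smallest end (kept
provably identical to the exhaustive all-segments search by resetting the
running sum only when it goes negative — zero-sum prefixes are retained).

Detection is multi-pass: each pass scores all 20 homopolymer targets on
the current working sequence, records the best segment if it reaches the
threshold (ties between residue types broken alphabetically, for
determinism), masks that residue's occurrences inside the span on the
working copy, and repeats. The working copy lets weaker tracts of other
residue types emerge after a dominant tract is neutralized, while reported
spans stay in original coordinates (masking never shifts positions). A
pass that detects a region containing no occurrence of its own target
residue (possible in principle when near-neighbour scores alone reach the
threshold) terminates the loop rather than spinning.

Masking is *selective*: within a detected span only the offending residue
is replaced by the mask character, default `X`. Since `X` scores −1
against every target, a fully masked output is a fixed point of detection.
Defaults — BLOSUM62, threshold 40, mask `X` — are conventional for this
method family and are exposed as options, not hard-coded. Note that
detected spans may extend a few positions beyond a biased tract through
residues scoring ≥ 0 against the target (e.g. K scores +1 against Q);
this widens the reported geometry but not the masked positions.

## Alignment engine

Local alignment uses Bio.Align's `PairwiseAligner` in local mode with
affine gaps. Gap costs follow the BLASTP convention — a gap of length k
costs open + k·extend, defaults 11/1 — mapped onto the aligner's
open/extend scores accordingly. The packaged BLOSUM62 is extended over
B, Z, J, U, O, X and `*` with a flat −1 for any pair touching a
non-standard letter: one consistent fallback across masking and search.
The engine is checked in the test suite against an independent pure-Python
affine dynamic program, itself validated on tiny strings against an
exhaustive enumeration of all monotone residue matchings.

The internal all-vs-all and query-vs-reference drivers exist so the
pipeline runs without external search tools at desk scale (hundreds of
sequences). They emit raw Smith-Waterman scores; the pairs-list E-value
column carries the monotone transform 10^(−score/10), not a
Karlin–Altschul calibrated E-value, and files written by the drivers say
so in a comment header. Downstream thresholds accept either a minimal
score or a maximal E-value, so externally produced BLAST tabular files
drop in unchanged. Large-scale search remains the job of BLAST/DIAMOND
via the pairs-list interface.

## Identifier encoding

Encoded ids have the shape `Code-tag-vv-nnnnnn`: a 4-letter species code
with initial capital, a free-form alphanumeric assembly tag, a 2-digit
collection version from 01, and a 6-digit serial from 000000 assigned
consecutively in input order. The complete original header becomes the
new description, so the encoding is information-preserving, and decode ∘
encode is the identity. The `-` delimiter is reserved (codes and tags may
not contain it), serial overflow past 999 999 records is a hard error,
and global id uniqueness is enforced when collections are concatenated.
Species codes are supplied explicitly by the user catalog; the helper that
suggests `genus[:3] + species[:1]` (e.g. *Taeniopygia guttata* → `Taeg`)
is advisory only, because collision policy across taxonomies belongs to
the user, not the mechanism.

## Markov clustering

The similarity graph takes w = −log₁₀ E (E = 0 capped at 200, keeping the
matrix well-posed) or raw bitscore; the two directions of a pair collapse
to one undirected edge at the maximum of the two weights. Self-loops of
weight max(incident weight, 1) are added at the matrix stage — standard
regularization ensuring aperiodicity. Iteration alternates expansion
(matrix power 2), inflation (entry-wise power, column renormalization) and
pruning of entries below 1e-5, stopping when the largest entry change
falls below 1e-6 or after 100 rounds (non-convergence warns and clusters
the current state). Column sums are asserted to 1 within 1e-9 after every
normalization. Vertices are indexed in sorted order, so the partition is
invariant to input edge order. Clusters are read from attractor rows of
the limit matrix; attractor systems sharing an attractor merge, and a
vertex attracted by two distinct clusters at numerically equal strength is
assigned to the lowest-indexed one (logged) so the output is always a
partition. Families are numbered from 1 by descending size, ties by
smallest member id. The dense-matrix implementation is intended up to a
few thousand vertices; beyond that a sparse representation would be the
growth path.

## Symmetrification and significance

The binary hit matrix has a true diagonal by convention (never validated).
Each asymmetric pair is arbitrated once by a Monte-Carlo shuffle test:
score the real pair, then N = 100 random permutations of one sequence
(composition preserved), and compute z = (S − mean)/sd; significant iff
z ≥ 10. A degenerate null (sd = 0) counts as significant only when the
real score exceeds the null mean. Significant pairs are set true both
ways, others cleared both ways; symmetric pairs are untouched, which makes
the operation idempotent. Per-pair RNG streams are derived from the seed
and the pair's indices, so results do not depend on visit order. The
z-threshold and shuffle count are deliberately conservative defaults for
a self-contained test with no database-size statistics behind it; both
are exposed as options, and the same machinery backs the
component-homology exclusion in fusion detection (one calibrated test
across the package).

## Multi-domain detection and clustering

A protein p is called multi-domain iff the validated matrix contains
neighbours x, y of p with no hit between x and y — a transitivity
violation; all witness pairs are reported. Core families are the
connected components over non-multi-domain proteins only; each
multi-domain protein is then attached, with annotation, to every core
family containing at least one of its neighbours. Excluding bridges first
and re-attaching after is what prevents one promiscuous multi-domain
protein from chaining unrelated families into a single component — the
reason this tool exists. The contrast is visible in the pipeline demo: the
Markov clustering places a fusion composite in one family with its
components, while this stage separates the cores and annotates the bridge.

## Fusion detection

Rows of the rectangular matrix are query-species proteins (candidate
components), columns are reference-species proteins (candidate
composites); only the best-scoring hit per cell is kept, with its
composite-side span — repeats are deliberately not split into units. A
component pair supports a fusion call when the spans overlap by at most
10 % of the shorter span (absorbing alignment end wobble; 0 would be
brittle, large values would admit overlapping-domain artefacts) and the
components are not significantly similar to each other (a significant
match means internal duplication, not fusion). Composites with ≥ 2
components in at least one valid pair are reported with every component
participating in a valid pair; three or more components (multiple fusion)
are allowed and reported together. The question is directional: swapping
which collection is query and which is reference changes what is being
asked, and composites are only ever reported from the reference side.

## Synthetic data: what it does and does not show

The generator draws background proteins uniformly over the 20 standard
residues — the simplest null, chosen so that compositional bias exists
only where an implant puts it and ground truth is exact. Implanted tracts
are pure homopolymers; planted families share an identical 80-residue
core with random 20-residue flanks; fusion trios place two full 120-residue
components into a composite joined by a 15-residue linker, so each
component's alignment span on the composite is sharply bounded by the
component itself. Default problem sizes (tens of sequences, 80–200
residues; 500-case oracle batteries; 100 random matrices for the
symmetrification property) were chosen to exercise every code path in
seconds on one core.

Real proteomes differ in ways the fixtures do not emulate: biased global
composition, families with genuine sequence divergence rather than
identical cores, partial-domain fusions whose spans wobble more than the
10 % slack, and search-score statistics from heuristic tools rather than
exact Smith-Waterman. Passing tests therefore establish correctness of
the algorithms and contracts, and recovery under idealized signal — not
field sensitivity/specificity on real genomes. One visible consequence of
the uniform null: random sequence occasionally contains a chance
tract that legitimately crosses the score-40 threshold (the worked example
in the README shows one), so the masking stage's background rate is small
but nonzero even on "featureless" input. For the planted-fusion analyses
the internal search threshold is set to score 100, above the empirical
noise floor of local alignments between unrelated random sequences of
these lengths (~40–55) and far below the planted-component scores
(several hundred).

## Known limitations

- E-values from the internal search are a monotone score transform, not
  calibrated statistics; thresholds on them are ordinal, not
  probabilistic.
- The Markov-clustering state is a dense matrix; memory grows
  quadratically in vertices.
- Fingerprints detect exact identity only; near-identical entries are the
  alignment stages' job.
- The mask character `X` collides with genuine ambiguity `X` in input
  data; masked and ambiguous positions are indistinguishable downstream.
- Domain boundaries are not inferred; multi-domain calls name witnesses,
  not coordinates.
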