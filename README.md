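# cggtools

A toolkit for desk-scale comparative genomics on protein sequence
collections, reimplementing a classic family of command-line tools as one
tested Python package: **MagicMatch**-style MD5 sequence fingerprinting,
**GeneCAST**-style selective masking of low-complexity tracts,
**CoGenT**-style structured genome identifiers, **Tribe-MCL**-style Markov
clustering of sequence similarity graphs, **GeneRAGE**-style binary-matrix
clustering with multi-domain detection, and **DifFuse**-style gene-fusion
(Rosetta Stone) detection. The pieces compose into a genome-comparison
workflow: fingerprint and cross-index collections, mask the query, encode
the reference, search, then cluster the resulting pairs-list into protein
families and call multi-domain proteins and fusion events.

It is written for bioinformaticians who need these operations scriptable
and reproducible: every stage reads and writes plain-text formats (FASTA;
the 12-column BLAST tabular pairs-list), every stochastic step is seeded,
and a synthetic-proteome generator with machine-readable ground truth makes
the whole pipeline testable offline.

## The methods in brief

- **Fingerprinting.** Two entries are the same protein exactly when their
  canonicalized residue strings are equal; the MD5 digest of those
  residues is a 32-character proxy for sequence identity, letting whole
  collections be cross-indexed in a single pass.
- **Low-complexity masking.** A tract biased toward residue *r* is a
  high-scoring local alignment against an unbounded homopolymer of *r*
  under infinite gap penalties, which reduces exactly to the
  maximum-scoring contiguous segment of per-position scores
  *s<sub>i</sub>* = M(*a<sub>i</sub>*, *r*) (BLOSUM62 by default). All 20
  homopolymer targets are scored per pass; the best segment ≥ *T*
  (default 40) is masked *selectively* — only occurrences of *r* are
  replaced by `X` — and passes repeat until nothing reaches threshold.
- **Markov clustering.** The pairs-list becomes a weighted graph
  (w = −log₁₀ E, capped, or bitscore); clustering alternates expansion
  (matrix power of the column-stochastic flow matrix) and inflation
  (entry-wise power r, then column renormalization) until the flow freezes
  into attractor basins — the families. Larger inflation, finer families.
- **Symmetrification and multi-domain detection.** Hits found in only one
  search direction are arbitrated by Smith-Waterman with a Monte-Carlo
  shuffle z-score (significant ⇒ both directions set; otherwise both
  cleared). A protein whose neighbours include a mutually dissimilar pair
  is flagged multi-domain and excluded from single-linkage cores, then
  re-attached with annotation — preventing domain-chaining collapse.
- **Fusion detection.** On a rectangular component-by-composite matrix, a
  composite matching ≥ 2 query components at essentially distinct spans
  (≤ 10 % overlap of the shorter span), with the components mutually
  non-homologous, is called a fusion candidate.

## Worked example

```bash
$ cgg cast demo.faa --out masked.faa --report regions.tsv
2 regions; 25 positions masked (2.64% of 947 residues)
$ cat regions.tsv
SYN00000	Q	9	33	103	1
SYN00005	W	73	78	41	1
```

`demo.faa` here is a six-protein synthetic collection (from
`cggtools.fixtures`) carrying one implanted 20-residue poly-Q tract. The
detector reports the tract on `SYN00000` (segment score 103, first pass;
the span runs 9–33 because neighbouring residues scoring ≥ 0 against Q
extend the segment) plus a chance tryptophan-rich stretch on `SYN00005`
that just reaches the threshold (41 ≥ 40) — low-complexity detection on
random sequence has a small but real background rate. In `masked.faa`
only the Q positions inside the first span are `X`-ed; every other
residue survives:

```
>SYN00000 synthetic background protein
DSLNPRALDKXXXXXXXXXXXXXXXXXXXXSFXLMWTTMYYDFHNTLYIWNRFNTVVYDS...
```

Searching the masked queries against the unmasked collection and
clustering the pairs-list then recovers the planted family triple:

```bash
$ cgg search masked.faa demo.faa --min-score 60 --out pairs.tsv
6 hits -> pairs.tsv
$ cgg clustt pairs.tsv --out fam --inflation 2.0
1 families over 3 sequences -> fam.pairs.tsv, fam.mcl, fam.families.tsv
$ cat fam.families.tsv
1	3	FAM00A,FAM00B,FAM00C
```

One clustering invocation always writes three files: a weighted edge list
for network viewers, the raw clusters (one family per line), and the
families table `family_id / member_count / members`.

`cgg demo --seed 17 --outdir run/` executes the whole workflow on a seeded
synthetic proteome and ends with a checksum manifest; reruns with the same
seed are byte-identical.

## Documentation

`docs/methods.md` describes the models, defaults, numerical choices, what
the synthetic generator does and does not emulate, and known limitations.
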