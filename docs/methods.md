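# Methods

## Model and assumptions

`barcodesig` treats a DNA-barcode alignment as a set of independent
multinomial columns. The position probability matrix (PPM) entry for
nucleotide *k* at column *j* is the relative frequency
`M[k,j] = (1/N) Σᵢ I(X[i,j] = k)`; no pseudocounts, no background
model, no log-odds — the raw frequencies are the object of interest,
because discrimination and pattern discovery both operate on "how
conserved is this exact base here". Rows are always ordered A, C, G, T.

Each aligned sequence is reduced to the vector of its own bases'
column probabilities (0 at gaps), and pairwise Euclidean distances
between these vectors measure divergence. This representation has a
known degeneracy: two sequences carrying different bases of equal
column frequency (e.g. C and T both at 0.5) receive identical vectors
and zero distance. The discrimination rule absorbs this conservatively
— a zero minimum inter-species distance always fails — and the test
suite documents the collision explicitly.

A species pair is *discriminated* when its minimum inter-species
distance strictly exceeds the maximum intra-species distance of both
species and is strictly positive (ties fail). The published rule does
not say which summary of intra-species distance is meant; min-vs-max
is the most conservative reading and reproduces the barcoding-gap
concept, so it is the default, with `--pair-policy all|any|majority`
controlling how per-pair outcomes aggregate to a per-species tally
(`all`, the strictest, is the default). A singleton species has
`max_intra = 0`, reducing the rule to "any non-zero separation".

## Site discovery and signature assembly

Discovery is two-step. At the genus level, per-genus majority
consensus sequences are compared column by column; any disagreement is
a genus-level site (no frequency threshold — the source procedure
gives none). At the species level, within one genus, a column
qualifies only when it is fixed (single base, no gaps or N) inside
*every* species yet differs between at least two: a signature must
match all sequences of its target species, so within-species
polymorphic columns are unusable for recall.

Sites live in original alignment-column coordinates (the gap-trimmed
alignment keeps an explicit column map); patterns live in ungapped
1-based coordinates on an exemplar — the first sequence of the target
species. Each site expands by `flank` bases per side (default 6,
giving 13-mers around isolated sites, the geometry of the published
exemplar signature; the window size is not stated anywhere, so it is a
parameter). Touching windows merge. Patterns are read off the
exemplar, so every signature matches its exemplar by construction.
**Patterns are always anchored on the untrimmed sequences**: trimming
serves only the matrix and site discovery, while signatures must match
real full-length barcodes.

The initial candidate signature uses the species-level sites (the
contrasts against the hardest neighbours — congeners); genus-level
sites form the refinement pool. While false positives remain, the
pool site whose incorporation most reduces FP without losing TP is
added greedily. The candidate set is the refinement trajectory's
prefixes plus the all-combined-sites signature; the winner maximizes
F-measure with ties broken by recall, then fewer patterns, then
shorter span, then lexicographic regex — a total order, so selection
is deterministic. If no site removes the last false positives the
signature is returned flagged, and for target sequences a signature
misses, a diagnostic reports which literal is absent or which
inter-pattern distance broke (the dominant real-world failure mode:
indels shifting pattern spacing).

Inter-pattern distances are exact (`.{d}`) by default, because spacing
mismatch is the documented cause of signature failure and a ranged gap
would hide it; `gap_tolerance = t` relaxes to `.{d−t,d+t}` when
robustness to single-base indels matters more than strictness.

Evaluation counts sequences, not occurrences: TP/FN over the target
species' sequences, FP over all others; recall = TP/(TP+FN),
precision = TP/(TP+FP) (with 0/0 := 0), F is balanced F1, binned into
A [0.75, 1], B [0.50, 0.75), C [0.25, 0.50), D [0, 0.25) — half-open
on the right except A, closed on the left.

## Classification semantics

Queries are searched forward-strand only (barcode amplicons are
deposited in canonical orientation; `--both-strands` opts in to
reverse-complement search). The leftmost match is reported, a query
counts once per signature regardless of repeat occurrences, and `N`
never matches a pattern literal (training data exclude N; letting it
match would inflate false positives) while bases inside the `.{d}`
runs are unconstrained. With several signatures, exactly one match
assigns the species, none leaves the query unidentified, two or more
flag it ambiguous with all species listed.

## QR serialization

Signatures serialize to a two-line text format — a `#species=…`,
`#exemplar=…`, `#span=…` header and the regex — and that byte string
is the QR payload verbatim, making the PNG self-describing. The QR
implementation is a complete model-2 codec written in this package:
byte mode, UTF-8, error-correction level M, automatic version
selection (1–40), mask chosen by the standard penalty rules,
Reed–Solomon over GF(2⁸)/0x11D with Berlekamp–Massey correction on
decode. The decoder targets clean, axis-aligned symbol images of the
kind the encoder writes (it locates the symbol by bounding box and
verifies the finder patterns; it is not a general camera-photo
reader), reads the format information with the BCH code's 3-bit error
tolerance, and only accepts EC-level-M symbols. Structural
self-consistency is enforced in tests: the block-structure table must
exactly fill the non-function modules of every version (remainder
< 8 bits), and symbols survive random module damage up to the RS
correction budget.

## Synthetic data: what it emulates, what it does not

The generator models the structure the method exploits: one random
uniform-composition backbone per genus, genus backbones differing at a
per-site rate (default 0.05, the order of inter-genus plastid
divergence), species within a genus differing from the backbone by a
small number of *fixed* diagnostic substitutions at disjoint positions
(default 2 per species — single-base differences dominate congeneric
divergence in slow plastid loci), at least two (default 3) sequences
per species, default length 700 bp (a typical matK amplicon). Optional
iid per-site substitution noise and single-base deletions (emitted as
alignment gaps, so trimming and coordinate mapping are exercised) are
off by default. A separate corruption step adds truncations, N's and
indels to stress the failure modes of exact-distance matching.

It does **not** model phylogenetic correlation, rate heterogeneity,
codon structure, alignment error, or shared polymorphism — so passing
recovery tests shows the algorithms are correct under their own
assumptions, not that real GenBank data will be as clean. On real
data, within-species indels and partial sequences are expected to
break some species' signatures; the per-sequence gap-break diagnostic
exists precisely for that case.

## Numerical and design choices

- Gap handling in the PPM: gaps contribute no count and columns are
  *not* renormalized — residual gap mass stays visible rather than
  being hidden. Default trim threshold `max_gap_frac = 0` (drop every
  column containing a gap) yields the equal-length gap-free alignment
  the matrices assume.
- Consensus ties break toward the alphabetically first base and are
  recorded per column, keeping consensi in the 4-letter alphabet so
  pattern literals stay plain regex strings.
- Sequence alphabet is strict {A,C,G,T,N,-}; IUPAC ambiguity codes are
  rejected at parse time (the curated training data exclude them).
- Taxonomy: a TSV sidecar (`id genus species locus`) always overrides
  FASTA-header parsing; headers are assumed GenBank-style
  (`>ACC Genus species …`) otherwise.
- Genus- and species-level sites are de-duplicated by column when
  combined (first occurrence wins, species level first).
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); pipeline reruns are byte-identical.

## Problem sizes

The bundled tests and the acceptance script run on the generator's
default panel (3 genera × 2 species × 3 sequences × 700 bp), 1000
random match fixtures, and 100 random QR round trips — sizes chosen so
the full suite completes in well under a minute while still exercising
versions, merges and refinement non-trivially.

## Known limitations

- The probability-vector collision above can mask genuinely different
  sequences in small panels with balanced base frequencies.
- Signatures assume co-linear, unrearranged barcodes; no reverse-strand
  search by default and no degenerate-base patterns.
- The QR decoder is not a general-purpose scanner (no perspective
  correction, single symbol per image, EC level M only).
- Headline tallies on the published curated GenBank panel (e.g.
  discrimination counts over 125 species) depend on that exact dataset
  and its alignment; they require the external accession set and are
  out of desk-scale scope here.
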