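# Methods

## Scope and conventions

All coordinates are 1-based and all intervals inclusive: codon *i* of a CDS
covers nucleotides 3i−2..3i and encodes protein residue *i*. Only the
unambiguous alphabet {A,C,G,T} is accepted; ambiguity codes are rejected
rather than skipped, because every count the package reports is meant to be
exact. A CDS may store its terminal stop codon; the stop is validated but
never translated or scanned. Genetic codes come from the NCBI tables via
Biopython; the standard code (3 stops, 61 sense codons) is the default and
the only one exercised against the packaged lambda data.

## The one-SNP-away scan

A codon is *accessible* to a target (an amino acid or STOP) when at least one
of its 9 Hamming-distance-1 neighbors encodes the target. The scan reports
positions, not substitutions: a codon with two routes to a stop counts once.
Codons already encoding the target are excluded by default
(`exclude_current=True`) — "one step away" excludes "zero steps away" — and
reports are byte-for-byte reproducible (hits sorted by position,
substitutions by offset then alternative base).

Two closed-form identities make good sanity checks and are enforced as
properties in the tests:

* target P under the standard code: the hit set is exactly the codons with C
  at offset 1 or 2, minus `CCN`;
* target STOP: a codon is a hit iff it belongs to the 18-codon stop-adjacent
  set (of the 61 sense codons, exactly 18 have a stop neighbor). Notably no
  isoleucine codon does, so an Ile→nonsense change always needs two
  substitutions.

## Substitution classification

Transitions are purine↔purine or pyrimidine↔pyrimidine (4 of the 12 ordered
base pairs); the rest are transversions. Stops are named amber (TAG), ochre
(TAA), opal (TGA). A change at codon 1 that leaves the initiation-codon set
is classed `start_loss`; when it also changes the encoded residue (Met1Lys)
it remains countable as missense for table summaries, which matches how such
alleles are tabulated in mutant screens.

## Embedded-ORF architectures

An embedded ORF is an ATG→stop reading frame at nucleotide offset *o* inside
a parent CDS with *o* mod 3 ∈ {1,2} (same strand; antisense overlap is out
of scope). `embed_codon_count` includes the terminal stop, so the embedded
protein has `embed_codon_count − 1` residues; for the lambda architecture
that is 61 codons and the familiar "60 codons" of Rz1. Because overlapping
codons share at most two nucleotides, one substitution touches exactly one
codon per frame; `dual_frame_effect` computes both consequences and is
validated against mutating the raw string once and re-translating both
frames. `design_constrained` exhaustively filters all 9·L substitutions
through per-frame effect predicates; "silent in the other frame" always
means synonymous, not merely non-nonsense. On the packaged lambda sequence
the parent-amber/embedded-synonymous query returns a single design at Rz
codon 100 (C→T, amber, silent at Rz1 codon 26) and the reciprocal query
returns the Rz1 codon-38 amber that is silent in Rz — the two published
knockout constructs.

## Mutant tables, saturation, heptads, span

Mutant-allele tables are TSV with `#` comments and columns
`gene, codon_position, ref_aa, alt, isolates, lysis, source[, change_type]`;
`alt` is a residue letter, `X(Amber|Ochre|Opal)`, or a free-text
engineered-replacement label. `isolates = 0` iff the allele is site-directed.
Summaries count random-source alleles (isolates ≥ 1): isolate sums and
distinct positions overall and per named domain interval. Engineered
replacements are excluded from missense/nonsense tallies. When a CDS is
supplied, transition/transversion status is recomputed from the codons
(records whose amino-acid change admits both a transition and a transversion
route are left unclassified rather than guessed).

The packaged table transcribes the published lambda Rz/Rz1 allele list
verbatim. Known discrepancies, documented rather than reconciled:

* the source text reports 49 Rz missense alleles "in 34 positions"; the
  table's rows sum to 49 alleles over 26 distinct positions;
* the printed transition arrow is chemically wrong for a frozen set of rows
  (Met1Lys in both genes and several site-directed Xaa→Pro rows, which are
  transversions); the `change_type` column transcribes the glyphs as printed
  and the recomputation test pins the exact erratum set;
* the printed region labels are not transcribed; domains always come from
  the domain map (Rz: NTMD 1–24, CC1 27–87, L2 89–120, CC2 121–150, CTD
  151–153; Rz1: signal 1–19, lipoylated Cys 20, linker 21–31, PRR 32–44,
  CTD 45–60). The Rz1 "periplasmic domain" means residues ≥ 21 (mature
  protein minus the lipid-anchored Cys20), which reproduces the published
  11-position missense count.

Saturation accounting reports observed/accessible and, under a uniform-draw
model, the expected distinct positions after *n* draws,
`m(1 − (1 − 1/m)^n)`. Uniformity is a deliberate simplification (real
mutagenesis is biased by base context and transition/transversion rates);
the closed form is verified against Monte-Carlo simulation to within three
standard errors. For the lambda numbers (m = 45 accessible nonsense
positions, n = 82 nonsense alleles) it gives 37.9 expected distinct
positions, consistent with the 34 observed and with the screen "approaching
saturation" (75.6%).

Heptad registers assign abcdefg letters cyclically from an anchor residue
given letter "a". With the anchor at Asp65 — the register implied by the
published observation of an interfacial "a"-position Asp — residues 60–86 of
Rz CC1 contain exactly 8 a/d positions (61, 65, 68, 72, 75, 79, 82, 86). No
single register makes every residue discussed in the source an a/d position
(A73 is not, under any anchor consistent with D65); the register is
therefore a parameter, not a constant. Span arithmetic is the trivial
product: 170 residues (130 Rz + 40 Rz1) × 0.15 nm/residue = 25.5 nm of
periplasm, assuming α-helix.

## Charge covariation

Residues are classed positive (K,R), negative (D,E), polar (H,S,T,N,Q,Y) or
other (remaining residues and gaps). For a column pair across homologs, a
homolog supports complementarity when the two columns carry opposite charges
or are jointly non-charged; the score is the supporting fraction (homologs
gapped at either column leave the denominator). A pair is *variable* only if
both columns take ≥ 2 charge classes — without variation there is no
covariation signal. The score definition is this package's own (the analysis
it generalizes exhibited a single observed pair, not a formula), and output
labels it as such. Ranking is deterministic: variable first, then score,
then proximity to the C-termini, then column indices. Significance is
assessed against a permutation null (one partner's homolog labels shuffled,
both column compositions preserved); note that with six homologs the null's
99th percentile of a perfectly complementary pair is itself 1.0, since a
sign-matching shuffle has probability ≥ 1/20, so "reaches the 99th
percentile" is the strongest attainable statement at this family size.

## Synthetic generators

All generators are pure functions of their arguments, including the seed.

* `generate_cds`: ATG start, n sense codons rejection-sampled from
  GC-weighted bases (default GC 0.5), one terminal stop.
* `generate_embedded_pair`: per-codon depth-first construction with
  backtracking satisfying both frames simultaneously, then a check that the
  planted ORF is the top located candidate (re-sampling on failure, error
  after bounded attempts). Defaults mirror the lambda geometry: 153-codon
  parent, 60-sense-codon ORF at offset 220 (+1 frame).
* `generate_family`: defaults mirror the published covariance analysis —
  six homologs, 20- and 18-column C-terminal segments, one planted
  complementary pair near both C-termini (columns 17/16) with at least one
  charge-sign swap. Background columns drift within the consensus residue's
  charge class (per-column consensus kept with probability 0.7), which
  models the chemically conservative variation of real homolog alignments;
  a `charge_noise` parameter (default 0) introduces class-breaking noise.
  A fully independent 20-residue background would instead make perfect
  "jointly non-charged" pairs near-certain and the planted signal
  unrecoverable under the fixed score rule — passing recovery tests on this
  generator therefore demonstrates signal recovery against conservative
  background drift, not against arbitrary compositional noise.

What the generators do *not* emulate: phylogenetic correlation among
homologs, indel structure beyond uniform gaps, codon-usage bias, and
mutational spectrum bias. Tests passing on synthetic data show algorithmic
correctness (against brute-force oracles), not robustness to those real-data
features.

## Packaged lambda sequence and known count discrepancies

The package ships a 462-nt transcription of the public lambda Rz CDS
(NC_001416.1:45966..46427); Rz1 is always recovered from it by
`locate_embedded_orf`, never stored separately. On this sequence the scans
give 45 stop-accessible positions in Rz and 19 in Rz1, and proline windows
23–63 → 20 and 92–133 → 22, all matching the published counts exactly. Two
published window counts do not reproduce: positions 64–93 compute to 14
Pro-accessible codons (published: 13) and the TMD window 1–24 to 8
(published: 7), by exhaustive enumeration; no single inclusive/exclusive
windowing convention yields all four published values at once (dropping
endpoints breaks the windows that do match). The computed values are
reported as-is.

## Problem sizes and numerical choices

Everything is exact combinatorics except two stochastic components: the
coverage Monte Carlo (10⁵ replicates of 82 draws; standard error ≈ 0.006
positions) and the covariance permutation null (1000 shuffles). The test
suite and the acceptance script each run in a few seconds on one CPU. Ties
are always broken lexicographically (position, offset, alternative base;
column indices) so every output is reproducible byte-for-byte.
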