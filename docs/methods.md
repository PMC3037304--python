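# Methods

## Repeat model

A locus is a maximal perfect tandem repetition of a primitive motif of
1–10 bp observed on the given strand. "Perfect" means complete, identical
motif copies only — no mismatch or indel tolerance; imperfect repeats are
out of scope. "Maximal" means the tract cannot be extended by one further
full motif copy on either side; partial trailing copies are not counted
toward the tract. Each tandem run is reported once, at its leftmost phase,
so the observed motif of a run is the unit starting at the run's first
base (`AAGAAG…` reports `AAG`, never the rotated `AGA`). Ambiguity
characters cannot match any base and therefore terminate tracts; a tract
interrupted by `N` splits into two.

The class I filter keeps tracts of ≥ `min_tract_bp` (default 20 bp) of
complete copies. Because only complete copies count, the implied minimum
repeat numbers at the default are: mono 20, di 10, tri 7, tetra 5,
penta/hexa 4, 7–9-mer 3, 10-mer 2. Mononucleotide tracts are detected but
carry a `homopolymer` flag, since EST poly-A tails make them suspect as
markers; they can be excluded entirely with
`MiningConfig(include_mononucleotide=False)`.

### Overlap elimination

Class I tracts of different periods can overlap (a trinucleotide run
ending in a dinucleotide run, for example). Elimination is greedy and
deterministic: candidates are taken longest tract first, ties broken by
leftmost start and then smaller motif length; a candidate overlapping an
already-selected locus is truncated to its largest run of whole motif
copies outside all selected loci (leftmost run on a tie) and re-kept only
if it still reaches class I. Exact duplicates collapse. The greedy rule
and its tie-breaks are this package's own specification of a step that
survey tools perform but rarely document; a quadratic reference
implementation of the same rule backs it in the test suite.

### Compound SSRs

Non-overlapping class I loci on one sequence whose gaps are each at most
`compound_max_interruption` (default 100 bp, the convention of the widely
used MISA search script) merge transitively into one compound SSR; all
other loci are singles. Every locus lands in exactly one class, so
`n_single + n_compound_members = n_loci` always holds.

### Canonical motif pairs

A motif is reported together with its reverse complement as `X/Y` with the
alphabetically smaller member first (`AG/CT`; self-complementary motifs as
`GC/GC`). Rotated motifs are *not* merged — `AG/CT` and `GA/TC` are
distinct families — because which rotation is observed carries positional
information in transcripts and EST-SSR surveys tabulate them separately.

## Survey statistics and rounding conventions

Percentages in survey tables round half away from zero to 2 decimals, with
one deliberate exception: the SSR/EST frequency (`100·n_loci/n_sequences`)
is **truncated** at 2 decimals. Back-calculating the reference survey's
printed per-species SSR/EST column reproduces it under truncation for ten
of eleven species (e.g. 980/40,525 = 2.4182 printed as 2.41) but under
half-away rounding for only seven, while its sequences-with-SSR column
matches half-away rounding; the package adopts the convention each column
evidently used. The eleventh SSR/EST value (968/19,830 printed as 4.66)
is not reproducible under any rounding and is reported as computed
(4.88). Average motif length is the mean tract length of *single* loci
only, since compound members would double-weight clustered repeats. The
percentage of multi-SSR sequences is reported relative to the number of
sequences carrying at least one SSR — the reference table's denominator
for that column is not back-calculable, so the package documents its own.
`avg_bp_per_est` rounds half away from zero to an integer, reproducing
the reference table's integer column exactly. GC content excludes
ambiguity codes from numerator and denominator, keeping it well defined on
masked ESTs.

## Amino-acid prediction and codon bias

Motifs of length 3, 6 or 9 are read as codons of the standard genetic
code. The repeat unit itself is translated in frame 0 by default: the true
reading frame of an EST is unknown without ORF annotation, and the other
phases of a tandem array are rotations of the unit, available via the
`frame` argument (1 or 2 rotate the unit before translation). Motifs are
translated as observed, not on both strands, and stop codons are retained
as `*` rather than dropped. Each residue of a multi-residue translation
(hexamers, nonamers) counts once in the profile.

Codon-usage tables are ingested from Kazusa-style listings (both the
`UUU 17.6(714298)` block layout and plain codon/value rows); raw counts
take precedence over per-thousand frequencies, and fractions are obtained
by normalization. GCk is the usage-weighted share of codons with G or C at
position k, so the uniform table gives GC1 = GC2 = GC3 = 50 by symmetry.
Motif–codon concordance reads the alphabetically first member of a trimer
pair as a codon and ranks its usage among synonymous codons (dense rank,
1 = preferred codon).

## Electronic PCR

Primer picking is a minimal deterministic rule, not thermodynamic design:
a fixed 20-base window on each flank, at least 3 bases from the tract,
sliding outward past windows containing ambiguity characters or
mononucleotide runs ≥ 6; no window, no primer pair. The contribution of
interest is the transferability assessment, so primer optimization is
deliberately out of scope.

The scan reports every site pair where the forward primer matches the plus
strand and the reverse primer the minus strand downstream on the same
record, each with at most `max_mismatches_per_primer` (default 1)
mismatches outside an exactly matching 3' anchor (default 5 bases), with
primer sites non-overlapping and the product (primer sites included) at
most `max_product_bp` (default 5000). These defaults are package choices
exposed on the CLI; the amplicon set is monotone non-decreasing in both
the mismatch allowance and the product cap, which the tests verify. An
amplicon is on-target when its span contains a class I locus of the same
canonical family as the source locus. Transfer rates are defined over all
supplied primer pairs. The scan is implemented as vectorized shifted
comparisons over a concatenated database array, with per-record offset
checks rather than separator characters.

The virtual gel groups amplicon sizes into lanes keyed by (primer pair,
target database), sizes descending, identical sizes collapsed into one
band annotated `×k`, rendered against a log-spaced ladder — mirroring how
bench electrophoresis of the same products would read.

## Synthetic databases

The generator emulates pre-clustered EST databases: 300–1000 bp sequences
(uniform lengths), i.i.d. background bases with a configurable GC
fraction, planted perfect tracts separated from each other and from
sequence ends by a margin (default 120 bp, above the compound-interruption
default so planted loci mine back as singles), and an optional fraction of
3' poly-A tails of 8–15 bases (below the class I threshold). Planted
tracts are dealt round-robin across sequences after a seeded shuffle, and
infeasible specifications fail before any output is produced.

Rather than rejecting accidental repeats only inside background segments,
every sequence is verified by mining it back: the class I set found must
equal the planted class I set, else the sequence is redrawn (junction
effects — a background base extending a planted tract by a partial copy —
would otherwise silently shift locus boundaries). The truth table is
therefore exact by construction. A single integer seed drives one
`numpy` generator through a documented stream order (tail draw, length,
gap split, background bases, per sequence in order), so identical specs
give byte-identical databases.

Ortholog derivatives apply i.i.d. point substitutions at a given rate
outside the planted tracts (inside too only when `mutate_tracts` is set,
in which case the truth table is rebuilt by re-mining). With
`flank_conservation`, 60 bp on each side of every tract are frozen — wide
enough to cover the primer window rule's realistic outward slide — so
conserved-flank transfer scenarios amplify at 100% by construction.

What the generator does *not* model: chimeric reads, base-quality decay,
expression-level redundancy, real codon structure or UTR/CDS composition.
Passing recovery and transfer tests on these databases demonstrates the
correctness of the detection, bookkeeping and e-PCR machinery under known
ground truth — not survey accuracy on real ESTs, which additionally
depends on upstream clustering and sequence quality.

## Problem sizes and numerical choices

The test and acceptance workloads use: oracle equivalence on 200 random
2 kb sequences (1% ambiguity characters); planted recovery on ten
databases of 1000 sequences (1000 planted loci each, dimer through trimer
motifs, 20% poly-A); self-transfer on a 200-sequence database (one locus
per sequence). These sizes give stable 100%-rate measurements while
keeping runs quick. Truncation and rounding helpers add a 1e-9 guard
against float noise at decimal boundaries. All coordinates are 1-based
inclusive in every serialized table; any half-open arithmetic is internal
only.

## Known limitations

- Perfect repeats only; imperfect or interrupted repeats (common in
  pines, for example) are not modelled.
- Primer picking ignores melting temperature, GC clamps and dimerization.
- The e-PCR mismatch model is positional only (no gaps, no thermodynamic
  weighting).
- Mining is optimized for EST-scale records; chromosome-scale scanning
  would want suffix-structure approaches.
- Gene-ontology annotation, dN/dS selection tests and redundancy
  clustering (CAP3) are upstream/downstream concerns outside this
  package.
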