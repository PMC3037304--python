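# ssrmine

Tools for surveying EST-derived microsatellite (EST-SSR) markers: mine
class I perfect simple sequence repeats from EST/cDNA FASTA databases,
compute the comparative statistics such surveys report, profile the amino
acids and codon-position GC bias behind trimer-family motifs, and assess
cross-species marker transferability by in-silico PCR with a virtual-gel
size report.

It is aimed at plant geneticists developing SSR markers from transcript
databases of model species for transfer to orphan species, and at anyone
comparing microsatellite occurrence patterns across taxa.

## The method

A microsatellite locus is a **maximal perfect tandem repeat**: at least
two complete copies of a *primitive* motif of 1–10 bp (a unit that is not
itself a repetition of a shorter unit — `AT`, never `ATAT`), not extendable
by a further full copy on either side. Ambiguity characters (`N` etc.)
terminate tracts. **Class I** loci — tracts of total length ≥ 20 bp of
complete copies — are retained as high-quality marker candidates; at the
20 bp default this implies minimum repeat numbers of 10 for dimers, 7 for
trimers, 5 for tetramers and so on. Overlapping tracts are eliminated
greedily (longest first; the loser is truncated to whole motif copies and
re-kept only if it still reaches class I). Loci on one sequence separated
by at most 100 bp (configurable) merge into **compound SSRs**; the rest
are **singles**.

Motifs are reported as canonical pairs with their reverse complement
(`AG/CT`); cyclic rotations remain distinct families (`GA/TC` ≠ `AG/CT`),
matching the convention of EST-SSR surveys. On top of the mined loci the
package computes per-database summaries (SSR/EST %, mean tract length,
sequences with one or several SSRs, single/compound split), motif-length
spectra and canonical-pair frequency tables, predicted amino-acid profiles
for 3/6/9 bp motifs, GC1/GC2/GC3 codon-position statistics from
Kazusa-style codon-usage tables, and motif–codon-bias concordance.

Transferability is assessed by electronic PCR: primers are picked from
clean 20 bp flank windows of each locus, then every (forward, reverse)
site pair with at most one mismatch per primer outside an exactly matching
5-base 3' anchor is reported as an amplicon; an amplicon is *on-target*
when it contains a class I SSR of the source locus's canonical family. The
transfer rate from database A to B is the percentage of A's primer pairs
with at least one amplicon in B.

A synthetic-data generator (`ssrmine.synthgen`) produces EST-like
databases with planted SSR tracts and exact truth tables, plus diverged
"ortholog" databases with optionally conserved primer flanks, so the whole
pipeline is testable without downloads.

## Worked example

```sh
cat > spec.cfg <<'CFG'
n_sequences = 8
length_min = 400
length_max = 800
gc_background = 0.5
seed = 5
plant = AG:12:5
plant = GCA:8:3
CFG
ssrmine simulate --spec spec.cfg --out-prefix sim
ssrmine mine --fasta sim.fasta --label sim --out loci.tsv
ssrmine summarize --loci loci.tsv --fasta sim.fasta --out summary.tsv
```

This prints (to stderr):

```
8 sequences, 8 planted loci
sim: 8 sequences, 8 class I loci (8 single, 0 in compounds)
sim: 8 loci, 100.0% SSR/EST
```

`loci.tsv` then holds one row per locus — e.g. an `AG` tract of 12 repeats
(24 bp, canonical pair `AG/CT`) with its 1-based coordinates — and
`summary.tsv` a survey row: 8 loci on 8 ESTs gives an SSR/EST frequency of
100%, mean single-locus tract length 24.0 bp, and no compound loci. The
same library calls are available from Python (`ssrmine.mine_database`,
`ssrmine.summarize`, ...), and `ssrmine transfer --db self=sim.fasta
--source self --out-prefix tr` writes the transferability matrix (100% on
the diagonal for this clean database), the per-pair amplicon counts and a
text virtual gel.

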