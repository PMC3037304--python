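"""Perfect tandem-repeat detection and SSR classification.

The pipeline per record is:

    find_perfect_repeats -> filter_class_i -> resolve_overlaps
        -> assemble_compounds

A microsatellite locus is a *maximal* perfect tandem repetition of a
*primitive* motif of 1-10 bp: the tract consists of complete motif copies
only and cannot be extended by one further full copy on either side.
Class I loci are tracts of at least 20 bp total, the length class treated
as high-quality marker candidates. Loci surviving the class filter are made
pairwise non-overlapping (longest tract wins, with whole-copy truncation of
the loser) and then partitioned into single SSRs and compound SSRs — runs
of class I tracts separated by no more than a fixed interruption distance.

Motifs are reported with their reverse complement as a canonical pair
(``AG/CT``); cyclic rotations remain distinct classes (``GA/TC`` is not
``AG/CT``), matching how EST-SSR surveys tabulate motif families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ssrmine.seqio import SequenceRecord, UNAMBIGUOUS

_ACGT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MiningConfig:
    """Search parameters for the repeat scan.

    min_tract_bp is the class I threshold: only complete motif copies count
    toward it, so the implied minimum repeat numbers at the 20 bp default
    are mono >=20, di >=10, tri >=7, tetra >=5, penta/hexa >=4, 7-9-mer >=3
    and 10-mer >=2.
    """

    min_motif: int = 1
    max_motif: int = 10
    min_tract_bp: int = 20
    compound_max_interruption: int = 100
    include_mononucleotide: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.min_motif <= self.max_motif <= 10):
            raise ValueError("need 1 <= min_motif <= max_motif <= 10")
        if self.min_tract_bp < 2 * self.min_motif:
            raise ValueError("min_tract_bp must allow at least two copies")
        if self.compound_max_interruption < 0:
            raise ValueError("compound_max_interruption must be >= 0")


def reverse_complement(motif: str) -> str:
    return str(Seq(motif).reverse_complement())


def canonical_pair(motif: str) -> str:
    """Strand-independent motif-family label, e.g. ``AG/CT``.

    The label pairs a motif with its reverse complement, alphabetically
    smaller member first; a self-reverse-complementary motif is labelled
    ``X/X``. Cyclic rotations are deliberately *not* merged: AG/CT and
    GA/TC are distinct families.
    """
    if not motif or not (1 <= len(motif) <= 10):
        raise ValueError(f"motif length must be 1-10, got {motif!r}")
    if set(motif) - UNAMBIGUOUS:
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    rc = reverse_complement(motif)
    a, b = sorted((motif, rc))
    return f"{a}/{b}"


def is_primitive(motif: str) -> bool:
    """True when the motif is not a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


@dataclass(frozen=True)
class SSRLocus:
    """One perfect tandem repeat tract (1-based inclusive coordinates)."""

    seq_id: str
    motif: str
    repeat_count: int
    start: int
    end: int

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    @property
    def tract_length(self) -> int:
        return self.end - self.start + 1

    @property
    def canonical_pair(self) -> str:
        return canonical_pair(self.motif)

    @property
    def is_homopolymer(self) -> bool:
        """Mononucleotide tract — suspect in ESTs because of poly-A tails."""
        return len(self.motif) == 1

    def __post_init__(self) -> None:
        if self.repeat_count < 2:
            raise ValueError("repeat_count must be >= 2")
        if self.end - self.start + 1 != len(self.motif) * self.repeat_count:
            raise ValueError("tract length inconsistent with motif * count")

    def overlaps(self, other: "SSRLocus") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class CompoundSSR:
    """Two or more class I tracts within the interruption limit."""

    seq_id: str
    members: tuple[SSRLocus, ...]
    interruptions: tuple[int, ...]

    @property
    def span_start(self) -> int:
        return self.members[0].start

    @property
    def span_end(self) -> int:
        return self.members[-1].end

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("compound SSR requires >= 2 members")
        if len(self.interruptions) != len(self.members) - 1:
            raise ValueError("need one interruption per adjacent pair")


def find_perfect_repeats(
    record: SequenceRecord, config: MiningConfig | None = None
) -> list[SSRLocus]:
    """All maximal perfect tandem repeats in a record (pre-filter).

    Returns every tract with a primitive motif of length in
    [min_motif, max_motif] and at least two complete copies, sorted by
    (start, motif_length). Ambiguity characters terminate tracts: an N
    cannot match any base.
    """
    config = config or MiningConfig()
    seq = record.residues
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = np.isin(arr, _ACGT_BYTES)
    loci: list[SSRLocus] = []
    lo = config.min_motif
    if lo == 1 and not config.include_mononucleotide:
        lo = 2
    for p in range(lo, config.max_motif + 1):
        if n < 2 * p:
            continue
        eq = (arr[:-p] == arr[p:]) & valid[:-p] & valid[p:]
        # run-length encode the match mask
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = edges[::2], edges[1::2]
        for a, b in zip(starts.tolist(), ends.tolist()):
            run = b - a  # consecutive base matches at lag p
            copies = (run + p) // p
            if copies < 2:
                continue
            motif = seq[a : a + p]
            if not is_primitive(motif):
                continue  # captured at the shorter period
            loci.append(
                SSRLocus(
                    seq_id=record.id,
                    motif=motif,
                    repeat_count=copies,
                    start=a + 1,
                    end=a + copies * p,
                )
            )
    loci.sort(key=lambda l: (l.start, l.motif_length))
    return loci


def filter_class_i(
    loci: Iterable[SSRLocus], config: MiningConfig | None = None
) -> list[SSRLocus]:
    """Keep loci whose tract length meets the class I threshold."""
    config = config or MiningConfig()
    return [l for l in loci if l.tract_length >= config.min_tract_bp]


def _truncate_to_free_copies(
    locus: SSRLocus, selected: Sequence[SSRLocus], min_tract_bp: int
) -> SSRLocus | None:
    """Largest run of whole motif copies not overlapping any selected locus.

    Returns the truncated locus if it still meets the class threshold,
    else None. Ties between equally long runs go to the leftmost.
    """
    p = locus.motif_length
    blockers = [s for s in selected if s.overlaps(locus)]
    free = []
    for m in range(locus.repeat_count):
        c_start = locus.start + m * p
        c_end = c_start + p - 1
        free.append(
            all(c_end < s.start or c_start > s.end for s in blockers)
        )
    best_len = best_at = 0
    cur_len = 0
    cur_at = 0
    for i, ok in enumerate(free):
        if ok:
            if cur_len == 0:
                cur_at = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_at = cur_len, cur_at
        else:
            cur_len = 0
    if best_len * p < min_tract_bp or best_len < 2:
        return None
    new_start = locus.start + best_at * p
    return SSRLocus(
        seq_id=locus.seq_id,
        motif=locus.motif,
        repeat_count=best_len,
        start=new_start,
        end=new_start + best_len * p - 1,
    )


def resolve_overlaps(
    loci: Iterable[SSRLocus], min_tract_bp: int = 20
) -> list[SSRLocus]:
    """Greedy elimination of overlapping tracts on one record.

    Candidates are taken longest tract first (ties: leftmost start, then
    smaller motif length). A candidate overlapping an already-selected
    locus is truncated to its largest run of whole motif copies outside all
    selected loci and re-kept only if that run still meets the class I
    threshold. Exact duplicates collapse to one locus.
    """
    order = sorted(
        loci, key=lambda l: (-l.tract_length, l.start, l.motif_length)
    )
    selected: list[SSRLocus] = []
    for cand in order:
        if any(cand.overlaps(s) for s in selected):
            cand2 = _truncate_to_free_copies(cand, selected, min_tract_bp)
            if cand2 is not None:
                selected.append(cand2)
        else:
            selected.append(cand)
    selected.sort(key=lambda l: (l.start, l.motif_length))
    return selected


def assemble_compounds(
    loci: Iterable[SSRLocus], config: MiningConfig | None = None
) -> tuple[list[SSRLocus], list[CompoundSSR]]:
    """Partition non-overlapping class I loci into singles and compounds.

    Consecutive loci on a record with gaps no larger than
    ``compound_max_interruption`` merge transitively into one compound;
    everything else is a single. Every input locus lands in exactly one
    output.
    """
    config = config or MiningConfig()
    d_max = config.compound_max_interruption
    by_seq: dict[str, list[SSRLocus]] = {}
    for l in loci:
        by_seq.setdefault(l.seq_id, []).append(l)
    singles: list[SSRLocus] = []
    compounds: list[CompoundSSR] = []
    for seq_id, group in by_seq.items():
        group.sort(key=lambda l: l.start)
        chain: list[SSRLocus] = [group[0]]
        for nxt in group[1:]:
            gap = nxt.start - chain[-1].end - 1
            if gap <= d_max:
                chain.append(nxt)
            else:
                _emit(chain, singles, compounds)
                chain = [nxt]
        _emit(chain, singles, compounds)
    singles.sort(key=lambda l: (l.seq_id, l.start))
    compounds.sort(key=lambda c: (c.seq_id, c.span_start))
    return singles, compounds


def _emit(
    chain: list[SSRLocus],
    singles: list[SSRLocus],
    compounds: list[CompoundSSR],
) -> None:
    if len(chain) == 1:
        singles.append(chain[0])
    else:
        gaps = tuple(
            chain[i + 1].start - chain[i].end - 1
            for i in range(len(chain) - 1)
        )
        compounds.append(
            CompoundSSR(chain[0].seq_id, tuple(chain), gaps)
        )


@dataclass
class MiningResult:
    """Mining outcome for one database."""

    singles: list[SSRLocus] = field(default_factory=list)
    compounds: list[CompoundSSR] = field(default_factory=list)
    n_sequences: int = 0

    @property
    def compound_members(self) -> list[SSRLocus]:
        return [m for c in self.compounds for m in c.members]

    @property
    def all_loci(self) -> list[SSRLocus]:
        return self.singles + self.compound_members

    @property
    def n_loci(self) -> int:
        return len(self.singles) + len(self.compound_members)

    def to_frame(self, database: str = "db") -> pd.DataFrame:
        """Long-format loci table (1-based inclusive coordinates)."""
        rows = []

        def _row(locus: SSRLocus, locus_type: str, compound_id: str) -> dict:
            return {
                "database": database,
                "seq_id": locus.seq_id,
                "start": locus.start,
                "end": locus.end,
                "motif": locus.motif,
                "motif_length": locus.motif_length,
                "repeat_count": locus.repeat_count,
                "tract_length": locus.tract_length,
                "canonical_pair": locus.canonical_pair,
                "locus_type": locus_type,
                "compound_id": compound_id,
                "homopolymer_flag": locus.is_homopolymer,
            }

        for locus in self.singles:
            rows.append(_row(locus, "single", ""))
        for i, comp in enumerate(self.compounds, start=1):
            cid = f"{comp.seq_id}.c{i}"
            for member in comp.members:
                rows.append(_row(member, "compound-member", cid))
        df = pd.DataFrame(
            rows,
            columns=[
                "database", "seq_id", "start", "end", "motif",
                "motif_length", "repeat_count", "tract_length",
                "canonical_pair", "locus_type", "compound_id",
                "homopolymer_flag",
            ],
        )
        return df.sort_values(["seq_id", "start"]).reset_index(drop=True)


def result_from_frame(df: pd.DataFrame, n_sequences: int = 0) -> MiningResult:
    """Rebuild a MiningResult from a loci table written by ``to_frame``."""
    result = MiningResult(n_sequences=n_sequences)
    comp_groups: dict[str, list[SSRLocus]] = {}
    for row in df.itertuples(index=False):
        locus = SSRLocus(
            seq_id=str(row.seq_id),
            motif=str(row.motif),
            repeat_count=int(row.repeat_count),
            start=int(row.start),
            end=int(row.end),
        )
        if str(row.locus_type) == "single":
            result.singles.append(locus)
        else:
            comp_groups.setdefault(str(row.compound_id), []).append(locus)
    for cid in sorted(comp_groups):
        members = sorted(comp_groups[cid], key=lambda l: l.start)
        gaps = tuple(
            members[i + 1].start - members[i].end - 1
            for i in range(len(members) - 1)
        )
        result.compounds.append(
            CompoundSSR(members[0].seq_id, tuple(members), gaps)
        )
    return result


def mine_database(
    records: Sequence[SequenceRecord], config: MiningConfig | None = None
) -> MiningResult:
    """Run the full detection pipeline over a database."""
    config = config or MiningConfig()
    result = MiningResult(n_sequences=len(records))
    for rec in records:
        raw = find_perfect_repeats(rec, config)
        kept = filter_class_i(raw, config)
        flat = resolve_overlaps(kept, config.min_tract_bp)
        singles, compounds = assemble_compounds(flat, config)
        result.singles.extend(singles)
        result.compounds.extend(compounds)
    return result
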