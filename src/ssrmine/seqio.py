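"""FASTA I/O and database-level sequence statistics.

An EST database is an ordered list of :class:`SequenceRecord`; the reader
enforces the invariants the rest of the toolkit relies on (unique ids,
uppercase IUPAC residues, no empty sequences) and reports violations with
the offending line number.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from ssrmine._rounding import round_half_away, round_int_half_away

#: IUPAC DNA alphabet: the four bases plus ambiguity codes and N.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")


class FastaParseError(ValueError):
    """Malformed FASTA input; message carries file and line context."""


@dataclass(frozen=True)
class SequenceRecord:
    """One EST / virtual transcript."""

    id: str
    description: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        bad = set(self.residues) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")


@dataclass(frozen=True)
class DatabaseStats:
    """Database-level size and composition summary."""

    n_sequences: int
    total_bp: int
    avg_bp_per_est: int
    gc_percent: float


def read_fasta(path: Union[str, os.PathLike]) -> list[SequenceRecord]:
    """Parse a FASTA file into sequence records.

    Accepts wrapped or unwrapped sequence lines and CRLF endings. Lowercase
    residues are uppercased. Raises :class:`FastaParseError` naming the
    offending line for malformed headers, duplicate ids, non-IUPAC
    characters or empty sequences.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"{path}: line {header_line}: record {header.split()[0]!r} "
                "has an empty sequence"
            )
        fields = header.split(None, 1)
        rec_id = fields[0]
        desc = fields[1] if len(fields) > 1 else ""
        if rec_id in seen:
            raise FastaParseError(
                f"{path}: line {header_line}: duplicate id {rec_id!r}"
            )
        seen.add(rec_id)
        records.append(SequenceRecord(rec_id, desc, seq))

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(
                        f"{path}: line {lineno}: header with no identifier"
                    )
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: line {lineno}: sequence data before "
                        "any '>' header"
                    )
                seq = line.strip().upper()
                bad = set(seq) - IUPAC_DNA
                if bad:
                    raise FastaParseError(
                        f"{path}: line {lineno}: non-IUPAC character(s) "
                        f"{sorted(bad)}"
                    )
                chunks.append(seq)
    flush()
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path: Union[str, os.PathLike],
    width: int = 70,
) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _as_records(
    records: Union[SequenceRecord, Iterable[SequenceRecord]],
) -> list[SequenceRecord]:
    if isinstance(records, SequenceRecord):
        return [records]
    return list(records)


def gc_content(
    records: Union[SequenceRecord, Iterable[SequenceRecord]],
) -> float:
    """Pooled GC percentage over all residues, to 2 decimals.

    Ambiguity codes and N are excluded from both numerator and denominator,
    so GC stays well defined on masked ESTs.
    """
    recs = _as_records(records)
    if not recs:
        raise ValueError("gc_content requires at least one record")
    gc = at = 0
    for rec in recs:
        gc += rec.residues.count("G") + rec.residues.count("C")
        at += rec.residues.count("A") + rec.residues.count("T")
    if gc + at == 0:
        raise ValueError(
            "GC content undefined: no unambiguous bases in input"
        )
    return round_half_away(100.0 * gc / (gc + at), 2)


def average_bp_per_est(total_bp: int, n_sequences: int) -> int:
    """Mean sequence length rounded half away from zero to an integer."""
    if n_sequences <= 0:
        raise ValueError("n_sequences must be positive")
    return round_int_half_away(total_bp / n_sequences)


def database_stats(
    records: Union[SequenceRecord, Iterable[SequenceRecord]],
) -> DatabaseStats:
    """Per-database size and GC summary (count, bp, mean bp/EST, GC%)."""
    recs = _as_records(records)
    if not recs:
        raise ValueError("database_stats requires a non-empty database")
    total = sum(r.length for r in recs)
    return DatabaseStats(
        n_sequences=len(recs),
        total_bp=total,
        avg_bp_per_est=average_bp_per_est(total, len(recs)),
        gc_percent=gc_content(recs),
    )


def stats_table(
    databases: Mapping[str, Sequence[SequenceRecord]],
) -> pd.DataFrame:
    """Tabulate :func:`database_stats` for several labelled databases."""
    rows = []
    for label, recs in databases.items():
        st = database_stats(recs)
        rows.append(
            {
                "database": label,
                "n_sequences": st.n_sequences,
                "total_bp": st.total_bp,
                "avg_bp_per_est": st.avg_bp_per_est,
                "gc_percent": st.gc_percent,
            }
        )
    return pd.DataFrame(rows)
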