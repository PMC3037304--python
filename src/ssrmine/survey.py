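"""Comparative survey statistics over mined SSR loci.

Per-database summaries (loci counts, SSR frequency per EST, mean tract
length, sequences carrying one or several SSRs, single vs compound split),
canonical-motif frequency tables per motif length, motif-length spectra and
cross-database aggregates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ssrmine._rounding import round_half_away, round_int_half_away, trunc2
from ssrmine.engine import MiningResult, SSRLocus


@dataclass(frozen=True)
class SurveySummary:
    """Per-database SSR survey row.

    ssr_per_est_pct is truncated at two decimals; the other percentages
    round half away from zero (see docs/methods.md for the convention).
    pct_seq_multi_ssr is expressed relative to the number of sequences that
    carry at least one SSR.
    """

    database: str
    n_sequences: int
    n_loci: int
    ssr_per_est_pct: float
    avg_motif_length_bp: float
    n_seq_with_ssr: int
    pct_seq_with_ssr: float
    n_seq_multi_ssr: int
    pct_seq_multi_ssr: float
    n_single: int
    n_compound_loci: int


def ssr_per_est_percent(n_loci: int, n_sequences: int) -> float:
    """SSR frequency per EST as a percentage, truncated at 2 decimals."""
    if n_sequences <= 0:
        raise ValueError("n_sequences must be positive")
    return trunc2(100.0 * n_loci / n_sequences)


def summarize(
    result: MiningResult,
    n_sequences: int | None = None,
    database: str = "db",
) -> SurveySummary:
    """Survey summary for one mined database."""
    n_seq = result.n_sequences if n_sequences is None else n_sequences
    if n_seq <= 0:
        raise ValueError("database has no sequences")
    loci = result.all_loci
    per_seq = Counter(l.seq_id for l in loci)
    n_with = len(per_seq)
    n_multi = sum(1 for c in per_seq.values() if c >= 2)
    singles = result.singles
    avg_len = (
        round_half_away(sum(l.tract_length for l in singles) / len(singles), 2)
        if singles
        else 0.0
    )
    return SurveySummary(
        database=database,
        n_sequences=n_seq,
        n_loci=len(loci),
        ssr_per_est_pct=ssr_per_est_percent(len(loci), n_seq),
        avg_motif_length_bp=avg_len,
        n_seq_with_ssr=n_with,
        pct_seq_with_ssr=round_half_away(100.0 * n_with / n_seq, 2),
        n_seq_multi_ssr=n_multi,
        pct_seq_multi_ssr=(
            round_half_away(100.0 * n_multi / n_with, 2) if n_with else 0.0
        ),
        n_single=len(singles),
        n_compound_loci=len(result.compound_members),
    )


def summary_table(summaries: Iterable[SurveySummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


@dataclass(frozen=True)
class MotifFrequencyTable:
    """Canonical-pair counts within one motif-length class."""

    motif_length: int
    rows: tuple[tuple[str, int, float], ...]  # (pair, count, percent)
    total: int

    def percent_of(self, pair: str) -> float:
        for p, _, pct in self.rows:
            if p == pair:
                return pct
        return 0.0

    def to_frame(self, database: str = "db") -> pd.DataFrame:
        df = pd.DataFrame(
            list(self.rows), columns=["canonical_pair", "count", "percent"]
        )
        df.insert(0, "motif_length", self.motif_length)
        df.insert(0, "database", database)
        # integer motif-share column mirroring prose-style reporting
        df["percent_int"] = [round_int_half_away(p) for p in df["percent"]]
        return df


def motif_frequency_table(
    loci: Iterable[SSRLocus], motif_length: int
) -> MotifFrequencyTable:
    """Counts and percents by canonical pair for one motif length."""
    if not 1 <= motif_length <= 10:
        raise ValueError("motif_length must be in 1..10")
    counts = Counter(
        l.canonical_pair for l in loci if l.motif_length == motif_length
    )
    total = sum(counts.values())
    rows = tuple(
        (pair, n, round_half_away(100.0 * n / total, 2))
        for pair, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return MotifFrequencyTable(motif_length, rows, total)


def length_class_spectrum(
    loci: Iterable[SSRLocus],
) -> dict[int, tuple[int, float]]:
    """Distribution of loci over motif lengths 1-10: {length: (count, %)}."""
    counts = Counter(l.motif_length for l in loci)
    total = sum(counts.values())
    if total == 0:
        return {}
    return {
        p: (counts[p], round_half_away(100.0 * counts[p] / total, 2))
        for p in sorted(counts)
    }


def cross_database_mean(values: Sequence[float]) -> float:
    """Unweighted arithmetic mean across databases, to 2 decimals."""
    vals = list(values)
    if not vals:
        raise ValueError("cross_database_mean requires at least one value")
    return round_half_away(sum(vals) / len(vals), 2)


@dataclass(frozen=True)
class MotifRankReport:
    top_per_database: dict[str, tuple[tuple[str, int], ...]]
    shared_pairs: tuple[str, ...]


def rank_motifs(
    tables: Mapping[str, MotifFrequencyTable], k: int = 5
) -> MotifRankReport:
    """Top-k canonical pairs per database and the pairs present in all.

    Ordering within a database is count descending, label ascending; the
    shared set is sorted alphabetically.
    """
    top: dict[str, tuple[tuple[str, int], ...]] = {}
    present: list[set[str]] = []
    for db, table in tables.items():
        ordered = sorted(table.rows, key=lambda r: (-r[1], r[0]))
        top[db] = tuple((pair, n) for pair, n, _ in ordered[:k])
        present.append({pair for pair, _, _ in table.rows})
    shared = set.intersection(*present) if present else set()
    return MotifRankReport(top, tuple(sorted(shared)))
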