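"""Amino-acid prediction for trimer-family motifs and codon-bias statistics.

Motifs whose length is a multiple of three (trimers, hexamers, nonamers)
are read as codons of the standard genetic code to predict the amino acids
an in-frame repeat would encode. Codon-usage tables (Kazusa-style) yield
GC frequencies at each codon position (GC1/GC2/GC3) and a concordance
report between a database's most frequent trimer motifs and the species'
preferred synonymous codons.
"""

from __future__ import annotations

import os
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

import pandas as pd
from Bio.Seq import Seq

from ssrmine._rounding import round_half_away
from ssrmine.engine import SSRLocus
from ssrmine.survey import MotifFrequencyTable

_CODON_RE = re.compile(
    r"([ACGTUacgtu]{3})\s+([0-9]+(?:\.[0-9]+)?)(?:\s*\(\s*([0-9]+)\s*\))?"
)

_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon usage fractions for one species (64 codons, sum 1)."""

    species: str
    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        codons = set(self.fractions)
        if codons != set(ALL_CODONS):
            missing = sorted(set(ALL_CODONS) - codons)[:3]
            raise ValueError(
                f"codon table must cover all 64 DNA codons "
                f"(missing e.g. {missing})"
            )
        total = sum(self.fractions.values())
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("usage fractions must be non-negative")
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"usage fractions sum to {total}, expected 1")

    @classmethod
    def from_counts(
        cls, species: str, counts: Mapping[str, float]
    ) -> "CodonUsageTable":
        """Normalize raw counts or per-thousand frequencies to fractions."""
        clean = {c.upper().replace("U", "T"): v for c, v in counts.items()}
        for codon in ALL_CODONS:
            clean.setdefault(codon, 0.0)
        total = sum(clean.values())
        if total <= 0:
            raise ValueError("codon counts sum to zero")
        return cls(species, {c: v / total for c, v in clean.items()})

    @classmethod
    def uniform(cls, species: str = "uniform") -> "CodonUsageTable":
        return cls(species, {c: 1.0 / 64.0 for c in ALL_CODONS})

    @classmethod
    def from_kazusa(
        cls, source: Union[str, os.PathLike], species: str = ""
    ) -> "CodonUsageTable":
        """Parse a Kazusa-style codon usage listing.

        Accepts both the "UUU 17.6(714298)" block layout and plain
        tab/space-delimited "codon value" rows; U is mapped to T. When raw
        counts are present they take precedence over the per-thousand
        frequency column.
        """
        if os.path.exists(str(source)):
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
            if not species:
                species = os.path.basename(str(source))
        else:
            text = str(source)
        counts: dict[str, float] = {}
        for codon, freq, raw in _CODON_RE.findall(text):
            value = float(raw) if raw else float(freq)
            counts[codon.upper().replace("U", "T")] = value
        if len(counts) != 64:
            raise ValueError(
                f"Kazusa table parsed {len(counts)} codons, expected 64"
            )
        return cls.from_counts(species or "unknown", counts)


def translate_motif(motif: str, frame: int = 0) -> str:
    """Translate a 3/6/9 bp motif after rotating it by ``frame`` bases.

    The repeat unit itself is translated (the EST reading frame is unknown
    without ORF annotation); frame 1 and 2 rotate the unit before
    translation, covering the other phases of the tandem array. Stop
    codons render as '*'.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if len(motif) % 3 != 0 or len(motif) == 0:
        raise ValueError(
            f"motif length {len(motif)} is not a multiple of 3"
        )
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains ambiguity characters")
    rotated = motif[frame:] + motif[:frame]
    return str(Seq(rotated).translate())


@dataclass(frozen=True)
class AminoAcidProfile:
    """Residue shares over translatable (3/6/9 bp motif) loci."""

    counts: Mapping[str, int]
    n_translatable: int
    n_untranslatable: int

    @property
    def percents(self) -> dict[str, float]:
        total = sum(self.counts.values())
        if total == 0:
            return {}
        return {
            aa: round_half_away(100.0 * n / total, 2)
            for aa, n in sorted(self.counts.items())
        }

    def to_frame(self) -> pd.DataFrame:
        pct = self.percents
        return pd.DataFrame(
            [
                {"amino_acid": aa, "count": self.counts[aa], "percent": pct[aa]}
                for aa in sorted(self.counts)
            ],
            columns=["amino_acid", "count", "percent"],
        )


def amino_acid_profile(
    loci: Iterable[SSRLocus], frame: int = 0
) -> AminoAcidProfile:
    """Predicted amino-acid occurrence profile over mined loci.

    Only motifs of length 3, 6 or 9 contribute; each residue of a
    multi-residue translation counts once. Motifs are translated as
    observed (one strand), stop codons are kept as '*'.
    """
    counts: Counter[str] = Counter()
    n_ok = n_skip = 0
    for locus in loci:
        if locus.motif_length in (3, 6, 9):
            n_ok += 1
            counts.update(translate_motif(locus.motif, frame))
        else:
            n_skip += 1
    return AminoAcidProfile(dict(counts), n_ok, n_skip)


def gc_by_codon_position(
    table: CodonUsageTable,
) -> tuple[float, float, float]:
    """GC1/GC2/GC3: usage-weighted GC percentage at each codon position."""
    gc = [0.0, 0.0, 0.0]
    for codon, frac in table.fractions.items():
        for k in range(3):
            if codon[k] in "GC":
                gc[k] += frac
    return tuple(round_half_away(100.0 * g, 2) for g in gc)  # type: ignore


def synonymous_rank(codon: str, table: CodonUsageTable) -> int:
    """Rank of a codon's usage among its synonymous codons (1 = preferred)."""
    codon = codon.upper().replace("U", "T")
    aa = str(Seq(codon).translate())
    family = {
        c: f
        for c, f in table.fractions.items()
        if str(Seq(c).translate()) == aa
    }
    better = sum(1 for f in family.values() if f > family[codon])
    return better + 1


def motif_codon_concordance(
    trimer_table: MotifFrequencyTable,
    usage: CodonUsageTable,
    top_k: int = 5,
) -> pd.DataFrame:
    """Do a database's top trimer motifs match the species' codon bias?

    For each of the top-k trimer canonical pairs the observed motif (the
    alphabetically first member of the pair) is read as a codon; the report
    gives its usage fraction, its rank among synonymous codons and a
    concordance flag (rank 1, i.e. the motif is the preferred codon for its
    amino acid).
    """
    if trimer_table.motif_length != 3:
        raise ValueError("concordance is defined for trimer tables")
    rows = []
    ordered = sorted(trimer_table.rows, key=lambda r: (-r[1], r[0]))
    for pair, count, pct in ordered[:top_k]:
        motif = pair.split("/")[0]
        frac = usage.fractions[motif]
        rank = synonymous_rank(motif, usage)
        rows.append(
            {
                "canonical_pair": pair,
                "motif_as_codon": motif,
                "amino_acid": str(Seq(motif).translate()),
                "locus_count": count,
                "locus_percent": pct,
                "usage_fraction": round_half_away(frac, 4),
                "synonymous_rank": rank,
                "concordant": rank == 1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "canonical_pair", "motif_as_codon", "amino_acid",
            "locus_count", "locus_percent", "usage_fraction",
            "synonymous_rank", "concordant",
        ],
    )
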