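"""Synthetic EST databases with planted SSR tracts and known truth.

The generator emulates the shape of a pre-clustered EST database — a few
hundred sequences of 300-1000 bp with a configurable GC background and an
optional fraction of 3' poly-A tails — and plants perfect SSR tracts of
specified motif and repeat count at margin-separated positions. Every
generated sequence is verified by mining it back: the class I loci found
must be exactly the planted class I tracts, otherwise the sequence is
redrawn. The emitted truth table is therefore the complete locus set by
construction, which is what makes recall/precision tests on the mining
engine meaningful.

Ortholog derivatives for transferability experiments apply point
substitutions at a given rate outside the planted tracts, optionally
freezing the primer-design windows next to each tract so conserved-flank
scenarios can be constructed exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from ssrmine.engine import (
    MiningConfig,
    filter_class_i,
    find_perfect_repeats,
    is_primitive,
)
from ssrmine.seqio import SequenceRecord, UNAMBIGUOUS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantRule:
    """Plant ``n_loci`` tracts of ``motif`` x ``repeat_count`` in a database."""

    motif: str
    repeat_count: int
    n_loci: int

    def __post_init__(self) -> None:
        if set(self.motif) - UNAMBIGUOUS or not self.motif:
            raise ValueError("motif must be non-empty unambiguous DNA")
        if not is_primitive(self.motif):
            raise ValueError(f"motif {self.motif!r} is not primitive")
        if self.repeat_count < 2 or self.n_loci < 0:
            raise ValueError("repeat_count >= 2 and n_loci >= 0 required")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic EST database."""

    n_sequences: int
    length_range: tuple[int, int] = (300, 1000)
    gc_background: float = 0.5
    plant_rules: tuple[PlantRule, ...] = ()
    polyA_fraction: float = 0.0
    margin: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if self.n_sequences < 1 or lo < 1 or hi < lo:
            raise ValueError("invalid n_sequences or length_range")
        if not 0.0 <= self.gc_background <= 1.0:
            raise ValueError("gc_background must be in [0, 1]")
        if not 0.0 <= self.polyA_fraction <= 1.0:
            raise ValueError("polyA_fraction must be in [0, 1]")
        if self.margin < 1:
            raise ValueError("margin must be >= 1")

    @classmethod
    def from_config(cls, path: Union[str, os.PathLike]) -> "SyntheticSpec":
        """Read a flat key=value config; `plant=MOTIF:COUNT:N` may repeat."""
        kv: dict[str, str] = {}
        rules: list[PlantRule] = []
        with open(path, "r", encoding="utf-8") as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key == "plant":
                    motif, count, n = value.split(":")
                    rules.append(PlantRule(motif.upper(), int(count), int(n)))
                else:
                    kv[key] = value
        return cls(
            n_sequences=int(kv.get("n_sequences", 100)),
            length_range=(
                int(kv.get("length_min", 300)),
                int(kv.get("length_max", 1000)),
            ),
            gc_background=float(kv.get("gc_background", 0.5)),
            plant_rules=tuple(rules),
            polyA_fraction=float(kv.get("polyA_fraction", 0.0)),
            margin=int(kv.get("margin", 120)),
            seed=int(kv.get("seed", 0)),
        )


@dataclass(frozen=True)
class TruthRow:
    seq_id: str
    start: int  # 1-based inclusive
    end: int
    motif: str
    repeat_count: int

    @property
    def tract_length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TruthTable:
    """Planted-locus ground truth for one synthetic database."""

    rows: list[TruthRow] = field(default_factory=list)

    @property
    def n_loci(self) -> int:
        return len(self.rows)

    def class_i(self, min_tract_bp: int = 20) -> list[TruthRow]:
        return [r for r in self.rows if r.tract_length >= min_tract_bp]

    def spectrum(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for r in self.rows:
            out[len(r.motif)] = out.get(len(r.motif), 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [r.__dict__ for r in self.rows],
            columns=["seq_id", "start", "end", "motif", "repeat_count"],
        )

    def verify(self, records: Sequence[SequenceRecord]) -> bool:
        """Every truth row's substring equals motif x repeat_count."""
        by_id = {r.id: r for r in records}
        for row in self.rows:
            rec = by_id.get(row.seq_id)
            if rec is None:
                return False
            if (
                rec.residues[row.start - 1 : row.end]
                != row.motif * row.repeat_count
            ):
                return False
        return True


def _background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode("ascii")


def _mined_class_i(seq: str, seq_id: str, config: MiningConfig):
    rec = SequenceRecord(seq_id, "", seq)
    return {
        (l.start, l.end, l.motif)
        for l in filter_class_i(find_perfect_repeats(rec, config), config)
    }


def _build_sequence(
    rng: np.random.Generator,
    seq_id: str,
    tracts: Sequence[tuple[str, int]],
    spec: SyntheticSpec,
    config: MiningConfig,
    max_tries: int = 80,
) -> tuple[str, list[TruthRow]]:
    lo, hi = spec.length_range
    k = len(tracts)
    tract_bp = sum(len(m) * c for m, c in tracts)
    tail = 0
    if spec.polyA_fraction > 0 and rng.random() < spec.polyA_fraction:
        tail = int(rng.integers(8, 16))  # below the class I threshold
    need = tract_bp + spec.margin * (k + 1) + tail
    if need > hi:
        raise ValueError(
            f"{seq_id}: planted tracts ({tract_bp} bp in {k} loci) do not "
            f"fit a sequence of at most {hi} bp with margin {spec.margin}"
        )
    for _ in range(max_tries):
        length = int(rng.integers(max(lo, need), hi + 1))
        extra = length - need
        bonus = (
            rng.multinomial(extra, [1.0 / (k + 1)] * (k + 1))
            if extra > 0
            else np.zeros(k + 1, dtype=int)
        )
        gaps = [spec.margin + int(b) for b in bonus]
        parts: list[str] = []
        rows: list[TruthRow] = []
        pos = 0
        for gap, (motif, count) in zip(gaps, tracts):
            parts.append(_background(rng, gap, spec.gc_background))
            pos += gap
            tract = motif * count
            rows.append(
                TruthRow(seq_id, pos + 1, pos + len(tract), motif, count)
            )
            parts.append(tract)
            pos += len(tract)
        parts.append(_background(rng, gaps[-1], spec.gc_background))
        if tail:
            parts.append("A" * tail)
        seq = "".join(parts)
        expected = {
            (r.start, r.end, r.motif)
            for r in rows
            if r.tract_length >= config.min_tract_bp
        }
        # mine-back check: accidental repeats or junction extensions of a
        # planted tract force a redraw, keeping the truth table exact
        if _mined_class_i(seq, seq_id, config) == expected:
            return seq, rows
    raise RuntimeError(
        f"{seq_id}: could not generate a clean sequence in {max_tries} tries"
    )


def generate_database(
    spec: SyntheticSpec, config: MiningConfig | None = None
) -> tuple[list[SequenceRecord], TruthTable]:
    """Generate FASTA records plus their planted-locus truth table.

    A single integer seed drives all randomness; identical specs produce
    byte-identical databases. Raises before emitting anything when the
    planted tracts cannot fit the length range.
    """
    config = config or MiningConfig()
    rng = np.random.default_rng(spec.seed)
    # deal planted tracts round-robin across sequences
    tract_list: list[tuple[str, int]] = []
    for rule in spec.plant_rules:
        tract_list.extend([(rule.motif, rule.repeat_count)] * rule.n_loci)
    per_seq: list[list[tuple[str, int]]] = [
        [] for _ in range(spec.n_sequences)
    ]
    order = rng.permutation(len(tract_list))
    for i, j in enumerate(order):
        per_seq[i % spec.n_sequences].append(tract_list[int(j)])
    # feasibility check before any emission
    lo, hi = spec.length_range
    for i, tracts in enumerate(per_seq):
        need = (
            sum(len(m) * c for m, c in tracts)
            + spec.margin * (len(tracts) + 1)
            + 15  # worst-case poly-A tail
        )
        if need > hi:
            raise ValueError(
                f"spec infeasible: sequence {i + 1} would need {need} bp "
                f"but length_range caps at {hi}"
            )
    records: list[SequenceRecord] = []
    truth = TruthTable()
    width = len(str(spec.n_sequences))
    for i, tracts in enumerate(per_seq, start=1):
        seq_id = f"synth{i:0{width}d}"
        seq, rows = _build_sequence(rng, seq_id, tracts, spec, config)
        records.append(SequenceRecord(seq_id, "synthetic EST", seq))
        truth.rows.extend(rows)
    return records, truth


def derive_ortholog_database(
    records: Sequence[SequenceRecord],
    truth: TruthTable,
    divergence: float,
    flank_conservation: bool = False,
    seed: int = 0,
    frozen_flank: int = 60,
    mutate_tracts: bool = False,
) -> tuple[list[SequenceRecord], TruthTable]:
    """Point-substituted copy of a database, emulating an ortholog set.

    Substitutions hit each eligible position independently with probability
    ``divergence``. Planted tracts are conserved unless ``mutate_tracts``
    is set; with ``flank_conservation`` the ``frozen_flank`` bases on each
    side of every tract are also left untouched (wide enough to cover the
    outward slide of the primer window rule), so primers picked from
    those windows still match exactly. When tracts are mutated the truth
    table is rebuilt by re-mining the derived records.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows_by_seq: dict[str, list[TruthRow]] = {}
    for row in truth.rows:
        rows_by_seq.setdefault(row.seq_id, []).append(row)
    out: list[SequenceRecord] = []
    for rec in records:
        arr = np.frombuffer(
            rec.residues.encode("ascii"), dtype=np.uint8
        ).copy()
        eligible = np.ones(len(arr), dtype=bool)
        for row in rows_by_seq.get(rec.id, []):
            lo = row.start - 1
            hi = row.end
            if not mutate_tracts:
                eligible[lo:hi] = False
            if flank_conservation:
                eligible[max(0, lo - frozen_flank) : lo] = False
                eligible[hi : hi + frozen_flank] = False
        hit = eligible & (rng.random(len(arr)) < divergence)
        for pos in np.flatnonzero(hit):
            choices = _BASES[_BASES != arr[pos]]
            arr[pos] = rng.choice(choices)
        out.append(
            SequenceRecord(rec.id, rec.description, arr.tobytes().decode())
        )
    if mutate_tracts:
        config = MiningConfig()
        new_truth = TruthTable()
        for rec in out:
            for start, end, motif in sorted(
                _mined_class_i(rec.residues, rec.id, config)
            ):
                new_truth.rows.append(
                    TruthRow(rec.id, start, end, motif, (end - start + 1) // len(motif))
                )
        return out, new_truth
    return out, TruthTable(rows=list(truth.rows))
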