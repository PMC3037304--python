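"""In-silico PCR for EST-SSR marker transferability.

Primer pairs are picked from the flanks of mined SSR loci by a minimal
deterministic window rule (the goal is transferability assessment, not
thermodynamic primer optimization). A scan then locates, in any target
database, every site pair where the forward primer matches the plus strand
and the reverse primer matches the minus strand downstream, each within a
mismatch allowance outside an exactly matching 3' anchor. Products are
classified on/off-target by whether they contain a class I SSR of the same
canonical motif family as the source locus, transfer rates are tabulated
per source/target database pair, and amplicon sizes can be rendered as a
virtual electrophoresis gel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ssrmine._rounding import round_half_away
from ssrmine.engine import MiningResult, SSRLocus, reverse_complement
from ssrmine.seqio import SequenceRecord, UNAMBIGUOUS


@dataclass(frozen=True)
class EPCRParams:
    """Matching rules for the electronic PCR scan."""

    max_mismatches_per_primer: int = 1
    three_prime_anchor: int = 5
    max_product_bp: int = 5000

    def __post_init__(self) -> None:
        if self.max_mismatches_per_primer < 0:
            raise ValueError("mismatch allowance must be >= 0")
        if self.three_prime_anchor < 0:
            raise ValueError("anchor must be >= 0")
        if self.max_product_bp < 1:
            raise ValueError("max_product_bp must be positive")


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primer pair bracketing a source SSR locus.

    The reverse primer is given 5'->3' on the opposite strand, as it would
    be ordered from a synthesis house.
    """

    pair_id: str
    source_seq_id: str
    forward: str
    reverse: str
    source_locus: SSRLocus | None = None

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not 15 <= len(seq) <= 30:
                raise ValueError(f"{name} primer must be 15-30 bases")
            if set(seq) - UNAMBIGUOUS:
                raise ValueError(f"{name} primer contains ambiguous bases")


@dataclass(frozen=True)
class Amplicon:
    """One predicted PCR product (1-based inclusive, primer sites included)."""

    pair_id: str
    target_db: str
    target_seq_id: str
    start: int
    end: int
    mismatches_fwd: int
    mismatches_rev: int
    on_target: bool | None = None

    @property
    def product_length(self) -> int:
        return self.end - self.start + 1


def _has_mono_run(seq: str, run: int = 6) -> bool:
    count = 1
    for a, b in zip(seq, seq[1:]):
        count = count + 1 if a == b else 1
        if count >= run:
            return True
    return False


def _pick_window(flank: str, window: int, from_end: bool) -> int | None:
    """Offset of the first clean window, sliding away from the tract.

    ``from_end`` scans right-to-left (5' flank); otherwise left-to-right.
    A window is clean when it has no ambiguity character and no
    mononucleotide run of 6 or more.
    """
    n = len(flank)
    if n < window:
        return None
    positions = range(n - window, -1, -1) if from_end else range(0, n - window + 1)
    for i in positions:
        win = flank[i : i + window]
        if set(win) - UNAMBIGUOUS:
            continue
        if _has_mono_run(win):
            continue
        return i
    return None


def design_flanking_primers(
    locus: SSRLocus,
    record: SequenceRecord,
    window: int = 20,
    offset: int = 3,
    pair_id: str | None = None,
) -> PrimerPair | None:
    """Pick a fixed-length primer window from each flank of a locus.

    Windows keep at least ``offset`` bases away from the tract and slide
    outward until clean (no ambiguity characters, no mono-run >= 6).
    Returns None when either flank is shorter than window + offset or no
    clean window exists.
    """
    if locus.seq_id != record.id:
        raise ValueError(
            f"locus {locus.seq_id!r} does not lie on record {record.id!r}"
        )
    seq = record.residues
    left = seq[: locus.start - 1 - offset]
    right = seq[locus.end + offset :]
    i = _pick_window(left, window, from_end=True)
    j = _pick_window(right, window, from_end=False)
    if i is None or j is None:
        return None
    fwd = left[i : i + window]
    rev = reverse_complement(right[j : j + window])
    return PrimerPair(
        pair_id=pair_id or f"{record.id}:{locus.start}-{locus.end}",
        source_seq_id=record.id,
        forward=fwd,
        reverse=rev,
        source_locus=locus,
    )


def design_primers_for_database(
    result: MiningResult,
    records: Sequence[SequenceRecord],
    window: int = 20,
    offset: int = 3,
) -> list[PrimerPair]:
    """Primer pairs for every single class I locus of a mined database."""
    by_id = {r.id: r for r in records}
    pairs: list[PrimerPair] = []
    for k, locus in enumerate(result.singles, start=1):
        pair = design_flanking_primers(
            locus, by_id[locus.seq_id], window, offset, pair_id=f"ssr{k}"
        )
        if pair is not None:
            pairs.append(pair)
    return pairs


class _TargetIndex:
    """Concatenated byte view of a database for vectorized site scans."""

    def __init__(self, records: Sequence[SequenceRecord]):
        self.records = list(records)
        self.arr = np.frombuffer(
            "".join(r.residues for r in self.records).encode("ascii"),
            dtype=np.uint8,
        )
        lengths = np.array([r.length for r in self.records], dtype=np.int64)
        self.starts = np.concatenate(([0], np.cumsum(lengths)))  # len n+1

    def record_of(self, pos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.starts, pos, side="right") - 1


def _site_scan(
    arr: np.ndarray,
    pattern: str,
    anchor_positions: range,
    max_mm: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Start positions where the pattern matches the array.

    Mismatches at ``anchor_positions`` (indices within the pattern) are
    forbidden; elsewhere up to ``max_mm`` are allowed. Returns (starts,
    mismatch counts outside the anchor).
    """
    pat = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
    L = len(pat)
    n = len(arr)
    if n < L:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int32)
    m = n - L + 1
    mm = np.zeros(m, dtype=np.int32)
    anchor_mm = np.zeros(m, dtype=np.int32)
    anchor = set(anchor_positions)
    for i in range(L):
        neq = arr[i : m + i] != pat[i]
        if i in anchor:
            anchor_mm += neq
        else:
            mm += neq
    hits = np.flatnonzero((anchor_mm == 0) & (mm <= max_mm))
    return hits, mm[hits]


def epcr_scan(
    pairs: Iterable[PrimerPair],
    targets: Sequence[SequenceRecord],
    params: EPCRParams | None = None,
    target_db: str = "db",
) -> list[Amplicon]:
    """All predicted amplicons of the primer pairs against a database.

    The forward primer must match the plus strand and the reverse primer
    the minus strand downstream on the same record; primer sites may not
    overlap and the product (primer sites included) may not exceed
    ``max_product_bp``. Every qualifying site pair is reported, so one
    primer pair can yield several amplicons per target. Output is sorted
    by (pair, target sequence, start).
    """
    params = params or EPCRParams()
    idx = _TargetIndex(targets)
    amplicons: list[Amplicon] = []
    for pair in pairs:
        lf, lr = len(pair.forward), len(pair.reverse)
        a_f = min(params.three_prime_anchor, lf)
        a_r = min(params.three_prime_anchor, lr)
        # forward primer 3' end = last bases of the plus-strand pattern
        f_hits, f_mm = _site_scan(
            idx.arr, pair.forward, range(lf - a_f, lf),
            params.max_mismatches_per_primer,
        )
        # reverse primer binds the plus strand as its reverse complement;
        # its 3' end maps to the *left* end of the plus-strand pattern
        rc = reverse_complement(pair.reverse)
        r_hits, r_mm = _site_scan(
            idx.arr, rc, range(0, a_r), params.max_mismatches_per_primer
        )
        if len(f_hits) == 0 or len(r_hits) == 0:
            continue
        f_rec = idx.record_of(f_hits)
        f_rec_end = idx.record_of(f_hits + lf - 1)
        f_ok = f_rec == f_rec_end
        r_rec = idx.record_of(r_hits)
        r_rec_end = idx.record_of(r_hits + lr - 1)
        r_ok = r_rec == r_rec_end
        f_hits, f_mm, f_rec = f_hits[f_ok], f_mm[f_ok], f_rec[f_ok]
        r_hits, r_mm, r_rec = r_hits[r_ok], r_mm[r_ok], r_rec[r_ok]
        for fi in range(len(f_hits)):
            f = int(f_hits[fi])
            rec_i = int(f_rec[fi])
            sel = np.flatnonzero(
                (r_rec == rec_i)
                & (r_hits >= f + lf)
                & (r_hits + lr - 1 - f + 1 <= params.max_product_bp)
            )
            base = int(idx.starts[rec_i])
            for ri in sel:
                r = int(r_hits[ri])
                amplicons.append(
                    Amplicon(
                        pair_id=pair.pair_id,
                        target_db=target_db,
                        target_seq_id=idx.records[rec_i].id,
                        start=f - base + 1,
                        end=r + lr - 1 - base + 1,
                        mismatches_fwd=int(f_mm[fi]),
                        mismatches_rev=int(r_mm[ri]),
                    )
                )
    amplicons.sort(key=lambda a: (a.pair_id, a.target_seq_id, a.start))
    return amplicons


def classify_on_target(
    amplicons: Iterable[Amplicon],
    target_mining: MiningResult,
    pairs: Iterable[PrimerPair],
) -> list[Amplicon]:
    """Set the on-target flag on each amplicon.

    An amplicon is on target when its product span contains at least one
    class I locus of the target whose canonical pair equals the canonical
    pair of the locus the primers were designed around.
    """
    source_pair = {
        p.pair_id: p.source_locus.canonical_pair
        for p in pairs
        if p.source_locus is not None
    }
    loci_by_seq: dict[str, list[SSRLocus]] = {}
    for locus in target_mining.all_loci:
        loci_by_seq.setdefault(locus.seq_id, []).append(locus)
    out = []
    for amp in amplicons:
        wanted = source_pair.get(amp.pair_id)
        hit = False
        if wanted is not None:
            for locus in loci_by_seq.get(amp.target_seq_id, []):
                if (
                    locus.start >= amp.start
                    and locus.end <= amp.end
                    and locus.canonical_pair == wanted
                ):
                    hit = True
                    break
        out.append(replace(amp, on_target=hit))
    return out


def transferability_matrix(
    primer_sets: Mapping[str, Sequence[PrimerPair]],
    targets: Mapping[str, Sequence[SequenceRecord]],
    params: EPCRParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-database amplification rates and per-pair amplicon counts.

    The transfer rate for (source, target) is the percentage of the
    source's primer pairs that yield at least one amplicon in the target.
    The second frame gives the per-pair amplicon count breakdown behind
    each rate (how many pairs gave 1, 2, 3... products).
    """
    params = params or EPCRParams()
    rate_rows, count_rows = [], []
    for src, pairs in primer_sets.items():
        for tgt, records in targets.items():
            amps = epcr_scan(pairs, records, params, target_db=tgt)
            per_pair = {p.pair_id: 0 for p in pairs}
            for a in amps:
                per_pair[a.pair_id] += 1
            n_amp = sum(1 for v in per_pair.values() if v > 0)
            rate = (
                round_half_away(100.0 * n_amp / len(pairs), 2)
                if pairs
                else 0.0
            )
            rate_rows.append(
                {
                    "source": src,
                    "target": tgt,
                    "n_pairs": len(pairs),
                    "n_pairs_amplifying": n_amp,
                    "transfer_rate_pct": rate,
                }
            )
            for pid, cnt in sorted(per_pair.items()):
                count_rows.append(
                    {
                        "source": src,
                        "target": tgt,
                        "pair_id": pid,
                        "n_amplicons": cnt,
                    }
                )
    return pd.DataFrame(rate_rows), pd.DataFrame(count_rows)


def virtual_gel(
    amplicons: Iterable[Amplicon],
) -> dict[tuple[str, str], list[tuple[int, int]]]:
    """Group amplicon sizes into gel lanes keyed by (pair, target db).

    Each lane is a descending list of (size, multiplicity); identical
    sizes collapse into one band annotated with its multiplicity.
    """
    lanes: dict[tuple[str, str], dict[int, int]] = {}
    for amp in amplicons:
        lane = lanes.setdefault((amp.pair_id, amp.target_db), {})
        lane[amp.product_length] = lane.get(amp.product_length, 0) + 1
    return {
        key: sorted(sizes.items(), key=lambda kv: -kv[0])
        for key, sizes in sorted(lanes.items())
    }


def render_gel(
    lanes: Mapping[tuple[str, str], list[tuple[int, int]]],
    n_rungs: int = 12,
) -> str:
    """Text rendering of a virtual gel with a log-spaced size ladder."""
    if not lanes:
        return "(no amplicons)\n"
    sizes = [s for bands in lanes.values() for s, _ in bands]
    lo = max(min(sizes) * 0.8, 10.0)
    hi = max(sizes) * 1.2
    rungs = np.geomspace(hi, lo, n_rungs)
    keys = list(lanes)
    width = 10
    header = "ladder".rjust(8) + " " + " ".join(
        f"{k[0]}|{k[1]}"[:width].center(width) for k in keys
    )
    lines = [header]
    for r_i, rung in enumerate(rungs):
        upper = rungs[r_i - 1] if r_i else float("inf")
        cells = []
        for k in keys:
            band = [
                (s, c) for s, c in lanes[k] if rung <= s < upper
            ]
            if band:
                label = ",".join(
                    f"{s}" + (f"x{c}" if c > 1 else "") for s, c in band
                )
                cells.append(label[:width].center(width))
            else:
                cells.append(" " * width)
        lines.append(f"{rung:7.0f}b " + " ".join(cells))
    return "\n".join(lines) + "\n"


def amplicon_table(amplicons: Iterable[Amplicon]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair_id": a.pair_id,
                "target_db": a.target_db,
                "target_seq": a.target_seq_id,
                "start": a.start,
                "end": a.end,
                "length": a.product_length,
                "mismatches_fwd": a.mismatches_fwd,
                "mismatches_rev": a.mismatches_rev,
                "on_target": a.on_target,
            }
            for a in amplicons
        ],
        columns=[
            "pair_id", "target_db", "target_seq", "start", "end",
            "length", "mismatches_fwd", "mismatches_rev", "on_target",
        ],
    )
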