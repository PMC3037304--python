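"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorized code paths:
they enumerate candidates quadratically straight from the definitions, so
they can vouch for the fast implementations.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from ssrmine import MiningConfig, PlantRule, SequenceRecord, SyntheticSpec
from ssrmine import generate_database

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

ACGT = set("ACGT")


def _primitive(motif: str) -> bool:
    n = len(motif)
    return not any(
        n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n)
    )


def brute_force_repeats(seq: str, min_motif: int = 1, max_motif: int = 10):
    """All maximal perfect tandem repeats by quadratic enumeration.

    Scans every (start, period) candidate; a locus is reported when at
    least two complete copies of a primitive, unambiguous motif follow
    from ``start`` and the run cannot be extended leftwards by one base
    (so each tandem run is reported once, at its leftmost phase).
    Returns (start, end, motif, repeat_count) with 1-based coordinates.
    """
    n = len(seq)
    out = []
    for p in range(min_motif, max_motif + 1):
        for start in range(0, n - 2 * p + 1):
            motif = seq[start : start + p]
            if set(motif) - ACGT or not _primitive(motif):
                continue
            k = 1
            while (
                start + (k + 1) * p <= n
                and seq[start + k * p : start + (k + 1) * p] == motif
            ):
                k += 1
            if k < 2:
                continue
            if (
                start > 0
                and seq[start - 1] in ACGT
                and seq[start - 1] == seq[start - 1 + p]
            ):
                continue  # not the leftmost phase of this run
            out.append((start + 1, start + k * p, motif, k))
    out.sort(key=lambda t: (t[0], len(t[2])))
    return out


def brute_force_overlap_resolution(loci, min_tract_bp: int = 20):
    """Reference greedy overlap elimination working on raw intervals.

    Independent of the package's locus objects: takes and returns
    (start, end, motif) tuples, applying longest-first selection with
    whole-copy truncation of losers.
    """
    def tract_len(t):
        return t[1] - t[0] + 1

    order = sorted(loci, key=lambda t: (-tract_len(t), t[0], len(t[2])))
    chosen = []

    def free(a, b):
        return all(b < s or a > e for s, e, _ in chosen)

    for start, end, motif in order:
        p = len(motif)
        copies = tract_len((start, end, motif)) // p
        best = None
        run = 0
        run_at = None
        for m in range(copies + 1):
            ok = m < copies and free(start + m * p, start + (m + 1) * p - 1)
            if ok:
                if run == 0:
                    run_at = m
                run += 1
            else:
                if run and (best is None or run > best[0]):
                    best = (run, run_at)
                run = 0
        if best and best[0] * p >= min_tract_bp and best[0] >= 2:
            a = start + best[1] * p
            chosen.append((a, a + best[0] * p - 1, motif))
    return sorted(chosen)


@pytest.fixture(scope="session")
def planted_db():
    """Small synthetic database with one AG x 12 tract per sequence."""
    spec = SyntheticSpec(
        n_sequences=15,
        plant_rules=(PlantRule("AG", 12, 15),),
        polyA_fraction=0.2,
        seed=11,
    )
    return generate_database(spec)


@pytest.fixture()
def record_factory():
    def make(seq: str, seq_id: str = "s1") -> SequenceRecord:
        return SequenceRecord(seq_id, "", seq)

    return make


@pytest.fixture()
def default_config() -> MiningConfig:
    return MiningConfig()
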