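import numpy as np
import pytest

from ssrmine import (
    Amplicon,
    EPCRParams,
    PrimerPair,
    SequenceRecord,
    SSRLocus,
    classify_on_target,
    design_flanking_primers,
    design_primers_for_database,
    epcr_scan,
    mine_database,
    render_gel,
    transferability_matrix,
    virtual_gel,
)
from ssrmine.engine import reverse_complement

RNG = np.random.default_rng(2024)


def _random_dna(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))

FWD = "ACGTTGCACGATCGTACGTA"
REV_SITE = "TGCATGCCTAGGATCGATCC"   # plus-strand segment the reverse binds
REVERSE = reverse_complement(REV_SITE)


def _template(between=60, lead=10, tail=10):
    return "C" * lead + FWD + _random_dna(between) + REV_SITE + "G" * tail


def _locus(seq_id, motif, count, start):
    return SSRLocus(
        seq_id=seq_id,
        motif=motif,
        repeat_count=count,
        start=start,
        end=start + len(motif) * count - 1,
    )


class TestPrimerDesign:
    def test_clean_flanks_give_bracketing_pair(self):
        left = _random_dna(50)
        right = _random_dna(50)
        seq = left + "AG" * 12 + right
        record = SequenceRecord("s", "", seq)
        locus = _locus("s", "AG", 12, 51)
        pair = design_flanking_primers(locus, record)
        assert pair is not None
        # windows sit >= 3 bases from the tract, nearest-first
        assert pair.forward == left[27:47]
        assert pair.reverse == reverse_complement(right[3:23])

    def test_short_flank_returns_none(self):
        seq = "CGT" + "AG" * 12 + _random_dna(50)
        record = SequenceRecord("s", "", seq)
        assert design_flanking_primers(_locus("s", "AG", 12, 4), record) is None

    def test_mono_run_everywhere_returns_none(self):
        seq = "A" * 40 + "GC" * 12 + "A" * 40
        record = SequenceRecord("s", "", seq)
        assert design_flanking_primers(_locus("s", "GC", 12, 41), record) is None

    def test_window_slides_past_dirty_region(self):
        left = _random_dna(30) + "TTTTTTTT" + _random_dna(15)
        right = _random_dna(50)
        seq = left + "AG" * 12 + right
        record = SequenceRecord("s", "", seq)
        pair = design_flanking_primers(_locus("s", "AG", 12, len(left) + 1), record)
        assert pair is not None
        assert "TTTTTT" not in pair.forward

    def test_locus_record_mismatch_is_error(self):
        record = SequenceRecord("other", "", _random_dna(100))
        with pytest.raises(ValueError):
            design_flanking_primers(_locus("s", "AG", 12, 30), record)


class TestEpcrScan:
    def test_constructed_product_arithmetic(self):
        template = _template(between=60)
        record = SequenceRecord("t", "", template)
        pair = PrimerPair("p1", "src", FWD, REVERSE)
        amps = epcr_scan([pair], [record])
        assert len(amps) == 1
        amp = amps[0]
        assert amp.product_length == 20 + 60 + 20
        assert (amp.start, amp.end) == (11, 110)
        assert amp.mismatches_fwd == amp.mismatches_rev == 0

    def test_mismatch_inside_anchor_kills_site(self):
        template = _template()
        # corrupt the last base of the forward site (the 3' anchor)
        site_end = 10 + len(FWD) - 1
        base = template[site_end]
        swapped = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
        mutated = template[:site_end] + swapped + template[site_end + 1:]
        pair = PrimerPair("p1", "src", FWD, REVERSE)
        assert epcr_scan([pair], [SequenceRecord("t", "", mutated)]) == []

    def test_mismatch_outside_anchor_tolerated(self):
        template = _template()
        pos = 12  # third base of the forward site, far from the 3' end
        base = template[pos]
        swapped = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
        mutated = template[:pos] + swapped + template[pos + 1:]
        pair = PrimerPair("p1", "src", FWD, REVERSE)
        amps = epcr_scan([pair], [SequenceRecord("t", "", mutated)])
        assert len(amps) == 1 and amps[0].mismatches_fwd == 1
        strict = EPCRParams(max_mismatches_per_primer=0)
        assert epcr_scan([pair], [SequenceRecord("t", "", mutated)], strict) == []

    def test_two_reverse_sites_give_two_amplicons(self):
        template = (
            "C" * 10 + FWD + _random_dna(40) + REV_SITE
            + _random_dna(30) + REV_SITE + "G" * 10
        )
        pair = PrimerPair("p1", "src", FWD, REVERSE)
        amps = epcr_scan([pair], [SequenceRecord("t", "", template)])
        assert [a.product_length for a in amps] == [80, 130]

    def test_product_cap_enforced(self):
        template = _template(between=200)
        pair = PrimerPair("p1", "src", FWD, REVERSE)
        params = EPCRParams(max_product_bp=150)
        assert epcr_scan([pair], [SequenceRecord("t", "", template)], params) == []

    def test_sites_must_share_a_record(self):
        rec_a = SequenceRecord("a", "", "C" * 10 + FWD + "G" * 10)
        rec_b = SequenceRecord("b", "", "C" * 10 + REV_SITE + "G" * 10)
        pair = PrimerPair("p1", "src", FWD, REVERSE)
        assert epcr_scan([pair], [rec_a, rec_b]) == []

    def test_zero_mismatch_equals_substring_search(self):
        rng = np.random.default_rng(5)
        records = [
            SequenceRecord(f"t{i}", "", _random_dna(400, rng))
            for i in range(6)
        ]
        # plant the sites into two of the records
        planted = records[2].residues[:50] + FWD + records[2].residues[70:250] \
            + REV_SITE + records[2].residues[270:]
        records[2] = SequenceRecord("t2", "", planted)
        pair = PrimerPair("p1", "src", FWD, REVERSE)
        params = EPCRParams(max_mismatches_per_primer=0)
        amps = epcr_scan([pair], records, params)
        expected = []
        for rec in records:
            f = rec.residues.find(FWD)
            r = rec.residues.find(REV_SITE)
            if f != -1 and r != -1 and r >= f + len(FWD):
                expected.append((rec.id, f + 1, r + len(REV_SITE)))
        assert [(a.target_seq_id, a.start, a.end) for a in amps] == expected

    def test_monotone_in_mismatches_and_product_cap(self):
        rng = np.random.default_rng(9)
        records = [
            SequenceRecord(f"t{i}", "", _random_dna(500, rng))
            for i in range(4)
        ]
        pair = PrimerPair("p1", "src", FWD, REVERSE)

        def keyset(params):
            return {
                (a.target_seq_id, a.start, a.end)
                for a in epcr_scan([pair], records, params)
            }

        for mm in (0, 1, 2):
            assert keyset(EPCRParams(mm, 5, 400)) <= keyset(
                EPCRParams(mm + 1, 5, 400)
            )
            assert keyset(EPCRParams(mm, 5, 300)) <= keyset(
                EPCRParams(mm, 5, 500)
            )


class TestClassifyOnTarget:
    def _setup(self, tract_motif):
        seq = _random_dna(60) + tract_motif * 12 + _random_dna(60)
        record = SequenceRecord("t", "", seq)
        result = mine_database([record])
        amp = Amplicon("p1", "db", "t", 1, len(seq), 0, 0)
        source = _locus("src", "AG", 12, 10)
        pair = PrimerPair("p1", "src", FWD, REVERSE, source_locus=source)
        return classify_on_target([amp], result, [pair])[0]

    def test_same_family_tract_is_on_target(self):
        assert self._setup("AG").on_target is True

    def test_reverse_complement_family_counts(self):
        assert self._setup("CT").on_target is True

    def test_other_family_is_off_target(self):
        assert self._setup("GCA").on_target is False

    def test_no_ssr_in_product_is_off_target(self):
        record = SequenceRecord("t", "", _random_dna(150))
        result = mine_database([record])
        amp = Amplicon("p1", "db", "t", 1, 150, 0, 0)
        pair = PrimerPair(
            "p1", "src", FWD, REVERSE,
            source_locus=_locus("src", "AG", 12, 10),
        )
        assert classify_on_target([amp], result, [pair])[0].on_target is False


class TestTransferability:
    def test_rates_from_counts(self):
        templates = [
            SequenceRecord("t0", "", _template()),
            SequenceRecord("t1", "", _random_dna(200)),
        ]
        pairs = [
            PrimerPair("hit", "src", FWD, REVERSE),
            PrimerPair("miss", "src", _random_dna(20), _random_dna(20)),
        ]
        rates, counts = transferability_matrix({"src": pairs}, {"tgt": templates})
        assert rates.loc[0, "transfer_rate_pct"] == 50.00
        by_pair = dict(zip(counts["pair_id"], counts["n_amplicons"]))
        assert by_pair == {"hit": 1, "miss": 0}

    def test_no_amplifying_pairs_is_zero(self):
        pairs = [PrimerPair("p", "src", _random_dna(20), _random_dna(20))]
        rates, _ = transferability_matrix(
            {"src": pairs}, {"tgt": [SequenceRecord("t", "", _random_dna(100))]}
        )
        assert rates.loc[0, "transfer_rate_pct"] == 0.00

    def test_self_transfer_is_identity(self, planted_db):
        records, _ = planted_db
        result = mine_database(records)
        pairs = design_primers_for_database(result, records)
        assert pairs, "expected primer pairs from the planted database"
        amps = epcr_scan(pairs, records, target_db="self")
        amps = classify_on_target(amps, result, pairs)
        per_pair = {p.pair_id: 0 for p in pairs}
        for a in amps:
            per_pair[a.pair_id] += 1
        assert set(per_pair.values()) == {1}
        assert all(a.on_target for a in amps)


class TestVirtualGel:
    def test_lane_sorted_descending(self):
        amps = [
            Amplicon("p1", "db", "t", 1, 110, 0, 0),
            Amplicon("p1", "db", "t", 1, 240, 0, 0),
        ]
        lanes = virtual_gel(amps)
        assert lanes[("p1", "db")] == [(240, 1), (110, 1)]

    def test_empty_gel(self):
        assert virtual_gel([]) == {}
        assert "no amplicons" in render_gel({})

    def test_duplicate_sizes_collapse_with_multiplicity(self):
        amps = [Amplicon("p1", "db", "t", 1, 110, 0, 0)] * 2
        lanes = virtual_gel(amps)
        assert lanes[("p1", "db")] == [(110, 2)]
        assert "110x2" in render_gel(lanes)

    def test_render_contains_lane_header_and_band(self):
        amps = [Amplicon("p9", "rice", "t", 1, 240, 0, 0)]
        text = render_gel(virtual_gel(amps))
        assert "p9|rice" in text and "240" in text
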