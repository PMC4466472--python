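"""Hairpin metrics, bias computations, structure filters and conservation."""

import numpy as np
import pytest

from phasiforge import sra_io
from phasiforge.mirna_discovery import (
    FilterThresholds,
    HairpinCandidate,
    ReadLocusIndex,
    apply_structure_filters,
    classify_conservation,
    compute_abundance_bias,
    compute_strand_bias,
    end_anchored_distance,
    fold_and_score,
)
from phasiforge.sra_io import Contig, LocusHit


def make_candidate(**overrides) -> HairpinCandidate:
    """A candidate with all metrics passing, to be perturbed per test."""
    base = dict(
        contig_id="c", window_start=0, window_end=100, strand="+",
        precursor_seq="A" * 100, mature_seq="A" * 21, mature_start=0,
        mature_end=21, mfe=-45.0, gc_pct=50.0, amfe=45.0, mfei=0.90,
        duplex_mismatches=2, strand_bias=0.95, abundance_bias=0.8,
    )
    base.update(overrides)
    return HairpinCandidate(**base)


class TestMetricArithmetic:
    def test_amfe_and_mfei_definitions(self, backend, rng):
        # len 100, mfe -45, GC 50% -> AMFE 45, MFEI 0.9 (checked through the
        # same formulas fold_and_score applies)
        c = make_candidate()
        assert c.amfe == pytest.approx(-c.mfe / 100 * 100)
        assert c.mfei == pytest.approx(c.amfe / c.gc_pct)

    def test_fold_and_score_on_planted_hairpin(self, backend, small_study):
        h = small_study.manifest.planted_hairpins[0]
        contig = next(c for c in small_study.contigs if c.id == h.contig_id)
        cand = HairpinCandidate(
            contig_id=h.contig_id,
            window_start=h.precursor_start, window_end=h.precursor_end,
            strand="+",
            precursor_seq=contig.sequence[h.precursor_start:h.precursor_end],
            mature_seq=h.mature_seq,
            mature_start=h.mature_start - h.precursor_start,
            mature_end=h.mature_end - h.precursor_start,
        )
        scored = fold_and_score(cand, backend=backend)
        assert scored is not None
        assert scored.duplex_mismatches == h.mismatches
        assert scored.mfe <= -30.0
        assert scored.mfei == pytest.approx(scored.amfe / scored.gc_pct, abs=1e-9)
        assert len(scored.structure) == len(scored.precursor_seq)


def _bias_fixture(sense_counts, anti_counts):
    contig = Contig("c", "A" * 200)
    reads, hits = [], {}
    seqs = []
    rng = np.random.default_rng(0)
    for i, n in enumerate(sense_counts + anti_counts):
        seq = "".join(rng.choice(list("ACGT"), size=21))
        strand = "+" if i < len(sense_counts) else "-"
        reads.extend([seq] * n)
        hits[seq] = [LocusHit("c", 10 + 2 * i, 31 + 2 * i, strand)]
        seqs.append(seq)
    collapsed = sra_io.collapse_reads({"l": reads})
    return collapsed, {s: hits[s] for s in hits}


class TestBiases:
    def test_strand_bias_arithmetic_and_limit(self):
        collapsed, hits = _bias_fixture([90], [10])
        idx = ReadLocusIndex(collapsed, hits)
        cand = make_candidate()
        assert compute_strand_bias(cand, idx) == pytest.approx(0.90)
        collapsed, hits = _bias_fixture([50], [])
        assert compute_strand_bias(cand, ReadLocusIndex(collapsed, hits)) == 1.0

    def test_abundance_bias_top3(self):
        collapsed, hits = _bias_fixture([50, 30, 20], [])
        cand = make_candidate()
        assert compute_abundance_bias(cand, ReadLocusIndex(collapsed, hits)) == 1.0
        collapsed, hits = _bias_fixture([40, 30, 20, 30, 30], [])
        assert compute_abundance_bias(
            cand, ReadLocusIndex(collapsed, hits)
        ) == pytest.approx(100 / 150)

    def test_abundance_bias_matches_sort_and_sum_oracle(self, rng):
        for _ in range(10):
            counts = [int(c) for c in rng.integers(1, 50, size=rng.integers(1, 8))]
            collapsed, hits = _bias_fixture(counts, [])
            got = compute_abundance_bias(make_candidate(), ReadLocusIndex(collapsed, hits))
            top3 = sum(sorted(counts, reverse=True)[:3])
            assert got == pytest.approx(top3 / sum(counts))

    def test_no_reads_rejected(self):
        idx = ReadLocusIndex([], {})
        cand = make_candidate()
        assert compute_strand_bias(cand, idx) is None
        cand.strand_bias = None
        ok, reasons = apply_structure_filters(cand)
        assert not ok and "strand_bias" in reasons


class TestStructureFilters:
    def test_all_boundaries_inclusive_accept(self):
        cand = make_candidate(duplex_mismatches=4, mfe=-30.0, mfei=0.30,
                              amfe=22.0, gc_pct=25.0, strand_bias=0.9,
                              abundance_bias=0.6)
        ok, reasons = apply_structure_filters(cand)
        assert ok and not reasons
        cand = make_candidate(mfei=1.80)
        ok, _ = apply_structure_filters(cand)
        assert ok

    @pytest.mark.parametrize(
        "field,value,reason",
        [
            ("duplex_mismatches", 5, "duplex_mismatches"),
            ("mfe", -29.0, "mfe"),
            ("mfei", 1.81, "mfei"),
            ("mfei", 0.29, "mfei"),
            ("amfe", 21.9, "amfe"),
            ("gc_pct", 24.9, "gc"),
            ("strand_bias", 0.89, "strand_bias"),
            ("abundance_bias", 0.59, "abundance_bias"),
        ],
    )
    def test_each_threshold_rejects_just_past_boundary(self, field, value, reason):
        cand = make_candidate(**{field: value})
        if field == "gc_pct":
            cand.mfei = 1.0  # isolate the gc rule from mfei's definition
        ok, reasons = apply_structure_filters(cand)
        assert not ok and reason in reasons

    def test_reason_codes_enumerate_every_failed_rule(self):
        cand = make_candidate(duplex_mismatches=5, mfe=-10.0, mfei=2.5,
                              amfe=10.0, gc_pct=20.0, strand_bias=0.5,
                              abundance_bias=0.1)
        ok, reasons = apply_structure_filters(cand)
        assert not ok
        assert reasons == {"duplex_mismatches", "mfe", "mfei", "amfe", "gc",
                           "strand_bias", "abundance_bias"}

    def test_filter_monotonicity(self):
        """Tightening any threshold never accepts a previously rejected candidate."""
        cand = make_candidate()
        loose = FilterThresholds()
        tight = FilterThresholds(max_mismatches=1, max_mfe=-40, min_mfei=0.5,
                                 max_mfei=1.2, min_amfe=30, min_gc=40,
                                 min_strand_bias=0.95, min_abundance_bias=0.7)
        ok_loose, _ = apply_structure_filters(cand, loose)
        ok_tight, _ = apply_structure_filters(cand, tight)
        assert ok_loose or not ok_tight


class TestConservation:
    def test_identical_and_boundary_distances(self):
        known = ["ACGGTTGCAGCTGAAGCTGAC"]
        assert classify_conservation(known[0], None, known) == "cs"
        three_mm = "TCGGATGCAGCTGAAGCTGAT"
        assert end_anchored_distance(three_mm, known[0]) == 3
        assert classify_conservation(three_mm, None, known) == "cs"
        four_mm = "TCGGATGCAGCTGAAGCTGGT"
        assert end_anchored_distance(four_mm, known[0]) == 4
        assert classify_conservation(four_mm, None, known) == "ls"

    def test_star_similarity_rescues_cs(self):
        known = ["ACGGTTGCAGCTGAAGCTGAC"]
        mature = "TTTTTTTTTTTTTTTTTTTTT"
        star = "ACGGTTGCAGCTGAAGCTGTC"  # distance 1
        assert classify_conservation(mature, star, known) == "cs"

    def test_length_difference_handled_by_end_alignment(self):
        known = ["ACGGTTGCAGCTGAAGCTGAC"]
        shorter = known[0][:19]  # 2 nt overhang -> distance 2
        assert end_anchored_distance(shorter, known[0]) == 2
        way_short = known[0][:15]
        assert end_anchored_distance(way_short, known[0]) == len(way_short)

    def test_empty_known_set_warns_ls(self):
        assert classify_conservation("ACG" * 7, None, []) == "ls"

    def test_planted_conservation_classes_recovered(self, small_study, small_result):
        expected = {
            h.mature_seq: ("cs" if i % 2 == 0 else "ls")
            for i, h in enumerate(small_study.manifest.planted_hairpins)
        }
        for ann in small_result.discovery.annotations:
            if ann.mature_seq in expected:
                assert ann.conservation == expected[ann.mature_seq]


class TestAbundanceThreshold:
    def test_low_abundance_read_yields_no_candidate(self, backend):
        """A read with total count 9 anchors nothing; 10 anchors a cluster."""
        rng = np.random.default_rng(7)
        from phasiforge.mirna_discovery import extract_precursor_candidates
        contig = Contig("c", "".join(rng.choice(list("ACGT"), size=300)))
        read9 = contig.sequence[100:121]
        collapsed = sra_io.collapse_reads({"l": [read9] * 9})
        hits = {read9: [LocusHit("c", 100, 121, "+")]}
        assert extract_precursor_candidates(collapsed, hits, [contig]) == []
        collapsed = sra_io.collapse_reads({"l": [read9] * 10})
        assert extract_precursor_candidates(collapsed, hits, [contig]) != []
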