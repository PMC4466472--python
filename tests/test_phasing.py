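"""Phasing statistic, window scan, PGT filters and read partitioning."""

import itertools
import math

import numpy as np
import pytest

from phasiforge import sra_io
from phasiforge.phasing_detector import (
    PhasedLocus,
    call_pgts,
    hypergeom_tail,
    partition_reads,
    phasing_scan,
)
from phasiforge.sra_io import LocusHit


def exact_tail(M, m, n, k):
    """Exact rational tail via integer combinatorics (independent of scipy)."""
    if k <= 0:
        return 1.0
    if k > min(m, n):
        return 0.0
    total = math.comb(M, n)
    hits = sum(math.comb(m, j) * math.comb(M - m, n - j)
               for j in range(k, min(m, n) + 1))
    return hits / total


def enumerated_tail(M, m, n, k):
    """Tail by brute-force enumeration of every n-subset placement."""
    if k <= 0:
        return 1.0
    count = 0
    total = 0
    for subset in itertools.combinations(range(M), n):
        total += 1
        if sum(1 for p in subset if p < m) >= k:
            count += 1
    return count / total if total else 1.0


class TestTail:
    def test_empty_occupancy_gives_one(self):
        assert hypergeom_tail(378, 18, 0, 0) == 1.0

    def test_all_in_register_closed_form(self):
        # all n occupied positions in-register with n = m: tail = 1/C(M, m)
        M, m = 42, 4
        assert hypergeom_tail(M, m, m, m) == pytest.approx(1 / math.comb(M, m), rel=1e-12)

    def test_matches_subset_enumeration_small(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            M = int(rng.integers(4, 11))
            m = int(rng.integers(1, M + 1))
            n = int(rng.integers(0, min(M, 6) + 1))
            for k in range(0, n + 1):
                assert hypergeom_tail(M, m, n, k) == pytest.approx(
                    enumerated_tail(M, m, n, k), abs=1e-12
                )

    def test_monotone_nonincreasing_in_k(self):
        vals = [hypergeom_tail(40, 10, 8, k) for k in range(9)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))


def _phased_fixture(n_cycles=8, register=30, cycle=21, contig_len=400,
                    count=20, extra=()):
    """Collapsed reads + hits with a planted sense register."""
    rng = np.random.default_rng(3)
    raw = []
    hits = {}
    seqs = []
    for i in range(n_cycles):
        seq = "".join(rng.choice(list("ACGT"), size=cycle))
        raw.extend([seq] * count)
        hits[seq] = [LocusHit("t", register + cycle * i, register + cycle * i + cycle, "+")]
    for pos, strand, cnt in extra:
        seq = "".join(rng.choice(list("ACGT"), size=cycle))
        raw.extend([seq] * cnt)
        start = pos if strand == "+" else pos - cycle + 1
        hits[seq] = [LocusHit("t", start, start + cycle, strand)]
    reads = sra_io.collapse_reads({"l": raw})
    return reads, hits


class TestScanAndCall:
    def test_planted_register_found_significant(self):
        reads, hits = _phased_fixture()
        ws = phasing_scan(reads, hits, {"t": 400})
        best = min(ws, key=lambda w: w.p_value)
        assert best.register == 30 % 21
        assert best.p_value < 1e-6
        # an all-sense locus fails the default strand-bias rule, so relax it
        pgts = call_pgts(ws, reads, hits, max_strand_bias=1.01)
        assert len(pgts) == 1
        assert pgts[0].register_start == 30

    def test_uniform_occupancy_not_significant(self):
        # positions spread without phase structure
        extra = [(17 * i + 5, "+", 3) for i in range(20)]
        reads, hits = _phased_fixture(n_cycles=0, extra=extra)
        ws = phasing_scan(reads, hits, {"t": 400})
        assert all(w.p_value > 0.01 for w in ws)

    def test_antisense_offset_participates(self):
        # antisense 5' ends at register + 2 mod 21 count as in-register
        extra = [(30 + 21 * i + 2, "-", 20) for i in range(2, 6)]
        reads, hits = _phased_fixture(n_cycles=4, extra=extra)
        ws = phasing_scan(reads, hits, {"t": 400})
        best = min(ws, key=lambda w: w.p_value)
        assert best.k_in_register >= 8

    def test_filter_boundaries(self):
        reads, hits = _phased_fixture(count=20)
        ws = phasing_scan(reads, hits, {"t": 400})
        # the fixtures are all-sense, so the strand-bias rule is relaxed to
        # isolate the abundance and fraction filters
        relaxed = dict(max_strand_bias=1.01)
        # best phased read count 9 < 10 -> rejected
        reads9, hits9 = _phased_fixture(count=9)
        assert call_pgts(phasing_scan(reads9, hits9, {"t": 400}), reads9, hits9,
                         **relaxed) == []
        # count exactly 10 -> retained
        reads10, hits10 = _phased_fixture(count=10)
        assert call_pgts(phasing_scan(reads10, hits10, {"t": 400}), reads10, hits10,
                         **relaxed)
        # phased fraction below half -> rejected
        extra = [(30 + 21 * i + 9, "+", 21) for i in range(8)]
        readsf, hitsf = _phased_fixture(count=20, extra=extra)
        assert call_pgts(phasing_scan(readsf, hitsf, {"t": 400}), readsf, hitsf,
                         **relaxed) == []
        # strand bias 1.0 (all sense) with max_strand_bias=1.01 passes,
        # the default (< 0.9) rejects an all-sense locus
        assert call_pgts(ws, reads, hits, max_strand_bias=1.01)
        assert call_pgts(ws, reads, hits, max_strand_bias=0.9) == []

    def test_short_window_skipped(self):
        reads, hits = _phased_fixture()
        assert phasing_scan(reads, hits, {"t": 50}) == []


class TestPartition:
    def test_modular_arithmetic(self):
        extra = [(30 + 42, "+", 5), (30 + 43, "+", 5), (30 + 23, "-", 5)]
        reads, hits = _phased_fixture(n_cycles=3, extra=extra)
        locus = PhasedLocus(contig_id="t", start=0, end=400, register=30 % 21,
                            register_start=30, cycle_len=21, p_value=0.0, n_windows=1)
        phased, nonphased = partition_reads(locus, reads, hits)
        phased_pos = {(p, s) for p, s, _ in phased}
        assert (30 + 42, "+") in phased_pos  # 42 = 0 mod 21
        assert (30 + 23, "-") in phased_pos  # antisense +2 offset
        assert {(p, s) for p, s, _ in nonphased} == {(30 + 43, "+")}
        assert not {(p, s) for p, s, _ in phased} & {(p, s) for p, s, _ in nonphased}

    def test_low_count_nonphased_dropped(self):
        extra = [(30 + 43, "+", 1)]
        reads, hits = _phased_fixture(n_cycles=3, extra=extra)
        locus = PhasedLocus(contig_id="t", start=0, end=400, register=30 % 21,
                            register_start=30, cycle_len=21, p_value=0.0, n_windows=1)
        _, nonphased = partition_reads(locus, reads, hits)
        assert nonphased == []


class TestCalibration:
    def test_background_window_pvalues_near_uniform(self):
        """Sparse random occupancy yields P(p < a) <= ~a for the corrected p."""
        rng = np.random.default_rng(11)
        n_windows = 3000
        n_sig = {0.05: 0, 0.01: 0}
        M, L = 378, 189
        for _ in range(n_windows):
            n_occ = int(rng.integers(3, 12))
            pos = rng.choice(L, size=n_occ, replace=False)
            strands = rng.random(n_occ) < 0.5
            k_by = {}
            for p, minus in zip(pos, strands):
                c = (p - 2) % 21 if minus else p % 21
                k_by[c] = k_by.get(c, 0) + 1
            k = max(k_by.values())
            p_adj = min(1.0, 21 * hypergeom_tail(M, 18, n_occ, k))
            for a in n_sig:
                if p_adj < a:
                    n_sig[a] += 1
        for a, c in n_sig.items():
            frac = c / n_windows
            assert frac <= a + 2.5 * math.sqrt(a / n_windows), (a, frac)
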