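"""Target-site scoring, trigger prediction and cis/trans classification."""

import numpy as np
import pytest

from phasiforge.phasing_detector import PhasedLocus
from phasiforge.sra_io import revcomp
from phasiforge.target_trigger_network import (
    CandidateSRNA,
    TriggerAssignment,
    build_network,
    classify_cleavage,
    edge_list_tsv,
    predict_triggers,
    score_target,
)

WOBBLE = {("G", "T"), ("T", "G")}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_score(srna, window):
    """Pure-python per-window penalty sum (independent of the vectorised path)."""
    L = len(srna)
    total = 0.0
    for i in range(1, L + 1):  # sRNA position i pairs window base L - i
        s = srna[i - 1]
        t = window[L - i]
        if COMP[s] == t:
            pen = 0.0
        elif (s, t) in WOBBLE:
            pen = 0.5
        else:
            pen = 1.0
        if 2 <= i <= 13:
            pen *= 2.0
        total += pen
    return total


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestScoring:
    def test_perfect_complement_scores_zero(self, rng):
        srna = random_dna(rng, 21)
        transcript = random_dna(rng, 50) + revcomp(srna) + random_dna(rng, 50)
        sites = score_target(srna, transcript, "t")
        best = min(sites, key=lambda s: s.expectation)
        assert best.expectation == 0.0
        assert best.start == 50 and best.end == 71
        assert best.cleavage_pos == 71 - 10

    def test_wobble_penalty_position_dependence(self):
        srna = "A" * 21
        # build a perfect site, then wobble opposite one sRNA position
        site = list(revcomp(srna))  # all T
        # position 15 (outside core): sRNA A->G gives G:T wobble = 0.5
        srna15 = srna[:14] + "G" + srna[15:]
        sites = score_target(srna15, "".join(site), "t", cutoff=10)
        assert sites[0].expectation == pytest.approx(0.5)
        srna5 = srna[:4] + "G" + srna[5:]
        sites = score_target(srna5, "".join(site), "t", cutoff=10)
        assert sites[0].expectation == pytest.approx(1.0)  # doubled in core

    def test_mismatch_double_in_core(self):
        srna = "A" * 21
        site = list(revcomp(srna))
        site[20 - 1] = "G"  # faces sRNA position 2 (core): A vs G mismatch
        sites = score_target(srna, "".join(site), "t", cutoff=10)
        assert sites[0].expectation == pytest.approx(2.0)

    def test_matches_window_oracle_on_random_pairs(self, rng):
        for _ in range(40):
            L = int(rng.integers(18, 25))
            srna = random_dna(rng, L)
            transcript = random_dna(rng, int(rng.integers(L, 120)))
            got = {s.start: s.expectation
                   for s in score_target(srna, transcript, "t", cutoff=1e9)}
            for start in range(len(transcript) - L + 1):
                window = transcript[start:start + L]
                assert got[start] == pytest.approx(oracle_score(srna, window))

    def test_cutoff_excludes_weak_sites(self, rng):
        srna = random_dna(rng, 21)
        transcript = random_dna(rng, 80)
        sites = score_target(srna, transcript, "t", cutoff=3.0)
        assert all(s.expectation <= 3.0 for s in sites)


def _locus(register_start=40, contig="pgt0"):
    return PhasedLocus(contig_id=contig, start=0, end=300, register=register_start % 21,
                       register_start=register_start, cycle_len=21,
                       p_value=1e-9, n_windows=3)


class TestTriggers:
    def test_planted_trigger_in_phase_one_hit(self, rng):
        trigger = random_dna(rng, 21)
        r = 40
        t = random_dna(rng, 300)
        t = t[: r - 11] + revcomp(trigger) + t[r + 10:]
        found = predict_triggers(_locus(r), t, [CandidateSRNA(trigger, "miRNA", "hp0", 50)])
        assert len(found) == 1
        a = found[0]
        assert a.in_phase and a.hit_model == "one_hit"
        assert a.site.cleavage_pos == r

    def test_off_register_site_excluded_at_zero_tolerance(self, rng):
        trigger = random_dna(rng, 21)
        r = 40
        t = random_dna(rng, 300)
        t = t[: r - 10] + revcomp(trigger) + t[r + 11:]  # cleaves at r + 1
        assert predict_triggers(_locus(r), t,
                                [CandidateSRNA(trigger, "miRNA", "hp0", 50)]) == []
        found = predict_triggers(_locus(r), t,
                                 [CandidateSRNA(trigger, "miRNA", "hp0", 50)],
                                 phase_tolerance=1)
        assert len(found) == 1

    def test_unexpressed_candidate_skipped(self, rng):
        trigger = random_dna(rng, 21)
        r = 40
        t = random_dna(rng, 300)
        t = t[: r - 11] + revcomp(trigger) + t[r + 10:]
        assert predict_triggers(_locus(r), t,
                                [CandidateSRNA(trigger, "miRNA", "hp0", 1)]) == []

    def test_no_candidate_under_cutoff_means_untriggered(self, rng):
        t = random_dna(rng, 300)
        found = predict_triggers(_locus(40), t,
                                 [CandidateSRNA(random_dna(rng, 21), "miRNA", "hp0", 50)])
        assert found == []

    def test_two_hit_model_flanking_sites(self, rng):
        trigger = random_dna(rng, 21)
        r = 80
        t = random_dna(rng, 400)
        t = t[: r - 11] + revcomp(trigger) + t[r + 10:]
        d = r + 105  # second site downstream, in phase (105 = 5 * 21)
        t = t[: d - 11] + revcomp(trigger) + t[d + 10:]
        found = predict_triggers(_locus(r), t, [CandidateSRNA(trigger, "miRNA", "hp0", 50)])
        assert found and all(a.hit_model == "two_hit" for a in found)


def _assignment(trigger, cls, pgt_id, cleavage):
    from phasiforge.target_trigger_network import TargetSite
    site = TargetSite(srna=trigger, transcript_id="x", start=0, end=21,
                      expectation=0.0, cleavage_pos=cleavage)
    return TriggerAssignment(trigger=trigger, trigger_class=cls, pgt_id=pgt_id,
                             site=site, in_phase=True, hit_model="one_hit")


class TestCleavageModes:
    transcripts = {"L1": "pgt7", "L2": "pgt7", "L3": "pgt3"}
    registers = {"L1": 40, "L2": 150, "L3": 30}

    def test_sirna_same_pgt_is_cis(self):
        a = _assignment("A" * 21, "pha-siRNA", "L2", 150)
        mode = classify_cleavage(a, {"A" * 21: {"pgt7"}}, self.transcripts, self.registers)
        assert mode == "cis"

    def test_sirna_other_pgt_is_trans(self):
        a = _assignment("A" * 21, "pha-siRNA", "L3", 30)
        mode = classify_cleavage(a, {"A" * 21: {"pgt7"}}, self.transcripts, self.registers)
        assert mode == "trans"

    def test_mirna_setting_register_is_initiator(self):
        a = _assignment("C" * 21, "miRNA", "L1", 40)
        assert classify_cleavage(a, {}, self.transcripts, self.registers) == "initiator"

    def test_mirna_in_phase_downstream_is_trans(self):
        a = _assignment("C" * 21, "miRNA", "L1", 40 + 42)
        assert classify_cleavage(a, {}, self.transcripts, self.registers) == "trans"

    def test_unknown_sirna_origin_errors(self):
        a = _assignment("G" * 21, "nonpha-siRNA", "L1", 40)
        with pytest.raises(ValueError):
            classify_cleavage(a, {}, self.transcripts, self.registers)

    def test_every_assignment_gets_exactly_one_mode(self, default_result):
        assert all(
            a.cleavage_mode in ("initiator", "cis", "trans")
            for a in default_result.assignments
        )


class TestNetwork:
    def test_empty_inputs_empty_graph(self):
        g = build_network([], [], [])
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_initiator_plus_cis_edges(self):
        l2 = _locus(150, "pgt7")
        a1 = _assignment("C" * 21, "miRNA", l2.id, 40)
        a1.cleavage_mode = "initiator"
        a2 = _assignment("A" * 21, "pha-siRNA", l2.id, 150)
        a2.cleavage_mode = "cis"
        g = build_network([], [l2], [a1, a2])
        assert g.number_of_edges() == 2
        assert {d["etype"] for _, _, d in g.edges(data=True)} == {"initiator", "cis"}

    def test_cycle_serializes(self, tmp_path):
        a = _assignment("A" * 21, "pha-siRNA", "A" * 21, 10)  # self-loop target
        a.cleavage_mode = "cis"
        g = build_network([], [], [a])
        text = edge_list_tsv(g)
        assert "cis" in text
        from phasiforge.target_trigger_network import write_graphml
        write_graphml(g, tmp_path / "g.graphml")
        assert (tmp_path / "g.graphml").stat().st_size > 0

    def test_planted_cascade_recovered(self, default_study, default_result):
        """miRNA -> donor PGT -> siRNA -> acceptor PGT paths exist in the graph."""
        g = default_result.network
        trans_regs = [
            (p, r)
            for p in default_study.manifest.planted_pgts
            for r in p.registers if r.expected_mode == "trans"
        ]
        assert trans_regs
        for p, r in trans_regs:
            # the donor PGT's siRNA targets this PGT: edge into a locus on p
            locus_nodes = [n for n, d in g.nodes(data=True)
                           if d.get("kind") == "PGT" and n.startswith(p.contig_id + ":")]
            assert any(
                g.has_edge(r.trigger_seq, ln) and g[r.trigger_seq][ln]["etype"] == "trans"
                for ln in locus_nodes
            )
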