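"""Small-RNA target scoring, PGT trigger prediction and cis/trans networks.

Target sites are scored with the classic plant-target penalty scheme:
mismatch 1.0, G:U wobble 0.5, with penalties doubled at sRNA positions
2-13 from the 5' end (the seed/cleavage core); sites at or below the
expectation cutoff (default 3.0) are reported with the cleavage position
opposite sRNA positions 10/11.  Scoring is over ungapped complementary
windows: a bulged site would incur a 2.0 gap penalty (4.0 in the core),
which already exceeds the remaining slack at the default cutoff, so gapped
alignment buys nothing at cleavage-competent stringency.

A candidate sRNA is a trigger of a phased locus when one of its sites
cleaves in phase with the locus register.  Triggers are classified
initiator (the miRNA/isomiR setting the transcript's primary register),
cis (an siRNA derived from the same PGT acting at another register) or
trans (an sRNA from a different source).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .phasing_detector import PhasedLocus
from .sra_io import revcomp

DEFAULT_CUTOFF = 3.0
CORE_START, CORE_END = 2, 13  # 1-based sRNA positions with doubled penalties

_ENC = np.zeros(128, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
_COMP = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class TargetSite:
    srna: str
    transcript_id: str
    start: int  # site span on the transcript, 0-based half-open
    end: int
    expectation: float
    cleavage_pos: int  # transcript coordinate opposite sRNA positions 10/11


@dataclass
class TriggerAssignment:
    trigger: str
    trigger_class: str  # miRNA | isomiRNA | pha-siRNA | nonpha-siRNA
    pgt_id: str
    site: TargetSite
    in_phase: bool
    hit_model: str  # one_hit | two_hit
    cleavage_mode: str = ""  # initiator | cis | trans


def score_target(
    srna: str,
    transcript: str,
    transcript_id: str = "",
    cutoff: float = DEFAULT_CUTOFF,
) -> list[TargetSite]:
    """All complementary windows of ``transcript`` scoring <= ``cutoff``.

    The sRNA pairs antiparallel: sRNA position i (1-based from its 5' end)
    faces transcript position ``end - i`` of a site ``[start, end)``.
    Cleavage occurs between the bases facing positions 10/11, i.e. the
    downstream fragment starts at ``end - 10``.
    """
    L = len(srna)
    if not 15 <= L <= 30:
        raise ValueError("sRNA length out of plausible range")
    n = len(transcript)
    if n < L:
        return []
    t = _encode(transcript)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    s = _encode(srna)[::-1]  # align sRNA 3'->5' with the site 5'->3'
    expected = _COMP[s][None, :]
    mism = windows != expected
    # wobble: sRNA G facing transcript T, or sRNA T facing transcript G
    wob = ((s[None, :] == 2) & (windows == 3)) | ((s[None, :] == 3) & (windows == 2))
    pen = np.where(mism, np.where(wob, 0.5, 1.0), 0.0)
    # doubled penalties at sRNA positions 2..13 -> site columns L-13 .. L-2
    core = np.zeros(L, dtype=bool)
    for j in range(L):
        if CORE_START <= L - j <= CORE_END:
            core[j] = True
    pen[:, core] *= 2.0
    scores = pen.sum(axis=1)
    out = []
    for start in np.nonzero(scores <= cutoff)[0]:
        start = int(start)
        out.append(
            TargetSite(
                srna=srna, transcript_id=transcript_id,
                start=start, end=start + L,
                expectation=float(scores[start]),
                cleavage_pos=start + L - 10,
            )
        )
    return out


@dataclass(frozen=True)
class CandidateSRNA:
    sequence: str
    srna_class: str  # miRNA | isomiRNA | pha-siRNA | nonpha-siRNA
    origin: str  # annotation id / PGT id the sRNA derives from
    total_count: int = 2


def predict_triggers(
    pgt: PhasedLocus,
    transcript: str,
    candidates: Sequence[CandidateSRNA],
    cutoff: float = DEFAULT_CUTOFF,
    phase_tolerance: int = 0,
    min_count: int = 2,
) -> list[TriggerAssignment]:
    """Candidates with an in-phase cleavage site on the PGT transcript.

    A trigger must itself be expressed (total count >= ``min_count``).
    ``hit_model`` is two_hit when the same sRNA has sites flanking the
    register start, else one_hit.
    """
    out: list[TriggerAssignment] = []
    cyc = pgt.cycle_len
    for cand in candidates:
        if cand.total_count < min_count:
            continue
        sites = score_target(cand.sequence, transcript, pgt.contig_id, cutoff=cutoff)
        in_phase_sites = []
        for site in sites:
            delta = (site.cleavage_pos - pgt.register_start) % cyc
            if min(delta, cyc - delta) <= phase_tolerance:
                in_phase_sites.append(site)
        if not in_phase_sites:
            continue
        # two-hit geometry: one site at/above the register start (the
        # initiating cleavage) plus a second site further downstream
        cleavs = [s.cleavage_pos for s in sites]
        two_hit = min(cleavs) <= pgt.register_start < max(cleavs)
        for site in in_phase_sites:
            out.append(
                TriggerAssignment(
                    trigger=cand.sequence,
                    trigger_class=cand.srna_class,
                    pgt_id=pgt.id,
                    site=site,
                    in_phase=True,
                    hit_model="two_hit" if two_hit else "one_hit",
                )
            )
    return out


def classify_cleavage(
    assignment: TriggerAssignment,
    srna_origins: Mapping[str, set[str]],
    pgt_transcript: Mapping[str, str],
    register_starts: Mapping[str, int],
    tolerance: int = 0,
) -> str:
    """Label one trigger assignment initiator, cis or trans.

    A miRNA/isomiR whose cleavage position coincides with the locus
    register start set that register: initiator.  A miRNA/isomiR acting
    in-phase elsewhere on the locus, or any sRNA from another source, is
    trans; an siRNA derived from the same PGT transcript is cis.

    ``srna_origins``: trigger sequence -> ids of the transcripts/PGTs it
    derives from (empty/missing for miRNAs and isomiRs).
    ``pgt_transcript``: locus id -> transcript (contig) id.
    ``register_starts``: locus id -> 5' position of the first phased read.
    """
    target_transcript = pgt_transcript[assignment.pgt_id]
    if assignment.trigger_class in ("miRNA", "isomiRNA"):
        delta = abs(assignment.site.cleavage_pos - register_starts[assignment.pgt_id])
        mode = "initiator" if delta <= tolerance else "trans"
    else:
        origins = srna_origins.get(assignment.trigger)
        if not origins:
            raise ValueError(f"unknown origin for siRNA trigger {assignment.trigger}")
        mode = "cis" if target_transcript in origins else "trans"
    assignment.cleavage_mode = mode
    return mode


def build_network(
    annotations: Sequence,
    pgts: Sequence[PhasedLocus],
    assignments: Sequence[TriggerAssignment],
    target_sites: Sequence[TargetSite] = (),
) -> nx.DiGraph:
    """Directed sRNA -> transcript graph with typed edges.

    Nodes are sRNA sequences and transcript/locus ids; trigger edges carry
    the cleavage mode, plain target edges the expectation only.  Insertion
    order is sorted so serialisations are deterministic; cycles are allowed
    (regulatory cascades can loop).
    """
    g = nx.DiGraph()
    for a in sorted(annotations, key=lambda a: a.mature_seq):
        g.add_node(a.mature_seq, kind="sRNA", srna_class="miRNA")
    for p in sorted(pgts, key=lambda p: p.id):
        g.add_node(p.id, kind="PGT", register=p.register_start, p_value=p.p_value)
    for t in sorted(target_sites, key=lambda t: (t.srna, t.transcript_id, t.start)):
        if not g.has_node(t.srna):
            g.add_node(t.srna, kind="sRNA", srna_class="sRNA")
        g.add_edge(t.srna, t.transcript_id, etype="target", expectation=t.expectation)
    for a in sorted(assignments, key=lambda a: (a.trigger, a.pgt_id, a.site.start)):
        if not g.has_node(a.trigger):
            g.add_node(a.trigger, kind="sRNA", srna_class=a.trigger_class)
        g.add_edge(
            a.trigger, a.pgt_id,
            etype=a.cleavage_mode or "trigger",
            expectation=a.site.expectation,
            cleavage_pos=a.site.cleavage_pos,
            hit_model=a.hit_model,
        )
    return g


def edge_list_tsv(g: nx.DiGraph) -> str:
    """Deterministic edge-list rendering (source, target, type, attributes)."""
    lines = ["source\ttarget\tetype\texpectation\tcleavage_pos\thit_model"]
    for u, v, d in sorted(g.edges(data=True)):
        lines.append(
            "\t".join(
                [
                    u, v, str(d.get("etype", "")),
                    f"{d.get('expectation', float('nan')):.2f}",
                    str(d.get("cleavage_pos", "")),
                    str(d.get("hit_model", "")),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_graphml(g: nx.DiGraph, path) -> None:
    nx.write_graphml(g, path)
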