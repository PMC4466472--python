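"""miRNA hairpin discovery from mapped small-RNA clusters.

Candidate precursor windows are generated around abundant read loci
(total count >= 10), screened by read-disposition filters, folded with a
thermodynamic backend, and filtered by the standard plant-miRNA annotation
criteria: <= 4 miRNA/miRNA* duplex mismatches, MFE <= -30 kcal/mol, MFEI in
[0.30, 1.80], AMFE >= 22 kcal/mol/100nt, GC >= 25%, single-strand bias
>= 0.9 and abundance bias >= 0.6 (all boundary comparisons inclusive).
Matures are classified as conserved (cs) when they - or their star - sit
within 3 end-anchored mismatches of a known plant miRNA, else
lineage-specific (ls).
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .fold import FoldBackend, default_backend, pair_table
from .sra_io import CollapsedRead, Contig, LocusHit, revcomp

log = logging.getLogger(__name__)

# candidate window flank grid (nt added upstream/downstream of the anchor)
FLANK_GRID = (5, 15, 30, 50, 80, 120, 200, 300, 450)
CLUSTER_GAP = 60  # nt between read loci before a new cluster is opened


@dataclass
class FilterThresholds:
    max_mismatches: int = 4
    max_mfe: float = -30.0
    min_mfei: float = 0.30
    max_mfei: float = 1.80
    min_amfe: float = 22.0
    min_gc: float = 25.0
    min_strand_bias: float = 0.9
    min_abundance_bias: float = 0.6


@dataclass
class HairpinCandidate:
    """A precursor window with fold structure, energetics and bias metrics.

    Window coordinates are on the contig (0-based half-open); mature/star
    coordinates are relative to the precursor sequence (which is the
    reverse complement of the window for minus-strand candidates).
    """

    contig_id: str
    window_start: int
    window_end: int
    strand: str
    precursor_seq: str
    mature_seq: str
    mature_start: int
    mature_end: int
    structure: str | None = None
    mfe: float | None = None
    gc_pct: float | None = None
    amfe: float | None = None
    mfei: float | None = None
    star_seq: str | None = None
    star_start: int | None = None
    star_end: int | None = None
    duplex_mismatches: int | None = None
    strand_bias: float | None = None
    abundance_bias: float | None = None
    reject_reasons: set[str] = field(default_factory=set)

    @property
    def id(self) -> str:
        return f"{self.contig_id}:{self.window_start}-{self.window_end}({self.strand})"


@dataclass
class MiRNAAnnotation:
    mature_seq: str
    precursor_ids: list[str]
    conservation: str  # 'cs' | 'ls'
    family: str | None = None

    @property
    def canonical(self) -> bool:
        """Canonical miRNAs are shorter than 23 nt; 23/24-mers are long miRNAs."""
        return len(self.mature_seq) <= 22


# ---------------------------------------------------------------------------
# Read-locus lookup
# ---------------------------------------------------------------------------

class ReadLocusIndex:
    """Per-contig sorted hit lists for fast window queries.

    Reads are at most ~30 nt, so hits overlapping a window have
    ``start > window_start - max_read_len``; a bisect plus short scan finds
    them.
    """

    def __init__(
        self,
        reads: Sequence[CollapsedRead],
        hits: Mapping[str, Sequence[LocusHit]],
    ):
        by_seq = {r.sequence: r for r in reads}
        self.max_read_len = max((len(r.sequence) for r in reads), default=30)
        table: dict[str, list[tuple[int, int, str, CollapsedRead]]] = {}
        for seq, hlist in hits.items():
            r = by_seq.get(seq)
            if r is None:
                continue
            for h in hlist:
                table.setdefault(h.contig_id, []).append((h.start, h.end, h.strand, r))
        self._table = {cid: sorted(v, key=lambda x: (x[0], x[1], x[2], x[3].sequence))
                       for cid, v in table.items()}
        self._starts = {cid: [x[0] for x in v] for cid, v in self._table.items()}

    def window_reads(
        self, contig_id: str, start: int, end: int
    ) -> list[tuple[int, int, str, CollapsedRead]]:
        items = self._table.get(contig_id, [])
        if not items:
            return []
        lo = bisect_left(self._starts[contig_id], start - self.max_read_len)
        out = []
        for s, e, strand, r in items[lo:]:
            if s >= end:
                break
            if e > start:
                out.append((s, e, strand, r))
        return out


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------

def _cluster_hits(
    items: list[tuple[LocusHit, CollapsedRead]], gap: int = CLUSTER_GAP
) -> list[list[tuple[LocusHit, CollapsedRead]]]:
    """Group hits on one contig into clusters separated by > ``gap`` nt."""
    items = sorted(items, key=lambda x: (x[0].start, x[0].end, x[0].strand, x[1].sequence))
    clusters: list[list[tuple[LocusHit, CollapsedRead]]] = []
    cluster_end = -1
    for hit, read in items:
        if clusters and hit.start <= cluster_end + gap:
            clusters[-1].append((hit, read))
        else:
            clusters.append([(hit, read)])
        cluster_end = max(cluster_end, hit.end)
    return clusters


def extract_precursor_candidates(
    reads: Sequence[CollapsedRead],
    hits: Mapping[str, Sequence[LocusHit]],
    contigs: Sequence[Contig],
    min_abundance: int = 10,
    max_span: int = 450,
    flank_grid: Sequence[int] = FLANK_GRID,
) -> list[HairpinCandidate]:
    """Unfolded candidate windows around abundant read loci.

    For every cluster of qualifying reads (total count >= ``min_abundance``)
    the most abundant read anchors the putative mature; windows extend the
    anchor locus by each flank pair from ``flank_grid``, capped so the
    duplex arms can sit at most ``max_span`` nt apart.
    """
    by_seq = {r.sequence: r for r in reads}
    contig_seq = {c.id: c.sequence for c in contigs}
    per_contig: dict[str, list[tuple[LocusHit, CollapsedRead]]] = {}
    for seq, hlist in hits.items():
        r = by_seq.get(seq)
        if r is None or r.total_count < min_abundance:
            continue
        for h in hlist:
            per_contig.setdefault(h.contig_id, []).append((h, r))

    candidates: list[HairpinCandidate] = []
    for cid in sorted(per_contig):
        cseq = contig_seq[cid]
        for cluster in _cluster_hits(per_contig[cid]):
            anchor_hit, anchor_read = max(
                cluster, key=lambda x: (x[1].total_count, x[1].sequence)
            )
            L = len(anchor_read.sequence)
            seen: set[tuple[int, int]] = set()
            for up in flank_grid:
                for down in flank_grid:
                    if up + down > max_span + L:
                        continue
                    ws = max(0, anchor_hit.start - up)
                    we = min(len(cseq), anchor_hit.end + down)
                    if we - ws < 2 * L + 3 or (ws, we) in seen:
                        continue
                    seen.add((ws, we))
                    window = cseq[ws:we]
                    if anchor_hit.strand == "+":
                        prec = window
                        m_start = anchor_hit.start - ws
                    else:
                        prec = revcomp(window)
                        m_start = we - anchor_hit.end
                    candidates.append(
                        HairpinCandidate(
                            contig_id=cid,
                            window_start=ws,
                            window_end=we,
                            strand=anchor_hit.strand,
                            precursor_seq=prec,
                            mature_seq=anchor_read.sequence,
                            mature_start=m_start,
                            mature_end=m_start + L,
                        )
                    )
    return candidates


# ---------------------------------------------------------------------------
# Folding and metric computation
# ---------------------------------------------------------------------------

_SHIFT_ORDER = (0, 1, -1, 2, -2, 3, -3)


def fold_and_score(
    candidate: HairpinCandidate,
    backend: FoldBackend | None = None,
    shift: int = 3,
    max_span: int = 450,
) -> HairpinCandidate | None:
    """Fold the window and fill structure, energetics and duplex metrics.

    The mature placement may shift up to ``shift`` nt from the anchor read
    locus; the placement minimising duplex mismatches wins (ties: smaller
    shift).  G:U wobbles count as pairs; each unpaired mature base (mismatch
    or asymmetric bulge) counts one mismatch.  Returns None when no arm-like
    placement exists (mature mostly unpaired, arms overlapping, or arms
    > ``max_span`` apart).
    """
    backend = backend or default_backend()
    try:
        structure, mfe = backend.fold(candidate.precursor_seq)
    except Exception as exc:  # pragma: no cover - backend failure path
        log.warning("folding failed for %s: %s", candidate.id, exc)
        return None
    pt = pair_table(structure)
    L = len(candidate.mature_seq)
    n = len(candidate.precursor_seq)

    best: tuple[int, int, int, int] | None = None  # (mismatches, |shift|, star_lo, star_hi)
    best_span = (candidate.mature_start, candidate.mature_end)
    for s in _SHIFT_ORDER:
        if abs(s) > shift:
            continue
        a, b = candidate.mature_start + s, candidate.mature_end + s
        if a < 0 or b > n:
            continue
        partners = [pt[i] for i in range(a, b) if pt[i] != -1]
        if len(partners) < L - 4:  # too few pairs to form a scorable duplex
            continue
        lo, hi = min(partners), max(partners) + 1
        if not (hi <= a or lo >= b):  # arms must be disjoint
            continue
        gap = a - hi if lo < a else lo - b
        if gap < 3 or gap > max_span:
            continue
        in_star = sum(1 for i in range(a, b) if lo <= pt[i] < hi)
        mismatches = L - in_star
        if best is None or (mismatches, abs(s)) < (best[0], best[1]):
            best = (mismatches, abs(s), lo, hi)
            best_span = (a, b)
    if best is None:
        return None

    mismatches, _, lo, hi = best
    a, b = best_span
    candidate.structure = structure
    candidate.mfe = mfe
    # the annotated mature stays the sequenced anchor read; the (possibly
    # shifted) coordinates describe the duplex placement used for scoring
    candidate.mature_start, candidate.mature_end = a, b
    candidate.star_start, candidate.star_end = lo, hi
    candidate.star_seq = candidate.precursor_seq[lo:hi]
    candidate.duplex_mismatches = mismatches
    candidate.gc_pct = 100.0 * (
        candidate.precursor_seq.count("G") + candidate.precursor_seq.count("C")
    ) / n
    candidate.amfe = -mfe / n * 100.0
    candidate.mfei = candidate.amfe / candidate.gc_pct if candidate.gc_pct else float("inf")
    return candidate


# ---------------------------------------------------------------------------
# Bias metrics
# ---------------------------------------------------------------------------

def compute_strand_bias(candidate: HairpinCandidate, index: ReadLocusIndex) -> float | None:
    """Sense-strand read fraction over the precursor window (None if no reads)."""
    sense = anti = 0
    for _, _, strand, r in index.window_reads(
        candidate.contig_id, candidate.window_start, candidate.window_end
    ):
        if strand == candidate.strand:
            sense += r.total_count
        else:
            anti += r.total_count
    if sense + anti == 0:
        return None
    return sense / (sense + anti)


def compute_abundance_bias(candidate: HairpinCandidate, index: ReadLocusIndex) -> float | None:
    """Count share of the three most abundant distinct reads at the locus."""
    per_seq: dict[str, int] = {}
    for _, _, _, r in index.window_reads(
        candidate.contig_id, candidate.window_start, candidate.window_end
    ):
        per_seq[r.sequence] = r.total_count
    counts = sorted(per_seq.values(), reverse=True)
    total = sum(counts)
    if total == 0:
        return None
    return sum(counts[:3]) / total


# ---------------------------------------------------------------------------
# Filters and conservation
# ---------------------------------------------------------------------------

def apply_structure_filters(
    candidate: HairpinCandidate, thresholds: FilterThresholds | None = None
) -> tuple[bool, set[str]]:
    """Accept/reject with exhaustive reason codes (inclusive boundaries)."""
    t = thresholds or FilterThresholds()
    reasons: set[str] = set()
    if candidate.duplex_mismatches is None:
        reasons.add("unevaluated")
        candidate.reject_reasons = reasons
        return False, reasons
    if candidate.duplex_mismatches > t.max_mismatches:
        reasons.add("duplex_mismatches")
    if candidate.mfe > t.max_mfe:
        reasons.add("mfe")
    if not (t.min_mfei <= candidate.mfei <= t.max_mfei):
        reasons.add("mfei")
    if candidate.amfe < t.min_amfe:
        reasons.add("amfe")
    if candidate.gc_pct < t.min_gc:
        reasons.add("gc")
    if candidate.strand_bias is None or candidate.strand_bias < t.min_strand_bias:
        reasons.add("strand_bias")
    if candidate.abundance_bias is None or candidate.abundance_bias < t.min_abundance_bias:
        reasons.add("abundance_bias")
    candidate.reject_reasons = reasons
    return not reasons, reasons


def end_anchored_distance(query: str, known: str, max_len_diff: int = 3) -> int:
    """Best ungapped end-alignment distance.

    The query slides over the known sequence at offsets up to
    ``max_len_diff``; the distance of one alignment is the Hamming distance
    over the overlap plus one per overhanging base.  Ties break toward the
    smaller offset magnitude.
    """
    if abs(len(query) - len(known)) > max_len_diff:
        return len(query)
    best = len(query)
    for off in sorted(range(-max_len_diff, max_len_diff + 1), key=abs):
        lo = max(0, off)
        hi = min(len(known), off + len(query))
        if hi <= lo:
            continue
        overlap = hi - lo
        mism = sum(1 for i in range(lo, hi) if known[i] != query[i - off])
        overhang = (len(query) - overlap) + (len(known) - overlap)
        best = min(best, mism + overhang)
    return best


def classify_conservation(
    mature: str,
    star: str | None,
    known_mirnas: Sequence[str],
    max_mismatches: int = 3,
) -> str:
    """'cs' when mature (or star) is within ``max_mismatches`` of a known miRNA."""
    if not known_mirnas:
        log.warning("empty known-miRNA set: all matures classified lineage-specific")
        return "ls"
    for probe in filter(None, (mature, star)):
        for k in known_mirnas:
            if end_anchored_distance(probe, k) <= max_mismatches:
                return "cs"
    return "ls"


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryResult:
    annotations: list[MiRNAAnnotation]
    accepted: list[HairpinCandidate]
    rejected: list[HairpinCandidate]

    def mirna_loci(self) -> dict[str, list[tuple[int, int]]]:
        """Accepted precursor windows per contig (for read exclusion downstream)."""
        loci: dict[str, list[tuple[int, int]]] = {}
        for c in self.accepted:
            loci.setdefault(c.contig_id, []).append((c.window_start, c.window_end))
        return loci


def discover_mirnas(
    reads: Sequence[CollapsedRead],
    hits: Mapping[str, Sequence[LocusHit]],
    contigs: Sequence[Contig],
    known_mirnas: Sequence[str] = (),
    backend: FoldBackend | None = None,
    thresholds: FilterThresholds | None = None,
    min_abundance: int = 10,
    shift: int = 3,
    max_span: int = 450,
) -> DiscoveryResult:
    """End-to-end hairpin discovery: windows -> bias screen -> fold -> filters.

    The (cheap) strand/abundance bias filters run before folding, so loci
    that can never qualify (e.g. phased-siRNA regions with two-strand read
    coverage) skip the expensive structure evaluation.  For each anchor the
    best accepted window (fewest duplex mismatches, then shortest precursor)
    is retained; matures occurring in several precursors aggregate into one
    annotation.
    """
    backend = backend or default_backend()
    thresholds = thresholds or FilterThresholds()
    index = ReadLocusIndex(reads, hits)
    raw = extract_precursor_candidates(
        reads, hits, contigs, min_abundance=min_abundance, max_span=max_span
    )
    by_anchor: dict[tuple, list[HairpinCandidate]] = {}
    rejected: list[HairpinCandidate] = []
    for cand in raw:
        cand.strand_bias = compute_strand_bias(cand, index)
        cand.abundance_bias = compute_abundance_bias(cand, index)
        if (
            cand.strand_bias is None
            or cand.strand_bias < thresholds.min_strand_bias
            or cand.abundance_bias < thresholds.min_abundance_bias
        ):
            apply_structure_filters(cand, thresholds)
            rejected.append(cand)
            continue
        scored = fold_and_score(cand, backend=backend, shift=shift, max_span=max_span)
        if scored is None:
            continue
        ok, _ = apply_structure_filters(scored, thresholds)
        key = (scored.contig_id, scored.strand, scored.mature_seq)
        if ok:
            by_anchor.setdefault(key, []).append(scored)
        else:
            rejected.append(scored)

    accepted: list[HairpinCandidate] = []
    for key in sorted(by_anchor):
        group = by_anchor[key]
        group.sort(
            key=lambda c: (
                c.duplex_mismatches,
                c.window_end - c.window_start,
                c.window_start,
            )
        )
        accepted.append(group[0])

    ann: dict[str, MiRNAAnnotation] = {}
    for c in accepted:
        a = ann.get(c.mature_seq)
        if a is None:
            conservation = classify_conservation(c.mature_seq, c.star_seq, known_mirnas)
            ann[c.mature_seq] = MiRNAAnnotation(
                mature_seq=c.mature_seq, precursor_ids=[c.id], conservation=conservation
            )
        else:
            a.precursor_ids.append(c.id)
    return DiscoveryResult(
        annotations=[ann[k] for k in sorted(ann)],
        accepted=accepted,
        rejected=rejected,
    )
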