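"""Phased-siRNA locus (PGT) detection via a hypergeometric phasing statistic.

Sliding windows over each reference sequence are scored for 21-nt phase
structure: of the M = 2 x window_len candidate 5' positions (both strands,
antisense carrying the +2 nt offset of the DCL 2-nt 3' overhang), m fall in
a given phase register.  With n distinct occupied positions of which k are
in-register, the per-register score is the hypergeometric tail
P(X >= k | M, m, n).  Occupancy is binary - abundance enters only through
the locus filters (a phased read with total count >= 10; phased fraction
>= 50%; strand bias < 0.9).

Because the register maximising k is selected per window, the reported
window p-value is Bonferroni-corrected for the number of registers tested;
the uncorrected tail is exposed as ``hypergeom_tail`` and on each window as
``p_register``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from .sra_io import CollapsedRead, LocusHit

DEFAULT_CYCLE = 21
DEFAULT_WINDOW_CYCLES = 9


def hypergeom_tail(M: int, m: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M, m, n); k <= 0 gives 1."""
    if k <= 0:
        return 1.0
    if k > min(m, n):
        return 0.0
    return float(hypergeom.sf(k - 1, M, m, n))


@dataclass
class WindowScore:
    contig_id: str
    start: int
    end: int
    register: int  # absolute phase class: in-register sense pos % cycle
    cycle_len: int
    n_occupied: int
    k_in_register: int
    m_slots: int
    M_positions: int
    p_register: float  # uncorrected hypergeometric tail for this register
    p_value: float  # register-selection corrected (x cycle_len, capped at 1)


@dataclass
class PhasedLocus:
    """A called PGT locus with its register and read partition."""

    contig_id: str
    start: int
    end: int
    register: int  # phase class modulo cycle_len
    register_start: int  # 5' position of the first phased read in the locus
    cycle_len: int
    p_value: float
    n_windows: int
    phased_reads: list[tuple[int, str, CollapsedRead]] = field(default_factory=list)
    nonphased_reads: list[tuple[int, str, CollapsedRead]] = field(default_factory=list)
    phased_fraction: float = 0.0
    strand_bias: float = 0.0

    @property
    def id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}/r{self.register}"


def _position_map(
    reads: Sequence[CollapsedRead],
    hits: Mapping[str, Sequence[LocusHit]],
) -> dict[str, dict[tuple[int, str], list[CollapsedRead]]]:
    """contig -> (5' position, strand) -> reads whose 5' end sits there."""
    by_seq = {r.sequence: r for r in reads}
    out: dict[str, dict[tuple[int, str], list[CollapsedRead]]] = {}
    for seq, hlist in hits.items():
        r = by_seq.get(seq)
        if r is None:
            continue
        for h in hlist:
            out.setdefault(h.contig_id, {}).setdefault((h.five_prime, h.strand), []).append(r)
    return out


def _phase_class(pos: int, strand: str, cycle: int) -> int:
    """Absolute phase class of a 5' position (antisense carries +2 offset)."""
    return pos % cycle if strand == "+" else (pos - 2) % cycle


def phasing_scan(
    reads: Sequence[CollapsedRead],
    hits: Mapping[str, Sequence[LocusHit]],
    contig_lengths: Mapping[str, int],
    cycle: int = DEFAULT_CYCLE,
    window_cycles: int = DEFAULT_WINDOW_CYCLES,
    step: int | None = None,
) -> list[WindowScore]:
    """Score sliding windows for phase structure.

    ``reads`` should already exclude miRNA-locus reads and carry total
    count >= 2 (the caller applies both).  Windows shorter than 3 cycles
    (at contig ends) are skipped.
    """
    window_len = cycle * window_cycles
    step = step or cycle
    posmap = _position_map(reads, hits)
    scores: list[WindowScore] = []
    for cid in sorted(posmap):
        positions = sorted(posmap[cid])
        clen = contig_lengths[cid]
        if not positions:
            continue
        for w in range(0, max(1, clen - 3 * cycle + 1), step):
            end = min(w + window_len, clen)
            if end - w < 3 * cycle:
                continue
            L = end - w
            occupied = [(p, s) for (p, s) in positions if w <= p < end]
            n = len(occupied)
            M = 2 * L
            # in-register slot count per strand for this window length
            k_by_class: dict[int, int] = {}
            for p, s in occupied:
                c = _phase_class(p, s, cycle)
                k_by_class[c] = k_by_class.get(c, 0) + 1
            if not k_by_class:
                best_class, k = w % cycle, 0
            else:
                best_class, k = min(
                    k_by_class.items(), key=lambda item: (-item[1], item[0])
                )
            m = 2 * ((L + cycle - 1) // cycle)  # sense + antisense slots per register
            p_reg = hypergeom_tail(M, m, n, k)
            p_adj = min(1.0, p_reg * cycle)
            scores.append(
                WindowScore(
                    contig_id=cid, start=w, end=end, register=best_class,
                    cycle_len=cycle, n_occupied=n, k_in_register=k,
                    m_slots=m, M_positions=M, p_register=p_reg, p_value=p_adj,
                )
            )
    return scores


def _merge_windows(
    windows: Iterable[WindowScore],
) -> list[tuple[str, int, int, int, float, int]]:
    """Merge overlapping significant windows sharing a register.

    Returns (contig, start, end, register, min_p, n_windows) per locus.
    """
    loci: list[tuple[str, int, int, int, float, int]] = []
    by_key: dict[tuple[str, int], list[WindowScore]] = {}
    for ws in windows:
        by_key.setdefault((ws.contig_id, ws.register), []).append(ws)
    for (cid, reg), group in sorted(by_key.items()):
        group.sort(key=lambda ws: ws.start)
        cur_start, cur_end, cur_p, cur_n = group[0].start, group[0].end, group[0].p_value, 1
        for ws in group[1:]:
            if ws.start <= cur_end:
                cur_end = max(cur_end, ws.end)
                cur_p = min(cur_p, ws.p_value)
                cur_n += 1
            else:
                loci.append((cid, cur_start, cur_end, reg, cur_p, cur_n))
                cur_start, cur_end, cur_p, cur_n = ws.start, ws.end, ws.p_value, 1
        loci.append((cid, cur_start, cur_end, reg, cur_p, cur_n))
    return loci


def partition_reads(
    locus: PhasedLocus,
    reads: Sequence[CollapsedRead],
    hits: Mapping[str, Sequence[LocusHit]],
    min_nonphased_count: int = 2,
) -> tuple[list[tuple[int, str, CollapsedRead]], list[tuple[int, str, CollapsedRead]]]:
    """Split locus reads into phased and non-phased sets (disjoint).

    A read is phased when its 5' position matches the locus register
    (antisense with the +2 offset); any other locus read with total count
    >= ``min_nonphased_count`` is non-phased.
    """
    posmap = _position_map(reads, hits)
    phased: list[tuple[int, str, CollapsedRead]] = []
    nonphased: list[tuple[int, str, CollapsedRead]] = []
    for (pos, strand), rs in sorted(posmap.get(locus.contig_id, {}).items()):
        if not (locus.start <= pos < locus.end):
            continue
        in_reg = _phase_class(pos, strand, locus.cycle_len) == locus.register
        for r in rs:
            if in_reg:
                phased.append((pos, strand, r))
            elif r.total_count >= min_nonphased_count:
                nonphased.append((pos, strand, r))
    return phased, nonphased


def call_pgts(
    window_scores: Sequence[WindowScore],
    reads: Sequence[CollapsedRead],
    hits: Mapping[str, Sequence[LocusHit]],
    p_cut: float = 0.01,
    min_pha_reads: int = 10,
    min_pha_frac: float = 0.5,
    max_strand_bias: float = 0.9,
) -> list[PhasedLocus]:
    """Apply the PGT filters to significant windows and build loci.

    Retained iff p < ``p_cut`` AND at least one phased read has total count
    >= ``min_pha_reads`` AND the phased count fraction is >= ``min_pha_frac``
    AND sense-strand bias < ``max_strand_bias``.
    """
    significant = [ws for ws in window_scores if ws.p_value < p_cut]
    out: list[PhasedLocus] = []
    for cid, start, end, reg, p, nwin in _merge_windows(significant):
        locus = PhasedLocus(
            contig_id=cid, start=start, end=end, register=reg,
            register_start=start, cycle_len=significant[0].cycle_len,
            p_value=p, n_windows=nwin,
        )
        phased, nonphased = partition_reads(locus, reads, hits)
        if not phased:
            continue
        locus.phased_reads = phased
        locus.nonphased_reads = nonphased
        locus.register_start = min(
            (pos for pos, s, _ in phased if s == "+"),
            default=min(pos for pos, _, _ in phased),
        )
        pha_counts = sum(r.total_count for _, _, r in phased)
        non_counts = sum(r.total_count for _, _, r in nonphased)
        total = pha_counts + non_counts
        locus.phased_fraction = pha_counts / total if total else 0.0
        sense = sum(r.total_count for _, s, r in phased + nonphased if s == "+")
        locus.strand_bias = sense / total if total else 0.0
        if max(r.total_count for _, _, r in phased) < min_pha_reads:
            continue
        if locus.phased_fraction < min_pha_frac:
            continue
        if locus.strand_bias >= max_strand_bias:
            continue
        out.append(locus)
    return out
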