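"""Classification of miRNA end-variants (isomiRs).

Reads deriving from an accepted miRNA locus that are not the annotated
mature or star are isomiRs, classified by which ends differ from the
canonical mature: 5'-end variants, 3'-end variants, or both-end variants.
Only templated variants are considered (the read must map within the
precursor); offsets beyond +/-5 nt mark a read as an unrelated locus read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .mirna_discovery import HairpinCandidate
from .sra_io import CollapsedRead, LocusHit

MAX_OFFSET = 5
LENGTH_RANGE = range(17, 28)


@dataclass
class IsomiR:
    sequence: str
    parent: str  # mature sequence of the parent annotation
    variant_class: str  # five_prime | three_prime | both
    offset5: int
    offset3: int
    from_star: bool = False
    source_precursors: list[str] = field(default_factory=list)


def classify_offsets(offset5: int, offset3: int) -> str | None:
    """Variant class from end offsets; (0, 0) is the mature itself."""
    if offset5 == 0 and offset3 == 0:
        return None
    if offset5 != 0 and offset3 != 0:
        return "both"
    return "five_prime" if offset5 != 0 else "three_prime"


def classify_isomir(
    read: CollapsedRead,
    hit: LocusHit,
    precursor: HairpinCandidate,
    max_offset: int = MAX_OFFSET,
) -> IsomiR | None:
    """Classify one read mapped inside an accepted precursor window.

    Offsets are computed against the canonical mature (or star, for
    star-arm reads) in precursor orientation.  Returns None for the mature
    and star themselves, for opposite-strand reads, and for reads outside
    either arm neighbourhood (loop/other reads, tallied by the caller).
    """
    if hit.strand != precursor.strand:
        return None
    # read span in precursor-relative coordinates
    if precursor.strand == "+":
        r_start = hit.start - precursor.window_start
    else:
        r_start = precursor.window_end - hit.end
    r_end = r_start + len(read.sequence)

    for arm_start, arm_end, parent, from_star in (
        (precursor.mature_start, precursor.mature_end, precursor.mature_seq, False),
        (precursor.star_start, precursor.star_end, precursor.star_seq, True),
    ):
        if arm_start is None:
            continue
        o5 = r_start - arm_start
        o3 = r_end - arm_end
        if abs(o5) > max_offset or abs(o3) > max_offset:
            continue
        cls = classify_offsets(o5, o3)
        if cls is None:
            return None  # the annotated mature (or star) itself
        return IsomiR(
            sequence=read.sequence, parent=parent, variant_class=cls,
            offset5=o5, offset3=o3, from_star=from_star,
        )
    return None


def attribute_multilocus(
    isomir: IsomiR, precursors: Sequence[HairpinCandidate]
) -> list[str]:
    """All precursors whose sequence contains the isomiR (sorted ids)."""
    ids = sorted(
        p.id for p in precursors if isomir.sequence in p.precursor_seq
    )
    isomir.source_precursors = ids
    return ids


def collect_isomirs(
    reads: Sequence[CollapsedRead],
    hits: dict[str, Sequence[LocusHit]],
    precursors: Sequence[HairpinCandidate],
    max_offset: int = MAX_OFFSET,
) -> tuple[list[IsomiR], int]:
    """Classify every read overlapping an accepted precursor window.

    Returns (isomiRs, n_other): ``n_other`` counts locus reads that fall in
    the loop or beyond the offset bound.  A read identical to a mature/star
    is never an isomiR; a read classified at one precursor is attributed to
    every precursor containing it.
    """
    by_window: dict[str, list[HairpinCandidate]] = {}
    for p in precursors:
        by_window.setdefault(p.contig_id, []).append(p)
    matures = {p.mature_seq for p in precursors}
    stars = {p.star_seq for p in precursors if p.star_seq}
    seen: dict[str, IsomiR] = {}
    n_other = 0
    for r in sorted(reads, key=lambda r: r.sequence):
        if r.sequence in matures or r.sequence in stars or r.sequence in seen:
            continue
        for h in hits.get(r.sequence, ()):
            found = False
            for p in by_window.get(h.contig_id, []):
                if h.start >= p.window_end or h.end <= p.window_start:
                    continue
                iso = classify_isomir(r, h, p, max_offset=max_offset)
                if iso is not None:
                    attribute_multilocus(iso, precursors)
                    seen[r.sequence] = iso
                    found = True
                    break
                n_other += 1
            if found:
                break
    return list(seen.values()), n_other


def summarize_isomirs(
    isomirs: Iterable[IsomiR],
    rpm: dict[str, float],
    min_rpm: float = 10.0,
) -> pd.DataFrame:
    """Length x variant-class abundance table (all + high-expression panel).

    For every length 17-27 and class: isomiR count, summed RPM and mean
    RPM per isomiR, plus the same columns restricted to isomiRs at or above
    ``min_rpm``.
    """
    rows = []
    items = [(iso, rpm.get(iso.sequence, 0.0)) for iso in isomirs]
    for length in LENGTH_RANGE:
        for cls in ("five_prime", "three_prime", "both"):
            sub = [r for iso, r in items
                   if len(iso.sequence) == length and iso.variant_class == cls]
            hi = [r for r in sub if r >= min_rpm]
            rows.append(
                {
                    "length": length,
                    "variant_class": cls,
                    "n": len(sub),
                    "rpm_sum": sum(sub),
                    "rpm_mean": sum(sub) / len(sub) if sub else 0.0,
                    "n_hi": len(hi),
                    "rpm_sum_hi": sum(hi),
                    "rpm_mean_hi": sum(hi) / len(hi) if hi else 0.0,
                }
            )
    return pd.DataFrame(rows)
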