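"""Small-RNA library IO: read collapsing, length filtering, exact mapping, RPM.

Libraries arrive either as raw read FASTA/FASTQ (one record per sequenced
read) or as a collapsed-read FASTA dialect ``>seq<serial>_x<count>``.  All
sequences are normalised to DNA uppercase (U -> T).  Coordinates are 0-based
half-open throughout the package; the GFF3 writer converts to 1-based closed
on output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MIN_LEN = 18
MAX_LEN = 26


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


@dataclass
class CollapsedRead:
    """A unique small-RNA sequence with per-library counts and RPM."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)
    rpm: dict[str, float] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def total_rpm(self) -> float:
        return sum(self.rpm.values())

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class Contig:
    """A reference sequence (genome contig or EST/transcript)."""

    id: str
    sequence: str


@dataclass(frozen=True, order=True)
class LocusHit:
    """A perfect-match placement of a read on the reference.

    ``start``/``end`` are 0-based half-open on the forward strand of the
    contig; ``end - start`` equals the read length.  For a minus-strand hit
    the read equals the reverse complement of ``contig[start:end]`` and its
    5' nucleotide sits at ``end - 1``.
    """

    contig_id: str
    start: int
    end: int
    strand: str

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def collapse_reads(raw_reads: Mapping[str, Iterable[str]]) -> list[CollapsedRead]:
    """Collapse per-library raw reads into unique sequences with counts.

    Sequences containing non-ACGT characters (after U->T normalisation) are
    rejected with a logged warning.  Output order is lexicographic by
    sequence, so identical inputs yield identical output.
    """
    table: dict[str, dict[str, int]] = {}
    n_rejected = 0
    for lib_id, reads in raw_reads.items():
        for raw in reads:
            seq = normalize_seq(raw)
            if not seq or not VALID_BASES.issuperset(seq):
                n_rejected += 1
                continue
            counts = table.setdefault(seq, {})
            counts[lib_id] = counts.get(lib_id, 0) + 1
    if n_rejected:
        log.warning("collapse_reads: rejected %d reads with non-ACGT characters", n_rejected)
    return [CollapsedRead(seq, table[seq]) for seq in sorted(table)]


def length_filter(
    reads: Sequence[CollapsedRead], min_len: int = MIN_LEN, max_len: int = MAX_LEN
) -> list[CollapsedRead]:
    """Keep reads with min_len <= length <= max_len (counts untouched)."""
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    return [r for r in reads if min_len <= len(r.sequence) <= max_len]


class ReferenceIndex:
    """Exact-match index over both strands of a contig set.

    A seed dictionary over fixed-length prefixes (default 18 nt, the minimum
    retained read length) maps to candidate forward-strand placements; a full
    string comparison verifies each candidate, so N in the reference never
    matches any read base.
    """

    def __init__(self, contigs: Sequence[Contig], seed_len: int = MIN_LEN):
        self.seed_len = seed_len
        self.contigs: dict[str, str] = {c.id: c.sequence for c in contigs}
        if len(self.contigs) != len(contigs):
            raise ValueError("duplicate contig ids")
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for c in contigs:
            seq = c.sequence.upper()
            for i in range(len(seq) - seed_len + 1):
                seed = seq[i : i + seed_len]
                self._seeds.setdefault(seed, []).append((c.id, i))

    def _forward_hits(self, query: str) -> list[tuple[str, int]]:
        out = []
        for cid, i in self._seeds.get(query[: self.seed_len], ()):
            if self.contigs[cid][i : i + len(query)] == query:
                out.append((cid, i))
        return out

    def find(self, read: str) -> list[LocusHit]:
        """All perfect-match loci of ``read``, sorted (contig_id, start, strand)."""
        if len(read) < self.seed_len:
            raise ValueError(f"read shorter than index seed length {self.seed_len}")
        hits = [LocusHit(cid, i, i + len(read), "+") for cid, i in self._forward_hits(read)]
        hits += [
            LocusHit(cid, i, i + len(read), "-")
            for cid, i in self._forward_hits(revcomp(read))
        ]
        return sorted(hits)


def build_index(contigs: Sequence[Contig], seed_len: int = MIN_LEN) -> ReferenceIndex:
    return ReferenceIndex(contigs, seed_len=seed_len)


@dataclass
class MappingResult:
    """Per-sequence perfect-match loci plus exclusion bookkeeping."""

    hits: dict[str, list[LocusHit]]
    hyper_repetitive: set[str]
    unmapped: set[str]

    def mapped_sequences(self) -> list[str]:
        return sorted(self.hits)


def map_exact(read: str, index: ReferenceIndex, max_loci: int = 500) -> list[LocusHit]:
    """Perfect-match loci of one read; empty if none or if > max_loci (hyper-repetitive)."""
    hits = index.find(read)
    if len(hits) > max_loci:
        return []
    return hits


def map_reads(
    reads: Sequence[CollapsedRead], index: ReferenceIndex, max_loci: int = 500
) -> MappingResult:
    """Map every collapsed read; flag hyper-repetitive (> max_loci) and unmapped."""
    hits: dict[str, list[LocusHit]] = {}
    hyper: set[str] = set()
    unmapped: set[str] = set()
    for r in reads:
        h = index.find(r.sequence)
        if not h:
            unmapped.add(r.sequence)
        elif len(h) > max_loci:
            hyper.add(r.sequence)
        else:
            hits[r.sequence] = h
    return MappingResult(hits=hits, hyper_repetitive=hyper, unmapped=unmapped)


def rpm_normalize(
    reads: Sequence[CollapsedRead], library_totals: Mapping[str, int]
) -> list[CollapsedRead]:
    """Populate per-library RPM = count * 1e6 / library_total (in place; returns reads)."""
    for lib, total in library_totals.items():
        if total <= 0:
            raise ValueError(f"library total for {lib!r} must be positive, got {total}")
    for r in reads:
        r.rpm = {
            lib: r.counts.get(lib, 0) * 1e6 / library_totals[lib] for lib in library_totals
        }
    return list(reads)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Contig]:
    return [Contig(rec.id, normalize_seq(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_library(path: str | Path, fmt: str | None = None) -> list[str]:
    """Read one library of raw reads (FASTA or FASTQ, by extension).

    The collapsed-read dialect ``>seq<serial>_x<count>`` is expanded back to
    raw reads so downstream counting is uniform.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    reads: list[str] = []
    for rec in SeqIO.parse(str(path), fmt):
        seq = normalize_seq(str(rec.seq))
        mult = 1
        if fmt == "fasta" and "_x" in rec.id:
            tail = rec.id.rsplit("_x", 1)[1]
            if tail.isdigit():
                mult = int(tail)
        reads.extend([seq] * mult)
    return reads


def write_collapsed_fasta(reads: Sequence[CollapsedRead], path: str | Path) -> None:
    """Write the collapsed dialect ``>seq<serial>_x<total_count>``."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads, start=1):
            fh.write(f">seq{i}_x{r.total_count}\n{r.sequence}\n")


def write_counts_tsv(
    reads: Sequence[CollapsedRead], libraries: Sequence[str], path: str | Path
) -> None:
    """Sidecar TSV: sequence, per-library counts, per-library RPM."""
    with open(path, "w") as fh:
        cols = ["sequence"] + [f"count_{l}" for l in libraries] + [f"rpm_{l}" for l in libraries]
        fh.write("\t".join(cols) + "\n")
        for r in reads:
            row = [r.sequence]
            row += [str(r.counts.get(l, 0)) for l in libraries]
            row += [f"{r.rpm.get(l, 0.0):.4f}" for l in libraries]
            fh.write("\t".join(row) + "\n")


def gff3_records(
    features: Iterable[tuple[str, str, int, int, str, str, dict[str, str]]],
    source: str = "phasiforge",
) -> str:
    """Render (contig, type, start0, end0, strand, score, attrs) as GFF3 text.

    Internal 0-based half-open coordinates are converted to GFF3 1-based
    closed on the way out.
    """
    lines = ["##gff-version 3"]
    for contig, ftype, start0, end0, strand, score, attrs in features:
        attr_str = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
        lines.append(
            "\t".join(
                [contig, source, ftype, str(start0 + 1), str(end0), score, strand, ".", attr_str]
            )
        )
    return "\n".join(lines) + "\n"
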