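"""Pipeline orchestration: simulate -> map -> mirna -> isomir -> phase ->
network -> de, with per-stage outputs, caching and a summary report.

``analyze`` is the in-memory engine used by tests and scripts; ``run_all``
wraps it with file IO under a run directory.  Stage outputs carry no
timestamps, so identical configs and seeds reproduce runs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import sra_io
from .diff_expression import DEThresholds, differential_expression
from .fold import FoldBackend, default_backend
from .isomir_classifier import IsomiR, collect_isomirs, summarize_isomirs
from .mirna_discovery import DiscoveryResult, FilterThresholds, discover_mirnas
from .phasing_detector import PhasedLocus, WindowScore, call_pgts, phasing_scan
from .sra_io import CollapsedRead, Contig
from .synthetic_data import GroundTruthManifest, SimConfig, simulate_study
from .target_trigger_network import (
    CandidateSRNA,
    TriggerAssignment,
    build_network,
    classify_cleavage,
    edge_list_tsv,
    predict_triggers,
    write_graphml,
)

log = logging.getLogger(__name__)

STAGES = ("simulate", "map", "mirna", "isomir", "phase", "network", "de", "report")


@dataclass
class MappingConfig:
    max_loci: int = 500
    min_len: int = 18
    max_len: int = 26


@dataclass
class MirnaConfig:
    min_abundance: int = 10
    shift: int = 3
    max_span: int = 450
    conservation_mismatches: int = 3
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)


@dataclass
class PhaseConfig:
    cycle_len: int = 21
    window_cycles: int = 9
    p_cut: float = 0.01
    min_abundance: int = 2
    min_pha_reads: int = 10
    min_pha_frac: float = 0.5
    max_strand_bias: float = 0.9


@dataclass
class NetworkConfig:
    expectation_cutoff: float = 3.0
    phase_tolerance: int = 0
    min_trigger_count: int = 2


@dataclass
class DEConfig:
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    k_groups: int = 5


@dataclass
class RunConfig:
    """All pipeline thresholds, with the cited defaults, plus the seed."""

    seed: int = 17
    sim: SimConfig = field(default_factory=SimConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    mirna: MirnaConfig = field(default_factory=MirnaConfig)
    isomir_max_offset: int = 5
    phase: PhaseConfig = field(default_factory=PhaseConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    de: DEConfig = field(default_factory=DEConfig)

    def __post_init__(self) -> None:
        self.sim.seed = self.seed

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        cfg = cls(seed=d.get("seed", 17))
        for key, sub in d.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config section {key!r}")
            cur = getattr(cfg, key)
            if dataclasses.is_dataclass(cur) and isinstance(sub, dict):
                for k, v in sub.items():
                    inner = getattr(cur, k, None)
                    if dataclasses.is_dataclass(inner) and isinstance(v, dict):
                        for kk, vv in v.items():
                            setattr(inner, kk, vv)
                    else:
                        setattr(cur, k, v)
            else:
                setattr(cfg, key, sub)
        cfg.sim.libraries = tuple(cfg.sim.libraries)
        return cfg


@dataclass
class AnalysisResult:
    reads: list[CollapsedRead]
    library_totals: dict[str, int]
    mapping: sra_io.MappingResult
    discovery: DiscoveryResult | None = None
    isomirs: list[IsomiR] = field(default_factory=list)
    n_locus_other: int = 0
    window_scores: list[WindowScore] = field(default_factory=list)
    pgts: list[PhasedLocus] = field(default_factory=list)
    assignments: list[TriggerAssignment] = field(default_factory=list)
    network: object = None
    de_results: pd.DataFrame | None = None
    de_categories: pd.Series | None = None
    de_clusters: pd.DataFrame | None = None
    counts: pd.DataFrame | None = None
    report: dict = field(default_factory=dict)


def _overlaps_mirna_locus(hits, loci: Mapping[str, list[tuple[int, int]]]) -> bool:
    for h in hits:
        for s, e in loci.get(h.contig_id, ()):
            if h.start < e and h.end > s:
                return True
    return False


def analyze(
    contigs: Sequence[Contig],
    libraries: Mapping[str, Sequence[str]],
    config: RunConfig,
    known_mirnas: Sequence[str] = (),
    backend: FoldBackend | None = None,
    until: str = "report",
) -> AnalysisResult:
    """Run the analysis stages in memory, stopping after ``until``."""
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    stop = STAGES.index(until)
    backend = backend or default_backend()

    # -- map ---------------------------------------------------------------
    reads = sra_io.collapse_reads(libraries)
    reads = sra_io.length_filter(
        reads, config.mapping.min_len, config.mapping.max_len
    )
    index = sra_io.build_index(contigs)
    mapping = sra_io.map_reads(reads, index, max_loci=config.mapping.max_loci)
    mapped = [r for r in reads if r.sequence in mapping.hits]
    totals = {
        lib: sum(r.counts.get(lib, 0) for r in mapped) for lib in libraries
    }
    sra_io.rpm_normalize(mapped, totals)
    result = AnalysisResult(reads=mapped, library_totals=totals, mapping=mapping)
    result.report["reads"] = {
        "raw_per_library": {lib: len(v) for lib, v in libraries.items()},
        "collapsed_18_26": len(reads),
        "mapped_unique": len(mapped),
        "unmapped_unique": len(mapping.unmapped),
        "hyper_repetitive": len(mapping.hyper_repetitive),
        "mapped_totals": totals,
    }
    if stop <= STAGES.index("map"):
        return result

    # -- mirna ---------------------------------------------------------------
    mc = config.mirna
    result.discovery = discover_mirnas(
        mapped, mapping.hits, contigs, known_mirnas=known_mirnas,
        backend=backend, thresholds=mc.thresholds,
        min_abundance=mc.min_abundance, shift=mc.shift, max_span=mc.max_span,
    )
    ann = result.discovery.annotations
    result.report["mirna"] = {
        "precursors": len(result.discovery.accepted),
        "matures": len(ann),
        "cs": sum(1 for a in ann if a.conservation == "cs"),
        "ls": sum(1 for a in ann if a.conservation == "ls"),
        "canonical": sum(1 for a in ann if a.canonical),
        "length_distribution": _length_dist(a.mature_seq for a in ann),
    }
    if stop <= STAGES.index("mirna"):
        return result

    # -- isomir --------------------------------------------------------------
    result.isomirs, result.n_locus_other = collect_isomirs(
        mapped, mapping.hits, result.discovery.accepted,
        max_offset=config.isomir_max_offset,
    )
    rpm_total = {r.sequence: r.total_rpm for r in mapped}
    result.report["isomir"] = {
        "isomirs": len(result.isomirs),
        "from_star": sum(1 for i in result.isomirs if i.from_star),
        "by_class": {
            c: sum(1 for i in result.isomirs if i.variant_class == c)
            for c in ("five_prime", "three_prime", "both")
        },
        "locus_other_reads": result.n_locus_other,
    }
    result.report["isomir_table"] = summarize_isomirs(
        result.isomirs, rpm_total
    ).to_dict("records")
    if stop <= STAGES.index("isomir"):
        return result

    # -- phase ---------------------------------------------------------------
    pc = config.phase
    loci = result.discovery.mirna_loci()
    phase_reads = [
        r for r in mapped
        if r.total_count >= pc.min_abundance
        and not _overlaps_mirna_locus(mapping.hits[r.sequence], loci)
    ]
    contig_lengths = {c.id: len(c.sequence) for c in contigs}
    result.window_scores = phasing_scan(
        phase_reads, mapping.hits, contig_lengths,
        cycle=pc.cycle_len, window_cycles=pc.window_cycles,
    )
    result.pgts = call_pgts(
        result.window_scores, phase_reads, mapping.hits,
        p_cut=pc.p_cut, min_pha_reads=pc.min_pha_reads,
        min_pha_frac=pc.min_pha_frac, max_strand_bias=pc.max_strand_bias,
    )
    n_pha = len({r.sequence for l in result.pgts for _, _, r in l.phased_reads})
    n_non = len({r.sequence for l in result.pgts for _, _, r in l.nonphased_reads})
    result.report["phase"] = {
        "windows_scored": len(result.window_scores),
        "pgt_loci": len(result.pgts),
        "pgt_transcripts": len({l.contig_id for l in result.pgts}),
        "phased_sirnas": n_pha,
        "nonphased_sirnas": n_non,
    }
    if stop <= STAGES.index("phase"):
        return result

    # -- network -------------------------------------------------------------
    nc = config.network
    contig_seq = {c.id: c.sequence for c in contigs}
    counts_by_seq = {r.sequence: r.total_count for r in mapped}
    candidates, srna_origins = _trigger_candidates(result, counts_by_seq)
    pgt_transcript = {l.id: l.contig_id for l in result.pgts}
    register_starts = {l.id: l.register_start for l in result.pgts}
    assignments: list[TriggerAssignment] = []
    for locus in result.pgts:
        found = predict_triggers(
            locus, contig_seq[locus.contig_id], candidates,
            cutoff=nc.expectation_cutoff, phase_tolerance=nc.phase_tolerance,
            min_count=nc.min_trigger_count,
        )
        for a in found:
            classify_cleavage(a, srna_origins, pgt_transcript, register_starts)
        assignments.extend(found)
    result.assignments = assignments
    result.network = build_network(
        result.discovery.annotations, result.pgts, assignments
    )
    triggered = {a.pgt_id for a in assignments}
    result.report["network"] = {
        "triggers": len(assignments),
        "trigger_sequences": len({a.trigger for a in assignments}),
        "pgts_with_triggers": len(triggered),
        "pgts_without_triggers": len(result.pgts) - len(triggered),
        "by_class": {
            c: sum(1 for a in assignments if a.trigger_class == c)
            for c in ("miRNA", "isomiRNA", "pha-siRNA", "nonpha-siRNA")
        },
        "by_mode": {
            m: sum(1 for a in assignments if a.cleavage_mode == m)
            for m in ("initiator", "cis", "trans")
        },
    }
    if stop <= STAGES.index("network"):
        return result

    # -- de ------------------------------------------------------------------
    de_seqs = sorted(
        {a.mature_seq for a in result.discovery.annotations}
        | {i.sequence for i in result.isomirs}
        | {r.sequence for l in result.pgts for _, _, r in l.phased_reads}
        | {r.sequence for l in result.pgts for _, _, r in l.nonphased_reads}
    )
    by_seq = {r.sequence: r for r in mapped}
    libs = list(libraries)
    result.counts = pd.DataFrame(
        {lib: [by_seq[s].counts.get(lib, 0) if s in by_seq else 0 for s in de_seqs]
         for lib in libs},
        index=de_seqs,
    )
    result.de_results, result.de_categories, result.de_clusters = (
        differential_expression(
            result.counts, totals,
            thresholds=config.de.thresholds, k_groups=config.de.k_groups,
        )
    )
    cats = result.de_categories
    result.report["de"] = {
        "tested": len(de_seqs),
        "significant": int((cats == "significant").sum()),
        "likely": int((cats == "likely").sum()),
        "ns": int((cats == "ns").sum()),
        "cluster_sizes": result.de_clusters["cluster_group"]
        .value_counts().sort_index().to_dict(),
    }
    return result


def _length_dist(seqs) -> dict[int, int]:
    out: dict[int, int] = {}
    for s in seqs:
        out[len(s)] = out.get(len(s), 0) + 1
    return dict(sorted(out.items()))


def _trigger_candidates(result: AnalysisResult, counts_by_seq: dict[str, int]):
    """Candidate sRNAs (deduplicated by class priority) and siRNA origins."""
    srna_origins: dict[str, set[str]] = {}
    ranked: dict[str, tuple[int, CandidateSRNA]] = {}

    def add(seq: str, cls: str, origin: str, rank: int) -> None:
        cand = CandidateSRNA(seq, cls, origin, counts_by_seq.get(seq, 0))
        if seq not in ranked or rank < ranked[seq][0]:
            ranked[seq] = (rank, cand)

    for a in result.discovery.annotations:
        add(a.mature_seq, "miRNA", a.precursor_ids[0], 0)
    for i in result.isomirs:
        add(i.sequence, "isomiRNA", i.parent, 1)
    for locus in result.pgts:
        for _, _, r in locus.phased_reads:
            add(r.sequence, "pha-siRNA", locus.contig_id, 2)
            srna_origins.setdefault(r.sequence, set()).add(locus.contig_id)
        for _, strand, r in locus.nonphased_reads:
            # an antisense off-register locus read is most likely the
            # footprint of an sRNA bound to its target site, not a
            # biogenesis product: it establishes neither derivation nor
            # nonphased-siRNA candidacy
            if strand == "+":
                add(r.sequence, "nonpha-siRNA", locus.contig_id, 3)
                srna_origins.setdefault(r.sequence, set()).add(locus.contig_id)
    candidates = [c for _, c in sorted(ranked.values(), key=lambda rc: rc[1].sequence)]
    return candidates, srna_origins


# ---------------------------------------------------------------------------
# File-level orchestration
# ---------------------------------------------------------------------------

def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_fresh(stage_dir: Path, key: str) -> bool:
    done = stage_dir / ".done"
    return done.exists() and done.read_text().strip() == key


def _mark_done(stage_dir: Path, key: str) -> None:
    (stage_dir / ".done").write_text(key + "\n")


def run_all(
    config: RunConfig,
    run_dir: str | Path,
    until: str = "report",
    backend: FoldBackend | None = None,
) -> AnalysisResult:
    """Execute the pipeline under ``run_dir`` with per-stage caching.

    The simulate stage is cached on its config section; a completed stage
    with unchanged inputs is not rewritten.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(config.to_yaml())

    sim_dir = run_dir / "simulate"
    sim_dir.mkdir(exist_ok=True)
    sim_key = _hash_obj(dataclasses.asdict(config.sim))
    if not _stage_fresh(sim_dir, sim_key):
        study = simulate_study(config.sim, backend=backend)
        sra_io.write_fasta(((c.id, c.sequence) for c in study.contigs), sim_dir / "reference.fa")
        for lib, rlist in study.libraries.items():
            sra_io.write_fasta(
                ((f"{lib}_{i + 1}", s) for i, s in enumerate(rlist)),
                sim_dir / f"lib_{lib}.fa",
            )
        sra_io.write_fasta(
            ((f"known_{i + 1}", s) for i, s in enumerate(study.manifest.known_mirnas)),
            sim_dir / "known_mirnas.fa",
        )
        study.manifest.save(sim_dir / "manifest.json")
        _mark_done(sim_dir, sim_key)
        log.info("simulate: %d contigs, %d libraries", len(study.contigs), len(study.libraries))
    contigs = sra_io.read_fasta(sim_dir / "reference.fa")
    libraries = {
        lib: sra_io.read_library(sim_dir / f"lib_{lib}.fa")
        for lib in config.sim.libraries
    }
    known = [c.sequence for c in sra_io.read_fasta(sim_dir / "known_mirnas.fa")]
    if until == "simulate":
        return AnalysisResult(reads=[], library_totals={}, mapping=None)

    result = analyze(contigs, libraries, config, known_mirnas=known,
                     backend=backend, until=until)
    run_key = _hash_obj([config.to_yaml(), sim_key, until])
    _write_outputs(result, config, run_dir, until, run_key)
    return result


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_outputs(
    result: AnalysisResult, config: RunConfig, run_dir: Path, until: str, run_key: str
) -> None:
    stop = STAGES.index(until)
    libs = list(config.sim.libraries)

    d = run_dir / "map"
    d.mkdir(exist_ok=True)
    if not _stage_fresh(d, run_key):
        sra_io.write_collapsed_fasta(result.reads, d / "collapsed.fa")
        sra_io.write_counts_tsv(result.reads, libs, d / "counts.tsv")
        (d / "mapping_stats.json").write_text(
            json.dumps(result.report["reads"], indent=1, sort_keys=True)
        )
        _mark_done(d, run_key)
    if stop <= STAGES.index("map"):
        return

    d = run_dir / "mirna"
    d.mkdir(exist_ok=True)
    if not _stage_fresh(d, run_key):
        acc = result.discovery.accepted
        sra_io.write_fasta(((c.id, c.precursor_seq) for c in acc), d / "precursors.fa")
        sra_io.write_fasta(
            ((f"mir{i + 1}", a.mature_seq) for i, a in enumerate(result.discovery.annotations)),
            d / "matures.fa",
        )
        feats = []
        for c in acc:
            feats.append((c.contig_id, "miRNA_primary_transcript",
                          c.window_start, c.window_end, c.strand, ".", {"ID": c.id}))
        (d / "precursors.gff3").write_text(sra_io.gff3_records(feats))
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "precursor": c.id, "mature": c.mature_seq,
                        "star": c.star_seq, "mfe": c.mfe, "gc_pct": c.gc_pct,
                        "amfe": c.amfe, "mfei": c.mfei,
                        "duplex_mismatches": c.duplex_mismatches,
                        "strand_bias": c.strand_bias,
                        "abundance_bias": c.abundance_bias,
                    }
                    for c in acc
                ]
            ),
            d / "metrics.tsv",
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "mature": a.mature_seq,
                        "conservation": a.conservation,
                        "canonical": a.canonical,
                        "n_precursors": len(a.precursor_ids),
                        "precursors": ",".join(a.precursor_ids),
                    }
                    for a in result.discovery.annotations
                ]
            ),
            d / "annotations.tsv",
        )
        _mark_done(d, run_key)
    if stop <= STAGES.index("mirna"):
        return

    d = run_dir / "isomir"
    d.mkdir(exist_ok=True)
    if not _stage_fresh(d, run_key):
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "sequence": i.sequence, "parent": i.parent,
                        "variant_class": i.variant_class,
                        "offset5": i.offset5, "offset3": i.offset3,
                        "from_star": i.from_star,
                        "source_precursors": ",".join(i.source_precursors),
                    }
                    for i in result.isomirs
                ]
            ),
            d / "isomirs.tsv",
        )
        _write_tsv(pd.DataFrame(result.report["isomir_table"]), d / "summary.tsv")
        _mark_done(d, run_key)
    if stop <= STAGES.index("isomir"):
        return

    d = run_dir / "phase"
    d.mkdir(exist_ok=True)
    if not _stage_fresh(d, run_key):
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "locus": l.id, "contig": l.contig_id,
                        "start": l.start, "end": l.end,
                        "register_start": l.register_start,
                        "cycle_len": l.cycle_len, "p_value": l.p_value,
                        "n_windows": l.n_windows,
                        "phased_fraction": l.phased_fraction,
                        "strand_bias": l.strand_bias,
                        "n_phased": len(l.phased_reads),
                        "n_nonphased": len(l.nonphased_reads),
                    }
                    for l in result.pgts
                ]
            ),
            d / "pgts.tsv",
        )
        feats = [
            (l.contig_id, "siRNA_locus", l.start, l.end, "+",
             f"{l.p_value:.3g}", {"ID": l.id, "register": str(l.register_start)})
            for l in result.pgts
        ]
        (d / "pgts.gff3").write_text(sra_io.gff3_records(feats))
        for name in ("phased", "nonphased"):
            rows = []
            for l in result.pgts:
                for pos, strand, r in getattr(l, f"{name}_reads"):
                    rows.append(
                        {"locus": l.id, "position": pos, "strand": strand,
                         "sequence": r.sequence, "total_count": r.total_count}
                    )
            _write_tsv(pd.DataFrame(rows), d / f"{name}_reads.tsv")
        _mark_done(d, run_key)
    if stop <= STAGES.index("phase"):
        return

    d = run_dir / "network"
    d.mkdir(exist_ok=True)
    if not _stage_fresh(d, run_key):
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "trigger": a.trigger, "class": a.trigger_class,
                        "pgt": a.pgt_id, "site_start": a.site.start,
                        "site_end": a.site.end,
                        "expectation": a.site.expectation,
                        "cleavage_pos": a.site.cleavage_pos,
                        "hit_model": a.hit_model, "mode": a.cleavage_mode,
                    }
                    for a in result.assignments
                ]
            ),
            d / "triggers.tsv",
        )
        (d / "edges.tsv").write_text(edge_list_tsv(result.network))
        write_graphml(result.network, d / "network.graphml")
        _mark_done(d, run_key)
    if stop <= STAGES.index("network"):
        return

    d = run_dir / "de"
    d.mkdir(exist_ok=True)
    if not _stage_fresh(d, run_key):
        _write_tsv(result.de_results, d / "tests.tsv")
        result.de_categories.to_frame().to_csv(d / "categories.tsv", sep="\t")
        result.de_clusters.to_csv(d / "clusters.tsv", sep="\t", float_format="%.6g")
        _mark_done(d, run_key)
    if stop <= STAGES.index("de"):
        return

    d = run_dir / "report"
    d.mkdir(exist_ok=True)
    (d / "report.json").write_text(
        json.dumps(result.report, indent=1, sort_keys=True, default=str)
    )
    (d / "report.txt").write_text(render_report(result.report))
    _mark_done(d, run_key)


def render_report(report: dict) -> str:
    """Human-readable run summary mirroring the per-stage funnels."""
    lines = ["phasiforge run summary", "=" * 22, ""]
    for stage in ("reads", "mirna", "isomir", "phase", "network", "de"):
        if stage not in report:
            continue
        lines.append(f"[{stage}]")
        for k, v in report[stage].items():
            lines.append(f"  {k}: {v}")
        lines.append("")
    return "\n".join(lines)
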