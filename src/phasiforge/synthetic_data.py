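"""Synthetic small-RNA study generator with planted ground truth.

Builds a reference (hairpin contigs, phased-siRNA gene transcripts, plain
background contigs) plus multi-library read sets in which every biological
signal the pipeline looks for is planted at known coordinates:

* miRNA/miRNA* duplexes inside foldable hairpins (0-4 duplex mismatches);
* isomiR end-variants around each canonical mature;
* 21-nt phase registers on PGT-like transcripts downstream of a trigger
  target site (miRNA initiators, same-transcript cis triggers, and
  other-transcript trans triggers);
* tissue-differential abundances (>= 2-fold effects);
* uniform background sampled from the reference, dominated by the 24-nt
  length class.

The ground-truth manifest round-trips losslessly through JSON and is the
oracle for every downstream recovery test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .fold import FoldBackend, default_backend, pair_table
from .sra_io import Contig, revcomp

BASES = np.array(list("ACGT"))
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

# Read-length profile of the background class: heavily dominated by 24-mers,
# with 21/22-mers as the secondary classes (typical plant sRNA library shape).
BACKGROUND_LENGTH_PROFILE = {
    18: 0.02, 19: 0.02, 20: 0.05, 21: 0.13, 22: 0.09, 23: 0.09,
    24: 0.50, 25: 0.07, 26: 0.03,
}


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


# ---------------------------------------------------------------------------
# Manifest types
# ---------------------------------------------------------------------------

@dataclass
class PlantedHairpin:
    id: str
    contig_id: str
    precursor_start: int
    precursor_end: int
    mature_seq: str
    mature_start: int
    mature_end: int
    star_seq: str
    star_start: int
    star_end: int
    mismatches: int
    arm: str  # which arm carries the mature: '5p' or '3p'


@dataclass
class PlantedRegister:
    register_start: int
    cycle_len: int
    n_cycles: int
    trigger_seq: str
    trigger_kind: str  # 'mirna' | 'phasi'
    trigger_origin: str  # id of the hairpin or PGT the trigger derives from
    expected_mode: str  # 'initiator' | 'cis' | 'trans'
    site_start: int
    site_end: int
    phased_sense: list[int] = field(default_factory=list)
    phased_antisense: list[int] = field(default_factory=list)  # 5' positions


@dataclass
class PlantedPGT:
    id: str
    contig_id: str
    length: int
    registers: list[PlantedRegister] = field(default_factory=list)


@dataclass
class PlantedIsomir:
    parent: str  # hairpin id
    sequence: str
    offset5: int
    offset3: int


@dataclass
class PlantedSpecies:
    """One expressed sequence with its relative abundance weight."""

    sequence: str
    kind: str  # mature | star | isomir | phased | phased_antisense | nonphased
    origin: str  # hairpin or PGT id
    weight: float


@dataclass
class GroundTruthManifest:
    rng_seed: int
    planted_hairpins: list[PlantedHairpin] = field(default_factory=list)
    planted_pgts: list[PlantedPGT] = field(default_factory=list)
    planted_isomirs: list[PlantedIsomir] = field(default_factory=list)
    species: list[PlantedSpecies] = field(default_factory=list)
    # sequence -> library -> expected RPM (filled by simulate_libraries)
    tissue_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    # sequences carrying a planted >= 2-fold tissue effect
    fold_changed: dict[str, dict[str, float]] = field(default_factory=dict)
    # stand-in for a known mature-miRNA library: even-indexed planted
    # matures, lightly mutated (<= 2 bases), so cs/ls calls have an oracle
    known_mirnas: list[str] = field(default_factory=list)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthManifest":
        return cls(
            rng_seed=d["rng_seed"],
            planted_hairpins=[PlantedHairpin(**h) for h in d["planted_hairpins"]],
            planted_pgts=[
                PlantedPGT(
                    id=p["id"], contig_id=p["contig_id"], length=p["length"],
                    registers=[PlantedRegister(**r) for r in p["registers"]],
                )
                for p in d["planted_pgts"]
            ],
            planted_isomirs=[PlantedIsomir(**i) for i in d["planted_isomirs"]],
            species=[PlantedSpecies(**s) for s in d["species"]],
            tissue_effects=d["tissue_effects"],
            fold_changed=d["fold_changed"],
            known_mirnas=d.get("known_mirnas", []),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruthManifest":
        return cls.from_dict(json.loads(Path(path).read_text()))

    # -- invariants ---------------------------------------------------------
    def verify_planted(self, contigs: Sequence[Contig]) -> None:
        """Check every planted sequence occurs verbatim at its coordinates."""
        by_id = {c.id: c.sequence for c in contigs}
        for h in self.planted_hairpins:
            seq = by_id[h.contig_id]
            assert seq[h.mature_start:h.mature_end] == h.mature_seq, h.id
            assert seq[h.star_start:h.star_end] == h.star_seq, h.id
        for p in self.planted_pgts:
            t = by_id[p.contig_id]
            for r in p.registers:
                assert t[r.site_start:r.site_end] == revcomp(r.trigger_seq), p.id


# ---------------------------------------------------------------------------
# Hairpin simulation
# ---------------------------------------------------------------------------

def _nonpairing_base(rng: np.random.Generator, opposite: Sequence[str]) -> str:
    """A base that cannot pair (canonically or by wobble) with any of ``opposite``."""
    ok = [b for b in "ACGT" if all((b, o) not in _PAIRS for o in opposite)]
    return str(rng.choice(ok)) if ok else "C"  # C pairs only with G


def simulate_hairpin(
    mature: str,
    loop_len: int,
    mismatches: int,
    rng: np.random.Generator,
    mature_arm: str = "5p",
    backend: FoldBackend | None = None,
    max_tries: int = 60,
) -> tuple[str, tuple[int, int], tuple[int, int], str]:
    """Build a precursor whose fold pairs mature with star at the requested
    mismatch count.

    Returns (precursor, (mature_start, mature_end), (star_start, star_end),
    star_seq), coordinates relative to the precursor.  Raises ValueError for
    mismatches > 4 or if no structure satisfying the contract is found.
    """
    if mismatches > 4:
        raise ValueError("at most 4 miRNA/miRNA* duplex mismatches are allowed")
    if mismatches < 0 or loop_len < 3:
        raise ValueError("need mismatches >= 0 and loop_len >= 3")
    backend = backend or default_backend()
    L = len(mature)
    if mismatches > max(0, (L - 6) // 3):
        raise ValueError(f"cannot place {mismatches} isolated mismatches in a {L}-nt duplex")

    for _ in range(max_tries):
        star = list(revcomp(mature))
        # choose mismatch positions on the star, >=3 from each end and >=3 apart
        positions: list[int] = []
        candidates = list(range(3, L - 3))
        rng.shuffle(candidates)
        for c in candidates:
            if len(positions) == mismatches:
                break
            if all(abs(c - p) >= 3 for p in positions):
                positions.append(c)
        if len(positions) < mismatches:
            continue
        for sp in positions:
            # star position sp sits opposite mature position L-1-sp; forbid
            # pairing with it and with its neighbours (prevents bulge slippage)
            mi = L - 1 - sp
            opp = mature[max(0, mi - 1): mi + 2]
            star[sp] = _nonpairing_base(rng, opp)
        # convert ~2 Watson-Crick pairs to G:U wobbles: real duplexes carry
        # them, and they keep the star from being a verbatim reverse
        # complement of the mature (which would cross-map reads between arms)
        n_wobble = 0
        for sp in candidates:
            if n_wobble >= 2:
                break
            if any(abs(sp - p) < 2 for p in positions):
                continue
            mi = L - 1 - sp
            if mature[mi] == "G" and star[sp] == "C":
                star[sp] = "T"
                n_wobble += 1
            elif mature[mi] == "T" and star[sp] == "A":
                star[sp] = "G"
                n_wobble += 1
        if n_wobble == 0:
            continue
        star_seq = "".join(star)
        loop = random_seq(rng, loop_len, gc=0.25)
        if mature_arm == "5p":
            precursor = mature + loop + star_seq
            m_span = (0, L)
            s_span = (L + loop_len, L + loop_len + L)
        else:
            precursor = star_seq + loop + mature
            s_span = (0, L)
            m_span = (L + loop_len, L + loop_len + L)
        structure, mfe = backend.fold(precursor)
        pt = pair_table(structure)
        paired = 0
        external = False
        for i in range(*m_span):
            j = pt[i]
            if j == -1:
                continue
            if s_span[0] <= j < s_span[1]:
                paired += 1
            else:
                external = True
        if not external and paired == L - mismatches:
            return precursor, m_span, s_span, star_seq
    raise ValueError(
        f"could not realise a hairpin with {mismatches} mismatches for {mature}"
    )


# ---------------------------------------------------------------------------
# PGT simulation
# ---------------------------------------------------------------------------

def plant_register(
    transcript: list[str],
    register_start: int,
    n_cycles: int,
    trigger: str,
    trigger_kind: str,
    trigger_origin: str,
    expected_mode: str,
    cycle: int = 21,
) -> PlantedRegister:
    """Write a trigger target site into ``transcript`` (in place) and record
    the phase register it initiates.

    The site is the reverse complement of the trigger, placed so that the
    trigger's cleavage position (opposite trigger nucleotides 10/11) equals
    ``register_start``: the site occupies
    ``[register_start - len(trigger) + 10, register_start + 10)``.
    """
    L = len(trigger)
    site_start = register_start - L + 10
    site_end = register_start + 10
    if site_start < 0:
        raise ValueError("register_start too close to the transcript 5' end")
    if register_start + cycle * n_cycles > len(transcript):
        raise ValueError("transcript too short for the requested cycles")
    transcript[site_start:site_end] = list(revcomp(trigger))
    sense = [register_start + cycle * i for i in range(n_cycles)]
    antisense = [
        register_start + cycle * i + 2
        for i in range(n_cycles)
        if register_start + cycle * i + 2 - (cycle - 1) >= 0
    ]
    return PlantedRegister(
        register_start=register_start,
        cycle_len=cycle,
        n_cycles=n_cycles,
        trigger_seq=trigger,
        trigger_kind=trigger_kind,
        trigger_origin=trigger_origin,
        expected_mode=expected_mode,
        site_start=site_start,
        site_end=site_end,
        phased_sense=sense,
        phased_antisense=antisense,
    )


def simulate_pgt(
    transcript_len: int,
    register_start: int,
    n_cycles: int,
    trigger: str,
    rng: np.random.Generator,
    cycle: int = 21,
    trigger_kind: str = "mirna",
    trigger_origin: str = "",
    expected_mode: str = "initiator",
) -> tuple[str, PlantedRegister]:
    """A random transcript with one planted trigger site and phase register."""
    if n_cycles < 3:
        raise ValueError("need at least 3 phase cycles")
    if register_start + cycle * n_cycles > transcript_len:
        raise ValueError("transcript too short for the requested cycles")
    t = list(random_seq(rng, transcript_len, gc=0.45))
    reg = plant_register(
        t, register_start, n_cycles, trigger, trigger_kind, trigger_origin,
        expected_mode, cycle=cycle,
    )
    return "".join(t), reg


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for the default synthetic run."""

    seed: int = 17
    libraries: tuple[str, ...] = ("leaf", "flower", "boll")
    depth_per_lib: int = 100_000
    background_frac: float = 0.35
    nb_dispersion: float = 0.1
    n_hairpins: int = 30
    n_pgt_initiator: int = 10
    n_pgt_cis: int = 3
    n_pgt_trans: int = 2
    pgt_len: int = 560
    n_cycles: int = 10
    cycle_len: int = 21
    n_background_contigs: int = 12
    background_contig_len: int = 2000
    # per-nt background sampling weight of the repeat-like contigs relative
    # to genic contigs: heterochromatic 24-nt siRNA background concentrates
    # on repeats rather than on miRNA precursors or PGTs
    repeat_background_weight: float = 8.0
    flank_len: int = 110
    mature_weight: float = 60.0
    fold_change: float = 4.0
    n_de_mirna: int = 8
    n_de_sirna: int = 8


@dataclass
class StudyData:
    contigs: list[Contig]
    libraries: dict[str, list[str]]
    manifest: GroundTruthManifest


def _mature_lengths(n: int, n_triggers: int) -> list[int]:
    """Mature lengths: trigger miRNAs are kept 21 nt; the rest mix 20-24."""
    tail_cycle = [21, 22, 21, 20, 24, 21, 22, 21]
    return [21] * n_triggers + [tail_cycle[i % len(tail_cycle)] for i in range(n - n_triggers)]


def build_reference(cfg: SimConfig, backend: FoldBackend | None = None):
    """Plant hairpins, PGTs and background contigs; return (contigs, manifest)."""
    backend = backend or default_backend()
    rng = np.random.default_rng(cfg.seed)
    contigs: list[Contig] = []
    manifest = GroundTruthManifest(rng_seed=cfg.seed)

    n_triggers = cfg.n_pgt_initiator + cfg.n_pgt_cis
    if cfg.n_hairpins < n_triggers:
        raise ValueError("need at least one hairpin per initiator-triggered PGT")
    lengths = _mature_lengths(cfg.n_hairpins, n_triggers)

    # --- hairpins ---------------------------------------------------------
    for i in range(cfg.n_hairpins):
        hid = f"hp{i:03d}"
        mm = i % 3  # duplex mismatches 0..2
        arm = "5p" if i % 2 == 0 else "3p"
        loop_len = int(rng.integers(12, 31))
        for _attempt in range(40):
            gc = float(rng.uniform(0.48, 0.62))
            mature = random_seq(rng, lengths[i], gc=gc)
            if not 0.42 <= gc_fraction(mature) <= 0.68:
                continue
            try:
                precursor, m_span, s_span, star = simulate_hairpin(
                    mature, loop_len, mm, rng, mature_arm=arm, backend=backend
                )
            except ValueError:
                continue
            _, mfe = backend.fold(precursor)
            if mfe <= -32.0:
                break
        else:
            raise RuntimeError(f"failed to generate hairpin {hid}")
        flank5 = random_seq(rng, cfg.flank_len, gc=0.32)
        flank3 = random_seq(rng, cfg.flank_len, gc=0.32)
        off = len(flank5)
        contigs.append(Contig(hid, flank5 + precursor + flank3))
        manifest.planted_hairpins.append(
            PlantedHairpin(
                id=hid, contig_id=hid,
                precursor_start=off, precursor_end=off + len(precursor),
                mature_seq=mature,
                mature_start=off + m_span[0], mature_end=off + m_span[1],
                star_seq=star,
                star_start=off + s_span[0], star_end=off + s_span[1],
                mismatches=mm, arm=arm,
            )
        )

    # --- known-miRNA stand-in library ------------------------------------
    for i, h in enumerate(manifest.planted_hairpins):
        if i % 2 == 0:
            manifest.known_mirnas.append(_mutate(h.mature_seq, i % 3, rng))

    # --- PGTs -------------------------------------------------------------
    hp = manifest.planted_hairpins
    cyc = cfg.cycle_len
    pgt_serial = 0

    def new_pgt(registers_builder) -> PlantedPGT:
        nonlocal pgt_serial
        pid = f"pgt{pgt_serial:03d}"
        pgt_serial += 1
        t = list(random_seq(rng, cfg.pgt_len, gc=0.45))
        regs = registers_builder(pid, t)
        pgt = PlantedPGT(id=pid, contig_id=pid, length=len(t), registers=regs)
        contigs.append(Contig(pid, "".join(t)))
        manifest.planted_pgts.append(pgt)
        return pgt

    # miRNA-initiated PGTs
    for j in range(cfg.n_pgt_initiator):
        trig_hp = hp[j]

        def build(pid, t, trig_hp=trig_hp):
            r0 = 30 + (pgt_serial % 3) * 7
            return [plant_register(t, r0, cfg.n_cycles, trig_hp.mature_seq,
                                   "mirna", trig_hp.id, "initiator", cycle=cyc)]

        new_pgt(build)

    # cis-triggered PGTs: miRNA initiator + secondary register set by one of
    # the PGT's own phased siRNAs
    for j in range(cfg.n_pgt_cis):
        trig_hp = hp[cfg.n_pgt_initiator + j]

        def build(pid, t, trig_hp=trig_hp):
            r0 = 32
            reg1 = plant_register(t, r0, 8, trig_hp.mature_seq,
                                  "mirna", trig_hp.id, "initiator", cycle=cyc)
            # cycle-2 phased siRNA of the primary register triggers a second,
            # out-of-phase register further downstream on the same transcript
            r2 = r0 + 8 * cyc + 10 + 7 * (j + 1) % cyc
            if (r2 - r0) % cyc == 0:
                r2 += 3
            n2 = (len(t) - r2) // cyc
            sirna_span = (r0 + 2 * cyc, r0 + 3 * cyc)
            reg2 = plant_register(t, r2, min(n2, 8), "A" * cyc,
                                  "phasi", pid, "cis", cycle=cyc)
            # the trigger sequence is the transcript's own cycle-2 siRNA,
            # extracted after all sites are planted
            sirna = "".join(t[sirna_span[0]:sirna_span[1]])
            t[reg2.site_start:reg2.site_end] = list(revcomp(sirna))
            reg2.trigger_seq = sirna
            return [reg1, reg2]

        new_pgt(build)

    # trans-triggered PGTs: register set by a phased siRNA from another PGT
    for j in range(cfg.n_pgt_trans):
        donor = manifest.planted_pgts[j]
        donor_reg = donor.registers[0]
        donor_seq = next(c.sequence for c in contigs if c.id == donor.contig_id)
        s = donor_reg.register_start + 3 * cyc
        donor_sirna = donor_seq[s:s + cyc]

        def build(pid, t, donor_sirna=donor_sirna, donor=donor):
            r0 = 40
            return [plant_register(t, r0, cfg.n_cycles, donor_sirna,
                                   "phasi", donor.id, "trans", cycle=cyc)]

        new_pgt(build)

    # --- background contigs ----------------------------------------------
    for b in range(cfg.n_background_contigs):
        contigs.append(Contig(f"bg{b:02d}", random_seq(rng, cfg.background_contig_len, gc=0.40)))

    _build_species(cfg, contigs, manifest, rng)
    manifest.verify_planted(contigs)
    return contigs, manifest


def _mutate(seq: str, k: int, rng: np.random.Generator) -> str:
    out = list(seq)
    for pos in rng.choice(len(seq), size=k, replace=False):
        out[pos] = str(rng.choice([b for b in "ACGT" if b != seq[pos]]))
    return "".join(out)


def _isomir_offsets(rng: np.random.Generator) -> tuple[int, int]:
    """End-offset pair for an isomiR: 3'-only twice as likely as 5'-only."""
    kind = rng.choice(["three", "five", "both"], p=[0.5, 0.25, 0.25])
    mag = lambda: int(rng.choice([-2, -1, 1, 2]))  # noqa: E731
    if kind == "three":
        return 0, mag()
    if kind == "five":
        return mag(), 0
    return mag(), mag()


def _build_species(cfg, contigs, manifest, rng) -> None:
    """Attach expression weights: matures, stars, isomiRs, phased reads."""
    by_id = {c.id: c.sequence for c in contigs}
    for h in manifest.planted_hairpins:
        seq = by_id[h.contig_id]
        w = cfg.mature_weight * float(rng.uniform(0.6, 1.6))
        manifest.species.append(PlantedSpecies(h.mature_seq, "mature", h.id, w))
        manifest.species.append(PlantedSpecies(h.star_seq, "star", h.id, 0.15 * w))
        n_iso = int(rng.integers(2, 4))
        seen = {h.mature_seq, h.star_seq}
        for _ in range(n_iso):
            o5, o3 = _isomir_offsets(rng)
            s, e = h.mature_start + o5, h.mature_end + o3
            iso = seq[s:e]
            if not (18 <= len(iso) <= 26) or iso in seen:
                continue
            seen.add(iso)
            manifest.planted_isomirs.append(PlantedIsomir(h.id, iso, o5, o3))
            manifest.species.append(
                PlantedSpecies(iso, "isomir", h.id, w * float(rng.uniform(0.05, 0.12)))
            )

    for p in manifest.planted_pgts:
        t = by_id[p.contig_id]
        phased_positions = set()
        for reg in p.registers:
            cyc = reg.cycle_len
            for pos in reg.phased_sense:
                s = t[pos:pos + cyc]
                phased_positions.add(pos)
                manifest.species.append(
                    PlantedSpecies(s, "phased", p.id, 18.0 * float(rng.uniform(0.7, 1.4)))
                )
            for p5 in reg.phased_antisense:
                span = t[p5 - (cyc - 1): p5 + 1]
                if len(span) == cyc:
                    manifest.species.append(
                        PlantedSpecies(revcomp(span), "phased_antisense", p.id,
                                       7.0 * float(rng.uniform(0.6, 1.3)))
                    )
        # a few off-register (non-phased) siRNAs per PGT
        reg0 = p.registers[0]
        lo = reg0.register_start
        hi = min(p.length - cfg.cycle_len, lo + cfg.cycle_len * reg0.n_cycles)
        for _ in range(4):
            for _try in range(20):
                pos = int(rng.integers(lo, hi))
                if all((pos - r.register_start) % r.cycle_len != 0 for r in p.registers):
                    break
            manifest.species.append(
                PlantedSpecies(t[pos:pos + cfg.cycle_len], "nonphased", p.id,
                               2.2 * float(rng.uniform(0.8, 1.6)))
            )

    # planted tissue effects: multiplicative fold changes in single libraries
    libs = list(cfg.libraries)
    matures = [s for s in manifest.species if s.kind == "mature"]
    sirnas = [s for s in manifest.species if s.kind in ("phased", "nonphased")]
    pick_m = rng.choice(len(matures), size=min(cfg.n_de_mirna, len(matures)), replace=False)
    pick_s = rng.choice(len(sirnas), size=min(cfg.n_de_sirna, len(sirnas)), replace=False)
    for idx_list, pool in ((pick_m, matures), (pick_s, sirnas)):
        for k, idx in enumerate(idx_list):
            seq = pool[int(idx)].sequence
            lib = libs[k % len(libs)]
            mult = cfg.fold_change if k % 2 == 0 else 1.0 / cfg.fold_change
            manifest.fold_changed[seq] = {l: (mult if l == lib else 1.0) for l in libs}


def simulate_libraries(
    manifest: GroundTruthManifest,
    contigs: Sequence[Contig],
    depth_per_lib: int,
    background_frac: float,
    libraries: Sequence[str],
    rng_seed: int,
    nb_dispersion: float = 0.1,
    contig_weights: dict[str, float] | None = None,
) -> dict[str, list[str]]:
    """Draw per-library raw reads around the planted expected abundances.

    Planted species counts are negative-binomial around their expected value
    (dispersion ``nb_dispersion``); background reads are uniform reference
    substrings with a 24-nt-dominated length profile.  One RNG stream per
    library (seeded ``rng_seed + lib_index``) keeps libraries individually
    reproducible.
    """
    if depth_per_lib <= 0:
        raise ValueError("depth_per_lib must be positive")
    if not 0 <= background_frac <= 1:
        raise ValueError("background_frac must lie in [0, 1]")

    # collapse duplicate planted sequences by summing weights
    weights: dict[str, float] = {}
    for s in manifest.species:
        weights[s.sequence] = weights.get(s.sequence, 0.0) + s.weight
    seqs = sorted(weights)
    base_w = np.array([weights[s] for s in seqs])

    contig_seqs = [c.sequence for c in contigs]
    cw = contig_weights or {}
    usable_len = np.array(
        [max(len(c.sequence) - 26, 1) * cw.get(c.id, 1.0) for c in contigs], dtype=float
    )
    contig_p = usable_len / usable_len.sum()
    lens = np.array(sorted(BACKGROUND_LENGTH_PROFILE))
    len_p = np.array([BACKGROUND_LENGTH_PROFILE[l] for l in lens])

    out: dict[str, list[str]] = {}
    planted_budget = depth_per_lib * (1 - background_frac)
    for li, lib in enumerate(libraries):
        rng = np.random.default_rng(rng_seed + li)
        mult = np.array(
            [manifest.fold_changed.get(s, {}).get(lib, 1.0) for s in seqs]
        )
        w = base_w * mult
        mu = planted_budget * w / w.sum() if w.sum() > 0 else w
        if nb_dispersion > 0:
            r = 1.0 / nb_dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
        else:
            counts = rng.poisson(mu)
        reads: list[str] = []
        for s, c in zip(seqs, counts):
            reads.extend([s] * int(c))
        for s, m in zip(seqs, mu):  # record expected RPM
            manifest.tissue_effects.setdefault(s, {})[lib] = float(m * 1e6 / depth_per_lib)

        n_bg = int(round(depth_per_lib * background_frac))
        if n_bg:
            cidx = rng.choice(len(contig_seqs), size=n_bg, p=contig_p)
            rlens = rng.choice(lens, size=n_bg, p=len_p)
            strands = rng.random(n_bg) < 0.5
            offs = rng.random(n_bg)
            for ci, L, minus, u in zip(cidx, rlens, strands, offs):
                seq = contig_seqs[ci]
                pos = int(u * (len(seq) - L))
                frag = seq[pos:pos + L]
                reads.append(revcomp(frag) if minus else frag)
        out[lib] = reads
    return out


def simulate_study(cfg: SimConfig | None = None, backend: FoldBackend | None = None) -> StudyData:
    """Full default synthetic study: reference + libraries + manifest."""
    cfg = cfg or SimConfig()
    contigs, manifest = build_reference(cfg, backend=backend)
    weights = {
        c.id: (cfg.repeat_background_weight if c.id.startswith("bg") else 1.0)
        for c in contigs
    }
    libraries = simulate_libraries(
        manifest, contigs, cfg.depth_per_lib, cfg.background_frac,
        cfg.libraries, cfg.seed, nb_dispersion=cfg.nb_dispersion,
        contig_weights=weights,
    )
    return StudyData(contigs=contigs, libraries=libraries, manifest=manifest)
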