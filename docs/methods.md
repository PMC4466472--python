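# Methods

phasiforge re-implements, as one tested pipeline, the standard desk
workflow for annotating plant small-RNA libraries: exact mapping of
collapsed 18–26-nt reads to a reference sequence set, miRNA hairpin
discovery with structural and read-disposition filters, isomiR end-variant
classification, detection of 21-nt phased siRNA loci (PGTs) with a
hypergeometric phasing statistic, prediction of the sRNAs that trigger
each phase register (initiator / cis / trans), and pairwise-tissue
differential expression of the annotated sRNAs. Everything is validated
end-to-end on synthetic libraries in which each signal class is planted at
known coordinates.

## Read processing and mapping

Raw reads are collapsed to unique sequences with per-library counts
(U→T normalised; non-ACGT reads dropped with a warning), filtered to
18–26 nt, and mapped by exact string match against both strands of the
reference. A read with more than `max_loci` (default 500) perfect-match
placements is flagged hyper-repetitive and excluded from discovery;
unmapped reads are likewise excluded. Coordinates are 0-based half-open
internally and converted to 1-based closed on GFF3 export. RPM uses the
per-library total of mapped 18–26-nt reads as its denominator — the
statistically meaningful "putative sRNA" population — and is configurable.
The index is a seed dictionary over 18-nt prefixes with full-string
verification, so `N` in the reference can never match a read base; the
contract is exhaustive perfect-match enumeration, and a naive two-strand
scan serves as its oracle in the tests.

## miRNA discovery

Read clusters (gap ≤ 60 nt) with an anchor read of total count ≥ 10 seed
candidate precursor windows: the anchor locus extended by each pair of
flanks from a fixed grid (5–450 nt, capped so the duplex arms sit ≤ 450 nt
apart). Cheap read-disposition filters run first — single-strand bias
(sense reads / all reads ≥ 0.9) and abundance bias (top-3 reads / all
reads ≥ 0.6) over the window — so regions that can never qualify skip
folding. Surviving windows are folded with the ViennaRNA MFE engine
(a bundled Nussinov base-pair-maximisation backend exists for
structure-only work; its energies are pair counts, not kcal/mol).

The mature may shift up to 3 nt from the anchor locus during duplex
placement; the placement minimising duplex mismatches wins (ties: smaller
shift). The annotated mature sequence, however, always remains the
sequenced anchor read — the shift is a structural allowance, not a
re-annotation. The star arm is the contiguous pairing partner region of
the mature; G:U wobbles count as pairs, and every unpaired mature base
(mismatch or asymmetric bulge) counts one mismatch. Acceptance requires,
with all boundaries inclusive:

| metric | rule | meaning |
|---|---|---|
| duplex mismatches | ≤ 4 | miRNA/miRNA* pairing quality |
| MFE | ≤ −30 kcal/mol | fold stability |
| AMFE | ≥ 22 kcal/mol/100 nt | length-normalised MFE (−MFE/len·100) |
| MFEI | 0.30–1.80 | AMFE / GC% |
| GC | ≥ 25 % | precursor composition |
| strand bias | ≥ 0.9 | transcripts, not dsRNA loci |
| abundance bias | ≥ 0.6 | discrete processing products |

Per anchor the accepted window with fewest mismatches (then shortest
precursor) is kept; matures recurring in several precursors aggregate into
one annotation. A mature (or its star) within 3 end-anchored mismatches of
a known mature-miRNA library entry is conserved (cs), else
lineage-specific (ls); the distance is a best ungapped end-alignment
(length difference ≤ 3, overhanging bases count as mismatches, ties to the
smaller offset). Matures ≤ 22 nt are canonical; 23/24-mers are long
miRNAs.

## isomiR classification

Any read mapping sense within an accepted precursor window that is not the
annotated mature or star is an end-variant of the nearer arm, described by
its 5′ and 3′ offsets against the canonical ends: 5′-only, 3′-only, or
both-end variants. Offsets beyond ±5 nt mark an unrelated locus read
(tallied separately), as do loop and antisense reads. Star-arm variants
are classified against the star and reported with a flag. Only templated
variants exist here — non-templated tailing is out of scope. Each isomiR
is attributed to every accepted precursor containing its sequence, so
multi-locus origins are visible. The summary table counts isomiRs and
their RPM by length (17–27) and class, with a parallel panel restricted to
≥ 10 RPM.

## Phased-siRNA detection

Input is every mapped read with total count ≥ 2 that does not overlap an
accepted miRNA precursor. On each reference sequence, 189-nt windows
(9 cycles of 21; configurable for 24-nt phasing) advance in 21-nt steps.
Within a window of length L there are M = 2L candidate 5′ positions (both
strands; an antisense read participates in a register with the +2-nt
offset of the DCL 2-nt 3′ overhang). For a register r, m = 2·⌈L/21⌉
positions are in-register. With n distinct occupied positions, k of them
in-register, the per-register score is the hypergeometric tail
P(X ≥ k | M, m, n). Occupancy is binary; abundance enters only through the
locus filters.

Because each window reports the register maximising k, the window p-value
is Bonferroni-corrected across the 21 registers tested (p = min(1, 21·tail));
the uncorrected tail is exposed as `p_register` and as the library
function `hypergeom_tail`. Without the correction, sparse background
windows would exceed the nominal false-positive rate purely through
register selection; with it, the corrected p is conservative and planted
registers (tails ~1e-20) are unaffected.

Overlapping significant windows (p < 0.01) sharing a register merge into a
locus (p = minimum window p, window count reported). A locus is kept when
at least one phased read has total count ≥ 10, the phased fraction of
locus read counts is ≥ 0.5 (raw counts; the abundance threshold is a count,
not RPM, and configurable), and sense-strand bias is < 0.9 (a true dsRNA
locus yields both strands — the mirror image of the miRNA rule). Locus
reads split into phased (5′ position in-register, antisense +2) and
non-phased (everything else with count ≥ 2); the sets are disjoint by
construction.

## Targets, triggers and the cleavage network

Target sites use the classic plant-target penalty scheme: per aligned
position, mismatch 1.0, G:U wobble 0.5, penalties doubled at sRNA
positions 2–13 from the 5′ end; sites with expectation ≤ 3.0 (configurable
and deliberately prominent — this cutoff is a convention, not a measured
value) are reported with the cleavage position opposite sRNA positions
10/11. Scoring is over ungapped complementary windows: at this cutoff a
bulge would cost 2.0 (4.0 in the core), leaving essentially no slack, so
gapped alignment changes nothing at cleavage-competent stringency while
costing an order of magnitude in compute. The scorer is vectorised; a
per-window pure-Python oracle checks it in the tests.

A candidate trigger (annotated miRNA, isomiR, phased or non-phased siRNA,
itself expressed with total count ≥ 2) triggers a locus when one of its
sites cleaves in phase with the locus register (tolerance 0 nt by default,
±1 configurable). The hit model is two-hit when the same sRNA also has a
second site downstream of the register start. Cleavage modes:

* **initiator** — a miRNA/isomiR whose cleavage position *is* the locus
  register start: it set the register. (With multi-register transcripts,
  "the primary register" is exactly the one whose start coincides with the
  initiating cleavage, so this is decidable locus-locally.)
* **cis** — a phased/non-phased siRNA derived from the same PGT transcript
  acting at another register.
* **trans** — any sRNA from a different source, including a miRNA/isomiR
  acting in-phase away from the register start.

Derivation ("which PGT does this siRNA come from") counts phased reads and
sense non-phased reads. An antisense, off-register locus read is treated
as the mapping footprint of an sRNA bound to its target site — a perfectly
complementary trigger necessarily maps antisense over its own target — and
establishes neither derivation nor siRNA candidacy. The network is a
directed sRNA → locus graph with typed edges (initiator/cis/trans/target),
serialised as a sorted edge list and GraphML; cycles are legal, since
cascades can loop.

## Differential expression

Kal's pooled two-proportion Z-test compares each sequence's raw counts
against library totals per pair of libraries (RPM is descriptive only):
z = (p̂_a − p̂_b)/√(p₀(1−p₀)(1/N_a + 1/N_b)), two-sided normal p, with
p = 1 by convention when the pooled proportion is degenerate. p-values are
Benjamini–Hochberg corrected per pair (own step-up implementation with
enforced monotonicity; cross-checked against statsmodels). Categories:
**significant** (q < 0.05 in ≥ 1 pair), **likely** (not significant, but
≥ 5 RPM in some library and ≥ 2-fold RPM change in some pair; a zero
denominator uses a 0.1-RPM floor and is flagged), else **ns**. Significant
sequences are row-standardised (sample sd, n−1; constant rows → 0) and cut
from a complete-linkage Euclidean tree into k = 5 expression groups
(configurable).

## The synthetic-data generator

The generator defines the study conditions; defaults are one fixed choice,
not a tuning surface. It emulates:

* **Hairpins** (30): random matures of 20–24 nt (21 nt dominant), GC
  0.42–0.68, embedded as mature–loop–star (arm order alternating) with a
  requested duplex mismatch count 0–2, mismatch bases chosen so they
  cannot pair or slip, and ~2 Watson–Crick pairs converted to G:U wobbles.
  Real duplexes carry wobbles; they also keep the star from being a
  verbatim reverse complement of the mature, which would make every mature
  read cross-map antisense onto its own star arm — an artifact no real
  locus shows. Each candidate precursor is verified by the fold backend to
  pair exactly len−mismatches mature bases against the star and to reach
  MFE ≤ −32 kcal/mol, with rejection sampling otherwise.
* **PGTs** (15 transcripts of 560 nt): a trigger target site (reverse
  complement of the trigger) placed so the 10/11 cleavage position equals
  the register start, sense phased 21-mers every 21 nt (8–10 cycles),
  antisense phased reads at the +2 offset, plus a few off-register
  non-phased reads. Ten transcripts have a miRNA initiator; three add a
  second register set by one of their own phased siRNAs (cis); two are
  triggered by a phased siRNA from another PGT (trans).
* **isomiRs**: 2–3 per hairpin with end offsets in {−2..2}, 3′-only
  variants twice as likely as 5′-only, at 5–12 % of the mature's weight.
* **Tissue effects**: 16 planted 4-fold changes (up or down, one library
  each) across matures and siRNAs.
* **Background** (35 % of each library): reference substrings with a
  24-nt-dominated length profile, drawn with 8× per-nt weight from twelve
  dedicated 2-kb repeat-like contigs. This mirrors real libraries, where
  heterochromatic 24-nt siRNAs concentrate on repeats rather than on miRNA
  precursors; smearing the background uniformly over a desk-sized
  reference would bury every locus under antisense coverage that a
  gigabase genome never produces per locus.

Counts are negative-binomial around the planted expectation (dispersion
0.1) with one RNG stream per library (seed + library index), at 100,000
reads per library across leaf/flower/boll. The manifest (JSON,
lossless round-trip) records every planted coordinate, sequence, weight
and effect and is the recovery oracle.

What the generator does **not** emulate: sequencing error, adapters,
non-templated tailing, mismatch mapping, hc-siRNA/nat-siRNA biogenesis,
replicate structure (one library per tissue, as in typical atlas designs),
and genome-scale repeat complexity. Passing recovery tests therefore
demonstrates the pipeline's correctness on clean planted signal plus
realistic background — not its behaviour on degraded or contaminant-rich
real libraries.

Because libraries are drawn with biological overdispersion, many
non-planted sequences genuinely differ between libraries; the DE stage
reporting more significant sequences than planted fold-changes is expected
behaviour, and the recovery criterion is the detection rate of the planted
effects.

## Numerical and design choices

* All cited thresholds compare inclusively (≥/≤) except the phasing
  p-value (strictly < 0.01) and PGT strand bias (strictly < 0.9), matching
  their stated senses; the boundary behaviour of all eleven thresholds is
  pinned by tests.
* Hypergeometric tails come from `scipy.stats.hypergeom.sf`; tests compare
  them to exhaustive subset enumeration (M ≤ 12) and to exact integer
  combinatorics (M ≤ 40) at 1e-9.
* Ties in register selection break to the smallest register; candidate
  windows deduplicate per anchor; all outputs are sorted, so identical
  config + seed reproduce a run byte-for-byte (no timestamps in outputs).
* Stage caching keys on a hash of the config section; a completed stage
  with unchanged inputs is a no-op.
* Problem sizes in the default study (100k reads/library, desk-scale
  reference) keep a full run at roughly half a minute on one CPU while
  leaving every planted signal at realistic relative abundance.

## Known limitations

Exact matching only (no mismatch mapping mode); miRBase-style family
naming is not attempted; translational-inhibition target sites are not
modelled; 22-nt-trigger enforcement and AGO-sorting rules are out of
scope; the phasing statistic treats occupancy as binary, so a single
highly-degraded transcript with dense uniform coverage is handled by the
filters, not the statistic.
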