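# Methods

This note documents the models, defaults and numerical choices behind
`igstyper`, and what its synthetic validation does and does not demonstrate.

## The marker and the decision rule

The assay types a specimen from a single PCR product spanning tRNA-Ile to
tRNA-Met of the mitogenome. Animal mitochondrial tRNAs are conserved
("tRNA punctuation"), while the intergenic spacers between them drift fast,
so the amplicon is a fixed 154 bp anchor scaffold (56 + 69 + 29 bp) holding
two variable spacers. The primary evidence is the length of IGS-I
(tRNA-Ile → tRNA-Gln): 40 bp (*C. capitata*), 2 bp (*C. cosyra*), 62–64 bp
(*C. quilicii*), 34 bp (*C. rosa*), absent (*B. dorsalis*).

**Window matching.** A measured length is compared against each species
window expanded by a symmetric tolerance (default 1 bp, absorbing a single
indel-type sequencing error; within-species IGS-I length is otherwise
stable). Two refinements keep the expanded windows pairwise disjoint and the
calls honest near zero:

* an *absence* window (0 bp) never expands — absence is a qualitative state,
  not a length with measurement error;
* a positive window never expands below 2 bp — a single observed base
  between the anchors is within one sequencing error of absence and is never
  treated as length-diagnostic (such reads fall through to the identity
  fallback instead of being forced into the *C. cosyra* or *B. dorsalis*
  bin).

With the default tolerance every length maps to at most one species; the
classifier therefore returns `unambiguous` or `no_call` from lengths alone,
and `ambiguous` only arises from IGS-II conflicts or the identity fallback.

**IGS-II.** Published windows exist only for *C. quilicii* (16–18 bp) and
*C. rosa* (18–22 bp), and they overlap at 18 bp, so IGS-II can never decide
between them. It is used solely to corroborate: an IGS-I call for a species
with a published IGS-II window is downgraded to `ambiguous` when the
measured IGS-II length fits a *different* species' window and not its own.

**Identity fallback.** When the length gives no call (or anchoring fails)
and a reference panel is present, the query is compared to one reference
amplicon per species by global-alignment identity (gap columns in the
denominator). The call is `unambiguous` only if the best identity is
≥ 90% *and* beats the runner-up by ≥ 2.0 percentage points. The margin is
deliberately conservative — the reported *C. quilicii* vs *C. rosa*
whole-amplicon gap is ≈ 15 points — and the absolute floor is standard
nearest-neighbour barcoding practice; together they make junk queries
structurally unable to produce a confident call. Confounder taxa known to
share high whole-amplicon identity with a called species (e.g.
*C. fasciventris* 100%, *B. invadens* 99.51%) are attached to every
confident call as caveats; they never veto a call, since none except
*C. quinaria* occurs in South Africa.

## In-silico PCR

Primer sites are found by sliding-window comparison under IUPAC semantics
(bases match iff their code sets intersect), vectorised over all start
positions; circular templates are scanned over the doubled sequence with
starts reported modulo the length, so origin-spanning sites and products are
found exactly. Defaults: ≤ 3 mismatches per primer, and no mismatch in the
last 5 bases (3'-end fidelity is what makes a polymerase extend); both are
assay-design conventions rather than published values. Products pair a
forward-primer site with an opposite-strand reverse site within 2000 bp;
multiple products are returned flagged rather than raised, since a clean
assay yields one band and multiplicity signals a bad template. Melting
temperatures are not computed (the published Tm values are specific to the
primer-design software used there).

## Anchor alignment

Dissection aligns the three tRNA references with Needleman–Wunsch variants
(match +1, mismatch −1, gap open −2, gap extend −1): ile pinned to the
amplicon 5' end with a free 3' target end, met mirrored, and gln free at
both ends but restricted to the interior between them — this removes
placement ambiguity when IGS-I is 0–2 bp. An anchor must reach 0.80
identity (matches / alignment columns, gaps and trimmed reference bases
counted); conserved tRNAs sit far above this and random sequence far below,
so the threshold separates anchor from background rather than tuning
sensitivity. Equal-score placements are resolved by preferring the
indel-free span (target span = reference length; substitutions alone can
never move a boundary) and then the leftmost start — without this rule a
substitution at a spacer/anchor boundary can create a score tie whose
arbitrary winner shifts the measured spacer length by 1. Orientation is
auto-detected by anchoring both strands and keeping the higher total score.

## Synthetic data

The generator exists so every downstream stage is testable without
downloads. It emulates:

* the amplicon architecture (56/69/29 bp anchors with the Mito_F footprint
  opening the ile segment and the Mito_R reverse complement closing met);
* per-species spacer lengths drawn uniformly from the published windows;
  species without a published IGS-II length get simulator-only defaults
  (*C. capitata* 19, *C. cosyra* 19, *B. dorsalis* 62 — the last forced by
  the published primer coordinates, which imply a 216 bp product);
* AT-rich composition (defaults per species from the assembled-genome
  statistics, 73.6–77.4% AT);
* toy circular genomes: the amplicon embedded at a seeded random rotation in
  filler screened to contain no secondary primer site within 3 mismatches;
* Sanger-style noise: independent per-base substitution/insertion/deletion
  with a full edit log.

Because the real tRNA and spacer sequences are not reproduced here, the
anchor segments are fixed per-genus pseudo-sequences (one Ceratitis set, one
Bactrocera set, ≈ 90% mutually identical, mirroring tRNA conservation), and
each species' spacer is a fixed canonical random-generated constant
truncated to the drawn length — within-species sequence consistency is what
makes the identity fallback meaningful, and is what the real marker shows.
Consequences: passing synthetic tests demonstrates the *geometry* of the
method (site finding, dissection exactness, length calling, noise
tolerance), not sequence-level fidelity to the real accessions; real-mode
runs must take tRNA references from the input GenBank annotation
(`trna_refs_from_annotation`), and real identity panels from user-supplied
accessions. The generator draws only from the published length windows; true
intraspecific sequence variants are not modelled. No chromatogram/quality
simulation, no PCR chimeras.

All randomness fans out from one integer seed as
`SeedSequence([seed, stream_id])` with a fixed stream id per operation, so
any run is reproduced exactly by (config, seed).

## Problem sizes and defaults used in validation

The shipped tests use 20 seeds × 5 species for exactness round trips, 200
amplicons at sub 1% / ins 0.2% / del 0.2% for noise robustness, 50 random
templates up to 5 kb against the brute-force scanner oracle, and 100
simulated 16 kb genomes for composition; the acceptance script mirrors these
at the same or smaller sizes. These run in seconds on one CPU.

## Known limitations

* Percent identities printed by BLASTn for the confounder taxa are stored as
  metadata, not recomputed: alignment parameterisation differs and bit-exact
  reproduction is not attempted.
* Tolerance-expanded windows assume at most ~1 bp of length error; heavily
  degraded reads route through the identity fallback or end as `no_call`.
* Real tRNA boundary conventions (annotation pipelines differ by ±1–2 bp)
  can shift real-data spacer lengths; the published lengths are taken as
  ground truth for the deposited accessions.
* Melt-curve (HRM) classification is out of scope — reported unsuccessful
  for this amplicon due to low GC — as are mitogenome assembly and
  annotation themselves.
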