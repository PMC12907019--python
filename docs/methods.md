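# Methods

## Coordinates and formats

All intervals are 0-based half-open internally, so `length = end − start`
everywhere. 1-based inclusive dialects (RepeatMasker `.out`, UCSC-style
tables, printed locus strings of the form `chr1:48 138 333–48 140 169`) are
converted on read by decrementing the start; printed locus strings are taken
verbatim with digit-group separators stripped, with no ±1 adjustment, which
makes `end − start` equal the printed lengths of such captions exactly.

The canonical on-disk format is a BED6+4 dialect (chrom, start, end,
record_id, score=0, strand, family, superfamily, destruction, repeat_class),
chosen so that a record round-trips field-for-field; destruction is an empty
field when absent. Chromosome names are matched exactly after trimming — no
`chr`-prefix repair — so naming mismatches between inputs surface as zero
overlaps rather than being silently patched. Records with identical
(chrom, start, end, family) are kept as distinct records with a logged
warning; deduplication is a curation decision this package does not make.

HERVd-style TSVs may carry either a `destruction` column (consumed directly)
or a `completeness` column, converted as `destruction = 100 − completeness`;
the conversion is logged because the exact complement relation is a modelling
assumption, not a documented identity.

## Classification

Superfamily assignment (ERV1, ERV2, ERV3, Gypsy, Unclassified) is a pure
table lookup on the family name, exact and case-sensitive after trimming.
`-int` suffixes are never auto-stripped: LTR and internal-portion names are
biologically distinct entries and the mapping table must list both. Families
flagged `ignored` in the table (orphan internal portions or LTR types with no
known partner) and families absent from it are governed by one policy switch:
labelled `Unclassified` (default, safe for third-party data) or dropped
(reproducing a filtering-style pipeline). The audit object reconciles exactly
— assigned + unmapped + ignored = input count — and is the place to look when
two sources disagree on classification rather than coordinates.

## Matching

Overlap discovery is a strand-blind interval join (pyranges) returning every
cross-source pair intersecting by ≥1 bp; a half-open touch is not an overlap.
Pairs are scored with `Sov = (minov + δ)/maxov`. Both δ conventions are
implemented:

* `as_printed`: δ = min(maxov − minov, minov, len₁, len₂);
* `half_capped` (default): δ = min(maxov − minov, minov, len₁/2, len₂/2),
  with real-valued halves (no flooring — flooring is indistinguishable at
  reported precision but the exact form keeps the containment closed form
  clean).

Containment closed forms, used as test oracles: for a ⊆ b, Sov = 1 iff
len(a) ≥ len(b)/2 under `as_printed` and iff len(a) ≥ ⅔·len(b) under
`half_capped`. The default is `half_capped` because it is the variant under
which a ~300 bp-shifted ~2 kb locus pair scores ≈0.8 rather than 1.0, i.e.
the variant that actually discriminates in the shifted-boundary regime; every
report records the variant used.

The match rule is `(Sov ≥ 1) ∨ (minov ≥ 0.95·min(len₁, len₂))` with the
secondary criterion switchable. Matching ignores strand and family identity;
matched pairs whose two records carry different superfamilies are counted as
a diagnostic (`cross_superfamily_matches`) rather than excluded, since
coordinate-only matching is the point of the comparison.

Counting is per record: a record is "matched in Y" when it has ≥1 matching
partner there, so many-to-one links (one merged record vs several fragments)
contribute asymmetric off-diagonal counts by design. Three-way decomposition
per source: shared-in-all = matched in both other sources; unique = matched
in neither; the remainder is matched-in-exactly-one, and the three always sum
to the source total. Reported bp totals are sums of matched-record lengths;
merged-union coverage is available as a separate mode but is not the
reporting default (summed lengths is the reading consistent with per-record
tables; RepeatMasker-style annotations rarely self-overlap, so the two modes
differ little in practice).

## Summary statistics

Length histograms use uniform half-open bins (default 100 bp) up to an
overflow threshold (default 2500 bp); "longer than" is strict, so a record of
exactly the threshold length stays binned and counts + overflow always equal
n. Destruction summaries are computed only over records carrying the
attribute, with n reported alongside; quantiles use linear interpolation
between order statistics (numpy default) throughout, including the
destruction-vs-length quartile table. Mb values are bp/10⁶ to one decimal.
Destruction histograms default to 2-percentage-point bins.

## Synthetic data generator

The generator emulates the data structure the matching procedure has to
survive, not the human genome's family composition:

* **Elements and archetypes.** 10 000 elements by default, split across the
  five superfamilies roughly in proportion to their prevalence in human
  annotation (ERV1 2500, ERV2 200, ERV3 6300, Gypsy 400, Unclassified 600).
  Lengths follow a three-archetype mixture — short degraded fragments
  (truncated-exponential on 50–250 bp, scale 40 bp; weight 0.35), solo LTRs
  (normal modes at 250 and 450 bp, sd 25/40; weight 0.45) and long
  internal/proviral elements (lognormal, mode 1600 bp, capped at 9 kb;
  weight 0.20). The exponential decay of the short archetype matters: a
  uniform law would flood the 200–300 bp bin's left neighbour and erase the
  characteristic bimodal short-length structure the defaults are required to
  show.
* **Fragmentation.** Elements with a core of ≥500 bp fragment with
  probability 0.30 into 2 + Poisson(0.8) collinear pieces (each ≥30 bp,
  uniform split) separated by 50–600 bp gaps. Short solo LTRs are detected
  whole in real pipelines — insertions disrupt long elements — so
  fragmentation is gated on length; the 30% rate applies to the eligible
  (defraggable) elements, making the merged-vs-fragments phenomenon common
  (several hundred fragmented elements per run at default size).
* **Sources.** `M` (merged/HERVd-like) emits one record per element spanning
  all fragments *including gaps*, so a multi-fragment element's merged length
  strictly exceeds the sum of its fragment lengths; `M` alone carries
  destruction. `F1`/`F2` emit one record per fragment with N(0, 5 bp)
  boundary jitter and, with probability 0.02, a whole-record ±300 bp shift
  (the shifted-boundary failure mode). Each source drops records with
  probability 0.02 and receives 200 injected source-only records placed in a
  reserved genomic zone, so truth-based precision is well defined.
* **Destruction.** Two-component Beta mixture on [0, 100]: Beta(2, 5)·100
  (low mode, mean 25) for long records, Beta(8, 2)·100 (high mode, mean 80)
  for records ≤250 bp with probability 0.85. Filtering at >250 bp therefore
  removes the high mode — the behaviour the destruction summaries must
  reproduce.
* **Determinism.** One root seed feeds named substreams (placement, lengths,
  fragmentation, jitter, shift, dropout, destruction, uniques) via spawned
  `SeedSequence`s, so identical parameters give byte-identical files and
  single-stage experiments can vary one stream's parameters without
  disturbing the draws of another stage.
* **Placement.** Elements are laid out left-to-right in shuffled order with
  200–2000 bp inter-element gaps over a 4 × 20 Mb genome; inter-element
  overlap is structurally impossible (nested repeats are out of scope for the
  default generator), and an undersized genome raises rather than truncates.

What passing tests on this generator show: the matching criteria behave as
designed under fragmentation, jitter, shift, dropout and uniques. What they
do not show: robustness to nested/overlapping repeats, non-Gaussian boundary
error, family-composition realism, or assembly-specific artefacts of real
annotation tracks.

## Recovery scoring

For each source pair, sensitivity is the fraction of planted elements
represented by ≥1 record in both sources for which at least one matched
record pair links records of the same element; precision is the fraction of
matched record pairs linking same-element records. Under noiseless
conditions both are exactly 1.0 by construction; sensitivity decreases
monotonically in jitter and shift magnitude, and the combined criterion
strictly dominates Sov-only matching whenever fragmentation is present.

## Problem sizes

The test suite exercises the generator at two scales: a ~1000-element triple
for structural checks and the full default 10 000-element conditions for
distribution-shape and recovery assertions; the brute-force overlap oracle
runs on 100 random fixtures of up to 500 records per side. These sizes were
chosen as the smallest at which the asserted distributional features are
stable across seeds.

## Known limitations

* Real HERVd defragmentation is semimanual; the generator models its output
  structure (gap-inclusive merged spans), not the curation process.
* Destruction is consumed/simulated as a per-record attribute, never
  recomputed from consensus alignments.
* No liftover: all inputs must be on one genome build, enforced by label.
* The family→superfamily table is data, not code; the shipped
  `default_family_map` only covers the generator's synthetic family names.
  Real analyses must supply a curated table.
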