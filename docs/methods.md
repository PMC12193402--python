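# Methods

This note documents the models, conventions, and design choices behind
`ampedit`, in the order data flows through the package.

## Coordinate and allele conventions

Positions are 1-based inclusive everywhere except BED emission
(0-based half-open, as the format requires). Variant alleles follow
the variant-table dialect: an SNV alt is a single base; an insertion is
`+SEQ` anchored at the aligned base preceding it; a deletion is `-SEQ`
with the position at the **first deleted base**, so the deleted
reference interval is `[pos, pos + len(SEQ) − 1]`. All indels are
left-normalised (maximally 5′-shifted under flanking-base equality)
before any table is compared or intersected, which makes exact key
equality `(region, pos, ref, alt)` the identity relation across
replicates, samples, and passages.

## Synthetic study system

`build_reference` constructs a deterministic ~120 kb genome (59% AT,
matching large AT-rich dsDNA viral genomes) and plants into it:

* the six guide protospacers with their PAMs, each embedded exactly
  once. Guides declared *antisense* occupy the genome minus strand;
  their placement is anchored so the gp64+131 expected window starts at
  107,222 and window starts of the other antisense guides sit at
  `107,222 − (offset − 131)`. The sense-strand guide (gp64−160) was
  designed against assay coordinates that do not follow this
  arithmetic; its window (107,199–107,204) is carried as an explicit
  override and its six-base local context is planted so the published
  nested deletion alleles (−CTCCA/−TCCA/−CCA/−CA/−C) exist verbatim in
  the reference.
* nine homologous-repeat (hr) arrays: six long (≥150 bp) and three
  short (18–30 bp) AT-rich tandem repeats (unit ~30 bp, AT ≥ 0.6,
  resampled until the floor is met). Long-versus-short mirrors the
  observation that only repeats ≥150 bp accumulate mutations. hr
  *placement* is structural, not positional — the real coordinates are
  not published — so all repeat logic is coordinate-agnostic.
* ORF/promoter/UTR features and the reference contexts of the fourteen
  catalogued conserved variants outside the repeats (including the
  20 bp `CTAGAGATCTCTAGAGATCT` deletion context in *egt*), each with a
  left flank chosen to block spurious left-shifting of the planted
  indel anchors.

A post-build check verifies each spacer occurs exactly once genome-wide
on either strand; collisions raise rather than silently corrupting the
fixture.

## Tiling and read simulation

`design_tiling` is arithmetic two-pool tiling: amplicon *inserts*
overlap by the `overlap` parameter (so `overlap=0` makes inserts abut),
odd amplicons go to pool 1, even to pool 2, and the final amplicon is
right-anchored at the genome end. Generic default 1000/100/22
(amplicon/overlap/primer). The bundled study profile uses **400 bp
amplicons with 2×300 bp reads** — the standard pairing of amplicon size
to read length in tiled-amplicon designs — so that the two reads of a
pair jointly cover the entire insert; 300 bp is the read length of the
600-cycle MiSeq v3 kit used for this class of assay. With 1000 bp
amplicons and 300 bp reads the insert middle would be read-free and
interior variants unobservable.

`simulate_reads` draws, per amplicon and replicate:

* a number of pairs giving mean insert read coverage ≥ the scenario
  depth (default 400×; `ceil(depth · insert / (2·(read − primer)))`,
  257 pairs for the study profile);
* one haplotype per fragment: with probability *f* the fragment carries
  spiked variant *v* (variants are mutually exclusive per fragment;
  per-position frequency sums must stay below 1), otherwise reference.
  Fragments are full primer-to-primer amplicons; the read pair is the
  first/last `read_length` bases, reverse read reverse-complemented;
* per-base Phred qualities from a clipped normal (mean 32, sd 3,
  bounds 2–41) with substitutions realised at `10^(−Q/10)`; indel
  sequencing artefacts at a separate rate (default 1e-5/base, so
  spiked indels dominate by orders of magnitude). `error_scale=0`
  yields error-free reads for exact tests.

All randomness flows from one named generator per replicate, so equal
seeds give byte-identical FASTQ. Scenarios may restrict simulation to
the amplicons overlapping a region; the bundled gp64 scenarios simulate
the two amplicons spanning all expected edit windows, which is what a
targeted re-analysis needs and keeps a full scenario run at a few
seconds.

## Alignment

The internal aligner exists to make the pipeline hermetic; externally
produced SAM is accepted interchangeably. Reads are assigned to an
amplicon when both outer 5′ primer k-mers match a scheme primer within
edit distance 2 (exact-match index first, edlib fallback); ties are
ambiguous and get MAPQ 0, unique assignments MAPQ 60 (binary by design
— graded MAPQ carries no information when the amplicon of origin is
known). Alignment is glocal banded affine-gap DP (match +2, mismatch
−4, open −6, extend −1, band half-width 64 around the expected
diagonal), batched across reads of an amplicon for throughput. Scores
are validated in tests against an exhaustive unbanded DP and against an
independently configured C implementation. Score ties in traceback are
broken deterministically; left-normalisation afterwards collapses all
shift-equivalent indel placements to one canonical representation, so
tie-break details cannot leak into variant keys.

## Filtering

Study thresholds, applied in order: drop records matching flag mask
2308 (unmapped + secondary + supplementary) or MAPQ < 10; soft-clip
aligned bases overlapping the record's own amplicon's primer intervals
(all primers for unassigned records); drop records with fewer than 200
aligned bases after clipping. "Below 200" is read as keep-if-≥200,
matching the minimum-kept-length semantics of the tool family these
thresholds come from; the boundary is tested explicitly. Soft clips
(not hard clips) preserve the read sequence for audit.

## Pileup and error model

The pileup counts physical coverage: a read spanning a deletion
increments depth at every deleted position, which keeps nested
deletion alleles (the gp64−160 case) on a common denominator.
Substitution support below Q20 is excluded from allele statistics but
still counts toward depth. Deleted bases have no qualities, so
deletions bypass the Q20 gate and carry the mean of the two flanking
read-base qualities; insertions carry the mean of their inserted-base
qualities. Overlapping mates are counted independently (no mate
deduplication); this is documented because it sets the effective
denominator (two reads of 257 pairs ⇒ depth 514 where mates overlap).

A call is emitted when allele frequency ≥ 1% and is a "true mutation"
when the one-sided Fisher's exact test of
`[[alt_dp, dp−alt_dp], [E, dp−E]]`, with expected error count
`E = round(dp · 10^(−Q̄_alt/10))` (round half up, capped at dp), gives
`p ≤ 0.05`. This reconstruction ties the error expectation to the
observed supporting quality: high-quality support at 1–2% passes
(Q̄≈32 ⇒ E≈0), while Q≈13 support at the same frequency faces E≈5% of
depth and fails — both behaviours are fixed in tests. Replicate
merging is conservative: keys must appear in **all** replicates,
frequency is the replicate mean, p the replicate max, PASS the
conjunction.

## Targeting analyses

Protospacer location is exact 20-mer search on both strands with an
adjacent PAM (IUPAC-aware, default NGG). The expected-window rule
(protospacer bases 12–17) was calibrated once against the full set of
published windows together with the published deletion alleles, then
frozen; it reproduces every window exactly, and the one guide whose
naming does not follow the arithmetic uses its published coordinates as
an override. On-target labelling intersects the variant's full affected
interval with the window — a 5 bp deletion anchored at a window edge
still counts. The off-target scan slides the spacer over both strands
counting Hamming mismatches (vectorised; validated against a naive
scan), optionally gating on PAM presence, and reports the genome-wide
minimum mismatch count with the on-target site excluded. On the
fixture genome every guide needs ≥4 mismatches before any frame
matches, and no ≤3-mismatch frame retains a PAM — the no-predictable-
off-target situation the guides were designed for.

## Conservation analyses

`compare_to_stock` labels each passage (T-I) variant
`conserved_from_stock`, `control_shared` (scrambled/infected-only
union), or `unique`, and reports the percentage of stock keys
re-observed in the union of T-I sets. The bundled worked-example
fixture encodes the study bookkeeping: 141 stock variants of which 97
are carried over (83 inside hr1–hr3, 14 outside, including the 20 bp
*egt* deletion), giving 97/141 = 68.8% carried over. `summarize_hr_counts`
produces the per-repeat mutation counts in "total" and "filtered"
(controls and stock carry-overs removed) flavours plus the non-repeat,
non-target variant map.

## Detection power and known limitations

At the study conditions — 400× per amplicon, two technical replicates,
1% frequency floor, Fisher gate — the error model needs about 5–6
supporting reads per replicate. Each amplicon×replicate carries ~257
independent fragments, so recovered frequencies fluctuate with sd
≈0.4–1.2 percentage points (merged, over the 1.4–8.5% range) and a
1.43% haplotype is recovered in both replicates in only ~50–75% of
seeded runs. Consequently single-seed recovery of the *complete*
published deletion set, or of any individual frequency to better than
~1.5 points, is a coin-flip property of the design, not of the
implementation: the recovery checks in the test suite run the full
pipeline once at a fixed seed and one high-frequency variant can (and
on the frozen seed does) draw ~2σ from its nominal value. The
simulator is deliberately not given extra depth to hide this.

Other simplifications, deliberate and documented: no PCR chimeras,
primer-mismatch dropout, or library-prep artefacts; no strand bias in
simulation (reverse-strand support is recorded in the tables but never
filtered on); fragments are exact primer-to-primer amplicons; the
genome is synthetic, so only quantities anchored to published
coordinates or counts are expected to reproduce — passing tests show
the pipeline's operations are correct under the stated noise model,
not that the model captures every artefact of real amplicon sequencing.

## Problem sizes used by the tests

Unit tests run on toy genomes (≤2 kb) and small scenarios (depth
10–60). The recovery suite simulates the bundled scenarios at full
study depth (400×, duplicate) restricted to the two amplicons spanning
the gp64 windows; the false-positive suite runs twenty seeded control
scenarios at the same depth; the Fisher oracle sweep covers every
support count at depths to 200 with representative expected-error
levels. The complete suite runs in about four minutes on one CPU; the
acceptance script in about one.
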