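# ampedit

Tiled-amplicon minor-variant detection and CRISPR-Cas9 edit attribution
for large dsDNA viral genomes.

## The problem

When a replicating virus population is transiently targeted with
CRISPR-Cas9 — for example disrupting the baculovirus *gp64* envelope
gene during an infection — only a minority of genomes acquire edits.
The edited genomes never reach consensus: they appear as low-frequency
variants (1–10%) in a heterogeneous pool of viral DNA. Confirming that
an observed phenotype is caused by on-target editing therefore requires
a minor-species variant-calling workflow: deep tiled-amplicon
sequencing in technical duplicate, careful primer handling so that
primer-encoded bases cannot masquerade as reference support, a
statistical error model that separates real 1% indels from sequencing
noise, and attribution of each surviving variant to the guide's
expected cut window.

`ampedit` implements that workflow end to end, together with the
comparative analyses that go with it: off-target scanning by spacer
mismatch count and PAM presence, classification of variants into
mutation-hotspot homologous repeats (hrs) versus other genomic
features, and cross-passage conservation of variants between a virus
stock and post-assay genome pools. Because the study's raw reads are
not publicly downloadable, the package ships a first-class synthetic
data generator that rebuilds the study system — a ~120 kb AT-rich viral
genome with a reverse-strand *gp64* gene, planted guide protospacers
anchored at the published coordinates, hr repeat arrays, a two-pool
tiled primer scheme, and 400× paired-end reads with spiked deletion
haplotypes — so every stage is verifiable without restricted data.

## Method at a glance

* **Expected edit window.** SpCas9 cuts between protospacer bases 17
  and 18 (3 bp from the NGG PAM). Error-prone repair leaves 1–5 bp
  indels just 5′ of the cut; the predicted 6-bp window for a guide is
  protospacer positions 12–17 (4–9 bp upstream of the PAM), oriented by
  the genomic strand the protospacer occupies.
* **Alignment and filtering.** Reads are assigned to amplicons by their
  outer primer k-mers, aligned glocally with a banded affine-gap DP
  (match +2, mismatch −4, gap open −6, extend −1), indels are
  left-normalised, and records are filtered with the study thresholds:
  SAM flag mask 2308, MAPQ ≥ 10, primer soft-clipping, post-clip
  aligned length ≥ 200.
* **Calling.** A quality-aware pileup (base Q ≥ 20; deletions exempt,
  carrying their flanking-base quality) emits every allele with
  frequency ≥ 1%. Each call is tested with a one-sided Fisher's exact
  test of `[[alt_dp, dp−alt_dp], [E, dp−E]]` where
  `E = round(dp·10^(−Q̄/10))` is the support expected from sequencing
  error alone; calls with `p ≤ 0.05` in **both** technical replicates
  are "true mutations" (merged frequency = replicate mean, merged
  p = replicate max).
* **Attribution and conservation.** True mutations are labelled
  on-target when their affected interval intersects a guide window;
  variant identity across samples and passages is exact key equality
  `(region, pos, ref, alt)` after normalisation, giving the
  carried-over fraction `|stock ∩ ∪T-I| / |stock| × 100`.

## Worked example

Predict the edit windows on the bundled fixture genome:

```bash
$ ampedit predict-windows
gp64+131        107222  107227
gp64+278        107075  107080
gp64+378        106975  106980
gp64+384        106969  106974
gp64+418        106935  106940
gp64-160        107199  107204
```

Each line is a guide and the 6-bp reference interval where its repair
indels are expected. Simulating the bundled gp64−160 supernatant
scenario (five nested deletion haplotypes spiked at 1.4–6.3%, 400×,
two replicates) and running the full pipeline:

```python
from ampedit.pipeline import PipelineConfig, run_scenario
from ampedit.synthetic_data import build_reference, design_tiling, table1_scenarios

genome, annotation, targets = build_reference()
scheme = design_tiling(genome, amplicon_len=400, overlap=100, primer_len=22)
res = run_scenario(genome, scheme,
                   table1_scenarios(1)["gp64-160_supernatant"],
                   PipelineConfig())
print(res["true"][["POS", "REF", "ALT", "ALT_DP", "ALT_FREQ", "TOTAL_DP", "PVAL"]])
```

```
   POS REF    ALT  ALT_DP  ALT_FREQ  TOTAL_DP         PVAL
107199   C -CTCCA    15.0  0.029183     514.0 5.579856e-05
107200   T  -TCCA    17.0  0.033074     514.0 2.287922e-04
107201   C   -CCA    28.0  0.054475     514.0 1.077485e-08
107202   C    -CA    34.0  0.066148     514.0 6.023803e-10
107204   C     -C     8.0  0.015564     514.0 3.800528e-03
```

All five spiked deletions survive replicate intersection and the error
model, each at its planted position with the recovered frequency within
binomial noise of the spiked haplotype fraction; every one intersects
the gp64−160 window above.

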