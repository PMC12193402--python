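"""Published study inputs: sgRNA spacers, expected edit windows, observed
gp64 deletions, and the conserved-variant catalogue.

These values are the experiment definition consumed by the synthetic-data
generator and the bundled scenario writer. Coordinates are 1-based inclusive
on the reference plus strand; deletion alleles are written ``-SEQ`` with the
position at the first deleted base, insertions ``+SEQ`` anchored at the base
preceding the inserted sequence.
"""

from __future__ import annotations

# sgRNA spacers (5'->3') with their PAMs.  "antisense" targets sit on the
# genome minus strand (the target gene reads right-to-left); the one "sense"
# target sits on the plus strand.
SPACERS = {
    "scrambled": {"spacer": "CACCTTGAAGCGCATGAACT", "pam": None, "strand": None},
    "gp64+131": {"spacer": "GGAAACGCTGCAAAAGGACG", "pam": "TGG", "strand": "antisense"},
    "gp64-160": {"spacer": "GTTGTAGTCCGTCTCCACGA", "pam": "TGG", "strand": "sense"},
    "gp64+278": {"spacer": "AACGCTGAATGTGGGCAAAG", "pam": "AGG", "strand": "antisense"},
    "gp64+378": {"spacer": "GACTGTTTTCGCGACAACGA", "pam": "GGG", "strand": "antisense"},
    "gp64+418": {"spacer": "AAGGCAAAGAGTTGGTGAAG", "pam": "CGG", "strand": "antisense"},
    "gp64+384": {"spacer": "TTTCGCGACAACGAGGGCCG", "pam": "CGG", "strand": "antisense"},
}

#: Expected 1-5 bp indel windows, 1-based inclusive.
EDIT_WINDOWS = {
    "gp64+131": (107_222, 107_227),
    "gp64-160": (107_199, 107_204),
    "gp64+278": (107_075, 107_080),
    "gp64+378": (106_975, 106_980),
    "gp64+418": (106_935, 106_940),
    "gp64+384": (106_969, 106_974),
}

#: The sense-strand target does not follow the offset arithmetic of the
#: antisense targets; its window is carried as a printed-coordinate override.
WINDOW_OVERRIDES = {"gp64-160": (107_199, 107_204)}

#: Observed true gp64 deletions per target and gDNA fraction:
#: (position, deleted sequence, haplotype frequency).
OBSERVED_DELETIONS = {
    ("gp64+131", "cell_pellet"): [(107_222, "C", 0.0662)],
    ("gp64-160", "cell_pellet"): [
        (107_201, "CCA", 0.0630),
        (107_202, "CA", 0.0847),
    ],
    ("gp64-160", "supernatant"): [
        (107_199, "CTCCA", 0.0305),
        (107_200, "TCCA", 0.0348),
        (107_201, "CCA", 0.0544),
        (107_202, "CA", 0.0634),
        (107_204, "C", 0.0143),
    ],
    ("gp64+378", "cell_pellet"): [(106_975, "T", 0.0451)],
    ("gp64+378", "supernatant"): [(106_975, "T", 0.0404)],
    ("gp64+418", "cell_pellet"): [(106_935, "CA", 0.0424)],
    ("gp64+418", "supernatant"): [(106_935, "CA", 0.0217)],
}

#: Reference context that must exist verbatim for the sense-strand target's
#: nested deletions (plus strand, starting at the key position).
SENSE_TARGET_CONTEXT = (107_198, "GCTCCAC")

#: Conserved variants outside the homologous repeats: label of the harbouring
#: feature, feature class, ref allele, alt allele, position.
CONSERVED_OUTSIDE_HR = [
    ("AcOrf-84-promoter", "promoter", "G", "T", 71_443),
    ("fgf-3UTR", "utr", "A", "G", 27_502),
    ("fgf-3UTR", "utr", "G", "A", 27_505),
    ("fgf-3UTR", "utr", "G", "A", 27_506),
    ("fgf-3UTR", "utr", "G", "A", 27_509),
    ("AcOrf-603", "orf", "C", "T", 3_960),
    ("AcOrf-1629", "orf", "G", "A", 6_375),
    ("lef10", "orf", "G", "A", 45_761),
    ("AcOrf-91", "orf", "T", "A", 78_627),
    ("AcOrf-91", "orf", "A", "T", 78_666),
    ("AcOrf-1629", "orf", None, "+GATC", 7_304),
    ("AcOrf-51", "orf", None, "+A", 44_073),
    ("egt", "orf", "CTAGAGATCTCTAGAGATCT", "-CTAGAGATCTCTAGAGATCT", 12_427),
    ("AcOrf-91", "orf", "TAT", "-TAT", 78_926),
]

#: Virus-stock variant bookkeeping: total true variants in the stock, how
#: many of them reappear after the transfection-infection passage, and how
#: many of the carried-over ones lie outside the repeat regions.
STOCK_TOTAL_VARIANTS = 141
STOCK_CARRIED_OVER = 97
CARRIED_OVER_OUTSIDE_HR = 14

#: Default anchoring of the synthetic reference: genome length and the left
#: edge of the gp64+131 edit window.
DEFAULT_GENOME_LENGTH = 120_000
DEFAULT_ANCHOR_WINDOW_START = 107_222

#: gp64 open reading frame on the fixture genome (minus strand).  The ATG
#: sits 130 bp gene-upstream of the +131 window start; the ORF spans every
#: planted protospacer.
GP64_INTERVAL = (105_816, 107_352)
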