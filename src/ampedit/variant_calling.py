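"""Quality-aware pileup construction and minor-variant calling.

A variant row is emitted for every non-reference allele reaching the
frequency floor (default 1%) built from bases at or above the quality
floor (default Q20).  Each row carries a one-sided Fisher's exact test
against the error count expected from the allele's mean supporting
quality; rows with p <= alpha (default 0.05) are flagged PASS ("true
mutations").

Conventions: positions are 1-based; a deletion allele "-SEQ" is
anchored at the first deleted base and the deleted interval is
[pos, pos+len(SEQ)-1]; an insertion "+SEQ" is anchored at the aligned
base preceding the inserted sequence.  Reads spanning a deletion count
toward TOTAL_DP at every deleted position (depth is physical coverage),
which keeps nested deletion alleles on a common denominator.  Deletions
carry no base qualities, so they bypass the per-base quality gate and
their ALT_QUAL is the mean quality of the two flanking read bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .amplicon_alignment import Alignment, FLAG_REVERSE
from .synthetic_data import Genome, _to_codes

_BASES = "ACGT"

#: iVar-compatible variant table columns.
TSV_COLUMNS = ["REGION", "POS", "REF", "ALT", "REF_DP", "REF_RV", "REF_QUAL",
               "ALT_DP", "ALT_RV", "ALT_QUAL", "ALT_FREQ", "TOTAL_DP",
               "PVAL", "PASS", "GFF_FEATURE"]


@dataclass(frozen=True)
class CallConfig:
    min_baseq: int = 20
    min_freq: float = 0.01
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.min_freq < 1:
            raise ValueError("min_freq must lie in (0,1)")


@dataclass
class PileupColumn:
    """One reference column: physical depth plus per-allele
    (count, summed quality, reverse-strand count) statistics."""
    pos: int
    ref_base: str
    total_dp: int
    alleles: dict[str, tuple[int, float, int]] = field(default_factory=dict)


class Pileup:
    """Array-backed pileup over the covered reference span."""

    def __init__(self, ref_id: str, start: int, length: int,
                 ref_codes: np.ndarray, min_baseq: int):
        self.ref_id = ref_id
        self.start = start  # 1-based genome position of column 0
        self.min_baseq = min_baseq
        self.ref_codes = ref_codes
        self.total_dp = np.zeros(length, dtype=np.int32)
        self.count = np.zeros((4, length), dtype=np.int32)
        self.qual_sum = np.zeros((4, length), dtype=np.float64)
        self.rev = np.zeros((4, length), dtype=np.int32)
        # pos -> allele ('+SEQ'/'-SEQ') -> [count, qual_sum, rev_count]
        self.indels: dict[int, dict[str, list]] = {}

    def __len__(self) -> int:
        return len(self.total_dp)

    def column(self, pos: int) -> PileupColumn:
        j = pos - self.start
        if not 0 <= j < len(self):
            raise IndexError(f"position {pos} outside pileup")
        alleles: dict[str, tuple[int, float, int]] = {}
        for b in range(4):
            if self.count[b, j]:
                alleles[_BASES[b]] = (int(self.count[b, j]),
                                      float(self.qual_sum[b, j]),
                                      int(self.rev[b, j]))
        for alt, (c, q, r) in self.indels.get(pos, {}).items():
            alleles[alt] = (int(c), float(q), int(r))
        return PileupColumn(pos=pos, ref_base=_BASES[self.ref_codes[j]],
                            total_dp=int(self.total_dp[j]), alleles=alleles)

    def positions(self) -> np.ndarray:
        return self.start + np.nonzero(self.total_dp)[0]


def build_pileup(alignments: list[Alignment], genome: Genome,
                 min_baseq: int = 20) -> Pileup:
    """Accumulate a pileup from clipped, filtered alignments.

    Substitution alleles below ``min_baseq`` are excluded from allele
    statistics but still count toward physical depth; soft-clipped
    bases contribute nothing; indel alleles are registered at their
    anchor position.
    """
    mapped = [a for a in alignments if not a.is_unmapped and a.cigar]
    if not mapped:
        raise ValueError("no mapped alignments to pile up")
    start = min(a.pos for a in mapped)
    end = max(a.reference_end() for a in mapped)
    L = end - start + 1
    pile = Pileup(genome.id, start, L,
                  _to_codes(genome.slice(start, end)), min_baseq)

    for a in mapped:
        codes = _to_codes(a.seq)
        quals = (np.frombuffer(a.quals.encode(), dtype=np.uint8)
                 .astype(np.int16) - 33)
        if len(quals) != len(codes):
            raise ValueError(f"{a.read_name}: CIGAR/quality mismatch")
        if sum(l for op, l in a.cigar if op in "MIS") != len(codes):
            raise ValueError(f"{a.read_name}: CIGAR inconsistent with read")
        is_rev = bool(a.flags & FLAG_REVERSE)
        r = a.pos
        q = 0
        for op, l in a.cigar:
            if op == "S":
                q += l
            elif op == "M":
                j0 = r - start
                seg = codes[q:q + l]
                sq = quals[q:q + l]
                pile.total_dp[j0:j0 + l] += 1
                hq = sq >= min_baseq
                idx = np.arange(j0, j0 + l)[hq]
                np.add.at(pile.count, (seg[hq], idx), 1)
                np.add.at(pile.qual_sum, (seg[hq], idx), sq[hq])
                if is_rev:
                    np.add.at(pile.rev, (seg[hq], idx), 1)
                r += l
                q += l
            elif op == "D":
                j0 = r - start
                pile.total_dp[j0:j0 + l] += 1
                alt = "-" + genome.slice(r, r + l - 1)
                lo = quals[q - 1] if q > 0 else quals[q]
                hi = quals[q] if q < len(quals) else quals[q - 1]
                rec = pile.indels.setdefault(r, {}).setdefault(
                    alt, [0, 0.0, 0])
                rec[0] += 1
                rec[1] += (float(lo) + float(hi)) / 2.0
                rec[2] += int(is_rev)
                r += l
            elif op == "I":
                alt = "+" + a.seq[q:q + l]
                anchor = r - 1
                if anchor >= start:
                    rec = pile.indels.setdefault(anchor, {}).setdefault(
                        alt, [0, 0.0, 0])
                    rec[0] += 1
                    rec[1] += float(quals[q:q + l].mean())
                    rec[2] += int(is_rev)
                q += l
            else:
                raise ValueError(f"unsupported CIGAR op {op}")
        if q != len(codes):
            raise ValueError(f"{a.read_name}: CIGAR inconsistent with read")
    return pile


def fisher_error_test(alt_dp: int, total_dp: int, alt_qual: float) -> float:
    """One-sided (greater) Fisher's exact test of observed allele
    support against the error count expected from the supporting
    quality: E = round(total_dp * 10^(-alt_qual/10)), round half up.
    """
    if total_dp <= 0:
        raise ValueError("total_dp must be positive")
    if not 0 <= alt_dp <= total_dp:
        raise ValueError("alt_dp outside [0, total_dp]")
    expected = int(np.floor(total_dp * 10.0 ** (-alt_qual / 10.0) + 0.5))
    expected = min(expected, total_dp)
    table = [[alt_dp, total_dp - alt_dp],
             [expected, total_dp - expected]]
    return float(fisher_exact(table, alternative="greater").pvalue)


def call_variants(pileup: Pileup, genome: Genome,
                  cfg: CallConfig | None = None,
                  region: str | None = None) -> pd.DataFrame:
    """Emit one row per (position, non-reference allele) at or above
    the frequency floor; rows sorted by position then allele."""
    cfg = cfg or CallConfig()
    region = region or pileup.ref_id
    rows = []

    ref = pileup.ref_codes
    cols = np.arange(len(pileup))
    cand_mask = pileup.count.copy()
    cand_mask[ref, cols] = 0
    snv_pos = np.nonzero(cand_mask.any(axis=0))[0]

    def ref_stats(j):
        b = ref[j]
        c = int(pileup.count[b, j])
        qual = float(pileup.qual_sum[b, j] / c) if c else 0.0
        return c, int(pileup.rev[b, j]), qual

    for j in snv_pos:
        total = int(pileup.total_dp[j])
        if total == 0:
            continue
        pos = pileup.start + int(j)
        ref_dp, ref_rv, ref_qual = ref_stats(j)
        for b in range(4):
            if b == ref[j] or not cand_mask[b, j]:
                continue
            alt_dp = int(pileup.count[b, j])
            freq = alt_dp / total
            if freq < cfg.min_freq:
                continue
            alt_qual = float(pileup.qual_sum[b, j] / alt_dp)
            pval = fisher_error_test(alt_dp, total, alt_qual)
            rows.append((region, pos, _BASES[ref[j]], _BASES[b],
                         ref_dp, ref_rv, ref_qual, alt_dp,
                         int(pileup.rev[b, j]), alt_qual, freq, total,
                         pval, pval <= cfg.alpha, ""))

    for pos, alleles in pileup.indels.items():
        j = pos - pileup.start
        total = int(pileup.total_dp[j])
        if total == 0:
            continue
        ref_dp, ref_rv, ref_qual = ref_stats(j)
        for alt, (c, qsum, rv) in alleles.items():
            freq = c / total
            if freq < cfg.min_freq:
                continue
            alt_qual = qsum / c
            pval = fisher_error_test(c, total, alt_qual)
            rows.append((region, pos, genome.slice(pos, pos), alt,
                         ref_dp, ref_rv, ref_qual, c, rv, alt_qual,
                         freq, total, pval, pval <= cfg.alpha, ""))

    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    return df.sort_values(["POS", "ALT"], kind="mergesort",
                          ignore_index=True)


def write_variant_tsv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["PASS"] = out["PASS"].map({True: "TRUE", False: "FALSE"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_variant_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     na_values=[], dtype={"REF": str, "ALT": str})
    df["PASS"] = df["PASS"].map(
        lambda v: str(v).strip().upper() in {"TRUE", "1"})
    return df
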