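"""Amplicon-aware read placement: primer-based amplicon assignment,
banded affine-gap alignment inside the assigned amplicon window,
5'-ward indel normalisation, and SAM interchange.

The aligner is glocal: the read is aligned end-to-end against a padded
reference window with free start/end positions in the window.  It exists
to make the pipeline hermetic; externally produced SAM is accepted
interchangeably (see ``parse_sam``).  MAPQ is binary by design: 60 for a
uniquely assigned amplicon, 0 for an ambiguous assignment - graded
mapper MAPQ carries no information when the amplicon of origin is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from .crispr_targeting import reverse_complement
from .synthetic_data import Genome, PrimerScheme, ReadPair, _to_codes

_NEG = np.int16(-20000)

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_MREVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


@dataclass
class AlignConfig:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    band: int | None = 64
    pad: int = 50
    assign_tolerance: int = 2


@dataclass
class Alignment:
    """One aligned (or unmapped) read in reference orientation."""
    read_name: str
    ref_id: str
    pos: int                      # 1-based leftmost aligned ref position
    cigar: list[tuple[str, int]]  # ops over M/I/D/S
    mapq: int
    flags: int
    seq: str
    quals: str
    amplicon: str | None = None
    score: int | None = None

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flags & FLAG_UNMAPPED)

    def query_length(self) -> int:
        return sum(l for op, l in self.cigar if op in "MIS")

    def aligned_query_length(self) -> int:
        """Query bases actually aligned (soft clips excluded)."""
        return sum(l for op, l in self.cigar if op in "MI")

    def reference_end(self) -> int:
        """1-based inclusive rightmost aligned ref position."""
        return self.pos + sum(l for op, l in self.cigar if op in "MD") - 1

    def validate(self) -> None:
        if not self.is_unmapped and self.query_length() != len(self.seq):
            raise ValueError(f"{self.read_name}: CIGAR/sequence length mismatch")
        for (a, _), (b, _) in zip(self.cigar, self.cigar[1:]):
            if a == b:
                raise ValueError(f"{self.read_name}: adjacent {a} ops")


def cigar_to_str(cigar) -> str:
    return "".join(f"{l}{op}" for op, l in cigar) or "*"


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, l in ops:
        if l <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + l)
        else:
            out.append((op, l))
    return out


# ---------------------------------------------------------------------------
# affine-gap DP (batched over same-length queries)


def _affine_dp_batch(queries: np.ndarray, window: np.ndarray,
                     cfg: AlignConfig, band_offset: int | None = None):
    """Glocal affine DP of ``queries`` (n, L) against ``window`` (W,).

    Free start/end in the window, full consumption of each query.  When
    ``cfg.band`` and ``band_offset`` are set, query base i may only pair
    with window offsets within band of the expected diagonal
    ``band_offset + i``.  Returns (scores, starts, cigars) with starts
    as 0-based window offsets.
    """
    n, L = queries.shape
    W = window.shape[0]
    ma, mm = np.int16(cfg.match), np.int16(cfg.mismatch)
    go, ge = np.int16(cfg.gap_open), np.int16(cfg.gap_extend)

    M = np.full((n, L + 1, W + 1), _NEG, dtype=np.int16)
    X = np.full_like(M, _NEG)   # gap in reference (query insertion)
    Y = np.full_like(M, _NEG)   # gap in query (reference deletion)
    M[:, 0, :] = 0
    jj = np.arange(W + 1, dtype=np.int32)

    for i in range(1, L + 1):
        sub = np.where(queries[:, i - 1:i] == window[None, :], ma, mm)
        best_prev = np.maximum(np.maximum(M[:, i - 1, :], X[:, i - 1, :]),
                               Y[:, i - 1, :])
        M[:, i, 1:] = sub + best_prev[:, :-1]
        X[:, i, :] = np.maximum(
            np.maximum(M[:, i - 1, :], Y[:, i - 1, :]) + go + ge,
            X[:, i - 1, :] + ge)
        base = np.maximum(M[:, i, :], X[:, i, :]).astype(np.int32)
        t = base - jj * int(ge)
        cum = np.maximum.accumulate(t[:, :-1], axis=1)
        Y[:, i, 1:] = np.clip(int(go) + jj[1:] * int(ge) + cum,
                              _NEG, None).astype(np.int16)
        if cfg.band is not None and band_offset is not None:
            lo = band_offset + i - cfg.band
            hi = band_offset + i + cfg.band
            out = (jj < lo) | (jj > hi)
            M[:, i, out] = _NEG
            X[:, i, out] = _NEG
            Y[:, i, out] = _NEG

    final = np.maximum(M[:, L, :], X[:, L, :])
    ends = np.argmax(final, axis=1)
    scores = final[np.arange(n), ends]

    results = []
    for r in range(n):
        results.append(_traceback(M[r], X[r], Y[r], queries[r], window,
                                  int(ends[r]), cfg))
    return scores.astype(int), results


def _traceback(M, X, Y, query, window, j, cfg):
    ma, mm = cfg.match, cfg.mismatch
    go, ge = cfg.gap_open, cfg.gap_extend
    L = query.shape[0]
    i = L
    state = "M" if M[L, j] >= X[L, j] else "X"
    ops: list[tuple[str, int]] = []
    while i > 0:
        if state == "M":
            ops.append(("M", 1))
            s = ma if query[i - 1] == window[j - 1] else mm
            v = M[i, j] - s
            i, j = i - 1, j - 1
            state = ("M" if M[i, j] == v else
                     "Y" if Y[i, j] == v else "X")
        elif state == "X":
            ops.append(("I", 1))
            v = X[i, j]
            i -= 1
            if X[i, j] + ge == v:
                state = "X"
            elif M[i, j] + go + ge == v:
                state = "M"
            else:
                state = "Y"
        else:  # Y: consumes window only
            ops.append(("D", 1))
            v = Y[i, j]
            j -= 1
            if Y[i, j] + ge == v:
                state = "Y"
            elif M[i, j] + go + ge == v:
                state = "M"
            else:
                state = "X"
    ops.reverse()
    return j, _merge_ops(ops)


def align_read(read: str, window: str, window_start: int, *,
               ref_id: str = "ref", read_name: str = "read",
               quals: str | None = None,
               config: AlignConfig | None = None,
               band_offset: int | None = None) -> Alignment:
    """Align one read glocally inside a reference window.

    ``window_start`` is the 1-based genome position of the window's
    first base.  Raises on an empty read or a window shorter than the
    read's banded reach.
    """
    cfg = config or AlignConfig()
    if not read:
        raise ValueError("empty read")
    if len(window) < len(read) - (cfg.band or 0):
        raise ValueError("window too short for read under banding")
    q = _to_codes(read)[None, :]
    w = _to_codes(window)
    scores, results = _affine_dp_batch(q, w, cfg, band_offset)
    j0, cigar = results[0]
    return Alignment(read_name=read_name, ref_id=ref_id,
                     pos=window_start + j0, cigar=cigar, mapq=60, flags=0,
                     seq=read, quals=quals or "I" * len(read),
                     score=int(scores[0]))


# ---------------------------------------------------------------------------
# amplicon assignment


def _primer_index(scheme: PrimerScheme):
    left, right = {}, {}
    for a in scheme.amplicons:
        if a.left.seq is None or a.right.seq is None:
            raise ValueError("primer sequences required for assignment; "
                             "use attach_primer_sequences")
        left.setdefault(a.left.seq, []).append(a.name)
        right.setdefault(a.right.seq, []).append(a.name)
    return left, right


def assign_amplicon(pair: ReadPair, scheme: PrimerScheme,
                    tolerance: int = 2, _index=None):
    """Match the pair's outer 5' k-mers against the scheme's primers.

    Returns ``(amplicon_name, ambiguous)`` where the name is None when
    no amplicon matches within the edit tolerance or when several match
    equally well.
    """
    left_idx, right_idx = _index if _index is not None else _primer_index(scheme)

    def candidates(prefix_of, index):
        k = len(next(iter(index)))
        probe = prefix_of[:k]
        if probe in index:
            return {name: 0 for name in index[probe]}
        out = {}
        for seq, names in index.items():
            d = edlib.align(probe, seq, task="distance", k=tolerance)["editDistance"]
            if d != -1:
                for name in names:
                    out[name] = d
        return out

    c1 = candidates(pair.seq1, left_idx)
    c2 = candidates(pair.seq2, right_idx)
    joint = {name: c1[name] + c2[name] for name in c1.keys() & c2.keys()}
    if not joint:
        return None, False
    best = min(joint.values())
    winners = [n for n, d in joint.items() if d == best]
    if len(winners) > 1:
        return None, True
    return winners[0], False


def _unmapped(pair: ReadPair, ref_id: str, which: int) -> Alignment:
    seq = pair.seq1 if which == 1 else pair.seq2
    qual = pair.qual1 if which == 1 else pair.qual2
    return Alignment(read_name=pair.name, ref_id=ref_id, pos=0, cigar=[],
                     mapq=0,
                     flags=FLAG_PAIRED | FLAG_UNMAPPED |
                     (FLAG_READ1 if which == 1 else FLAG_READ2),
                     seq=seq, quals=qual)


def align_pairs(pairs: list[ReadPair], scheme: PrimerScheme, genome: Genome,
                config: AlignConfig | None = None,
                chunk: int = 32) -> list[Alignment]:
    """Assign and align read pairs; reverse reads are stored in
    reference orientation with the reverse flag set."""
    cfg = config or AlignConfig()
    index = _primer_index(scheme)

    # bucket read ends by (amplicon, mate) so each bucket shares a window
    buckets: dict[tuple[str, int], list[int]] = {}
    assignment: list[str | None] = []
    out: list[Alignment | None] = [None] * (2 * len(pairs))
    for idx, pair in enumerate(pairs):
        name, ambiguous = assign_amplicon(pair, scheme, cfg.assign_tolerance,
                                          _index=index)
        assignment.append(name if not ambiguous else "__ambiguous__")
        if name is None and not ambiguous:
            out[2 * idx] = _unmapped(pair, genome.id, 1)
            out[2 * idx + 1] = _unmapped(pair, genome.id, 2)
            continue
        key = name if name is not None else scheme.amplicons[0].name
        buckets.setdefault((key, 1), []).append(idx)
        buckets.setdefault((key, 2), []).append(idx)

    for (amp_name, mate), idxs in buckets.items():
        amp = scheme.get(amp_name)
        w_start = max(1, amp.start - cfg.pad)
        w_end = min(len(genome), amp.end + cfg.pad)
        window = _to_codes(genome.slice(w_start, w_end))
        span = amp.end - amp.start + 1

        # expected 0-based window offset of the read start
        if mate == 1:
            exp = amp.start - w_start
        else:
            exp = None  # depends on read length; set per group below

        by_len: dict[int, list[int]] = {}
        for i in idxs:
            p = pairs[i]
            seq = p.seq1 if mate == 1 else p.seq2
            by_len.setdefault(len(seq), []).append(i)

        for L, group in by_len.items():
            if mate == 1:
                offset = exp
            else:
                offset = (amp.end - L + 1) - w_start
            offset = max(0, offset)
            for c0 in range(0, len(group), chunk):
                sub = group[c0:c0 + chunk]
                qarr = np.empty((len(sub), L), dtype=np.uint8)
                for r, i in enumerate(sub):
                    p = pairs[i]
                    s = p.seq1 if mate == 1 else reverse_complement(p.seq2)
                    qarr[r] = _to_codes(s)
                scores, results = _affine_dp_batch(qarr, window, cfg, offset)
                for r, i in enumerate(sub):
                    p = pairs[i]
                    ambiguous = assignment[i] == "__ambiguous__"
                    j0, cigar = results[r]
                    if mate == 1:
                        flags = (FLAG_PAIRED | FLAG_PROPER | FLAG_MREVERSE
                                 | FLAG_READ1)
                        seq, quals = p.seq1, p.qual1
                    else:
                        flags = (FLAG_PAIRED | FLAG_PROPER | FLAG_REVERSE
                                 | FLAG_READ2)
                        seq, quals = reverse_complement(p.seq2), p.qual2[::-1]
                    out[2 * i + (mate - 1)] = Alignment(
                        read_name=p.name, ref_id=genome.id,
                        pos=w_start + j0, cigar=cigar,
                        mapq=0 if ambiguous else 60, flags=flags,
                        seq=seq, quals=quals,
                        amplicon=None if ambiguous else amp_name,
                        score=int(scores[r]))
    return [a for a in out if a is not None]


# ---------------------------------------------------------------------------
# indel normalisation


def left_normalize_indels(aln: Alignment, genome: Genome) -> Alignment:
    """Shift every I/D op maximally 5'-ward on the reference.

    Uses the standard haplotype-invariance condition (flanking base
    equality), so shift-equivalent placements collapse to one canonical
    representation; idempotent; the read sequence implied by the
    alignment is unchanged.
    """
    if aln.is_unmapped or not aln.cigar:
        return aln
    seq = genome.sequence
    ops = [list(o) for o in aln.cigar]
    pos = aln.pos

    changed = True
    while changed:
        changed = False
        ref = pos
        for k, (op, l) in enumerate(ops):
            if op in "MD":
                start_ref = ref
                ref += l
            else:
                start_ref = ref
            if op not in "ID" or k == 0:
                continue
            prev = ops[k - 1]
            if prev[0] != "M" or prev[1] < 1:
                continue
            if op == "D":
                r = start_ref  # first deleted base, 1-based
                if prev[1] >= 1 and seq[r - 2] == seq[r + l - 2]:
                    prev[1] -= 1
                    if k + 1 < len(ops) and ops[k + 1][0] == "M":
                        ops[k + 1][1] += 1
                    else:
                        ops.insert(k + 1, ["M", 1])
                    if prev[1] == 0:
                        ops.pop(k - 1)
                    changed = True
                    break
            else:  # insertion after ref position start_ref - 1
                anchor = start_ref - 1
                q0 = sum(x[1] for x in ops[:k] if x[0] in "MIS")
                ins = aln.seq[q0:q0 + l]
                if anchor >= pos and ins[-1] == seq[anchor - 1]:
                    prev[1] -= 1
                    if k + 1 < len(ops) and ops[k + 1][0] == "M":
                        ops[k + 1][1] += 1
                    else:
                        ops.insert(k + 1, ["M", 1])
                    if prev[1] == 0:
                        ops.pop(k - 1)
                    changed = True
                    break
    new = replace(aln, cigar=_merge_ops([tuple(o) for o in ops]))
    new.validate()
    return new


# ---------------------------------------------------------------------------
# SAM interchange (via pysam)

_OP_TO_CODE = {"M": 0, "I": 1, "D": 2, "S": 4}
_CODE_TO_OP = {0: "M", 1: "I", 2: "D", 3: "D", 4: "S", 7: "M", 8: "M"}


def _sam_header(genome: Genome) -> dict:
    return {"HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": genome.id, "LN": len(genome)}]}


def emit_sam(alignments: list[Alignment], genome: Genome, path) -> None:
    import pysam
    header = pysam.AlignmentHeader.from_dict(_sam_header(genome))
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = a.read_name
            seg.flag = a.flags
            seg.query_sequence = a.seq
            seg.query_qualities = pysam.qualitystring_to_array(a.quals)
            seg.mapping_quality = a.mapq
            if a.is_unmapped:
                seg.reference_id = -1
                seg.reference_start = -1
            else:
                seg.reference_id = 0
                seg.reference_start = a.pos - 1
                seg.cigartuples = [(_OP_TO_CODE[op], l) for op, l in a.cigar]
            if a.amplicon:
                seg.set_tag("XA", a.amplicon)
            if a.score is not None:
                seg.set_tag("AS", a.score)
            fh.write(seg)


def parse_sam(path) -> list[Alignment]:
    import pysam
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                cigar: list[tuple[str, int]] = []
            else:
                cigar = _merge_ops([(_CODE_TO_OP[c], l)
                                    for c, l in seg.cigartuples or []
                                    if c in _CODE_TO_OP])
            out.append(Alignment(
                read_name=seg.query_name,
                ref_id=seg.reference_name or (fh.references[0]
                                              if fh.references else "ref"),
                pos=(seg.reference_start + 1) if not seg.is_unmapped else 0,
                cigar=cigar,
                mapq=seg.mapping_quality,
                flags=seg.flag,
                seq=seg.query_sequence or "",
                quals=pysam.qualities_to_qualitystring(seg.query_qualities)
                if seg.query_qualities is not None else "",
                amplicon=seg.get_tag("XA") if seg.has_tag("XA") else None,
                score=seg.get_tag("AS") if seg.has_tag("AS") else None))
    return out
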