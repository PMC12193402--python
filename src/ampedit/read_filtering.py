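"""Alignment-level filters: SAM flag mask, mapping-quality floor, primer
soft-clipping, and post-clip length floor.

Defaults mirror the study pipeline: flag mask 2308 (unmapped +
secondary + supplementary), MAPQ >= 10, and >= 200 aligned bases after
primer clipping.  "Below 200" is read as keep-if->=200, matching the
minimum-kept-length semantics of the clipping tool the thresholds come
from; the boundary is tested explicitly.  Clipping uses soft clips so
the read sequence survives for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .amplicon_alignment import Alignment, _merge_ops
from .synthetic_data import PrimerScheme


@dataclass(frozen=True)
class FilterConfig:
    mapq_min: int = 10
    flag_mask: int = 2308
    min_post_clip_len: int = 200

    def __post_init__(self):
        if self.mapq_min < 0 or self.flag_mask < 0:
            raise ValueError("thresholds must be non-negative")


def filter_flags_mapq(alignments: list[Alignment],
                      cfg: FilterConfig | None = None) -> list[Alignment]:
    """Keep records with (flags & mask) == 0 and MAPQ >= floor."""
    cfg = cfg or FilterConfig()
    return [a for a in alignments
            if (a.flags & cfg.flag_mask) == 0 and a.mapq >= cfg.mapq_min]


def _clip_5prime(aln: Alignment, clip_end: int) -> Alignment:
    """Soft-clip aligned bases at reference positions <= clip_end from
    the 5' (left) end of the record."""
    if aln.pos > clip_end:
        return aln
    ops = [list(o) for o in aln.cigar]
    new_ops: list[list] = []
    ref = aln.pos
    clipped_q = 0
    k = 0
    # carry over an existing leading soft clip
    while k < len(ops) and ops[k][0] == "S":
        clipped_q += ops[k][1]
        k += 1
    while k < len(ops) and ref <= clip_end:
        op, l = ops[k]
        if op == "M":
            take = min(l, clip_end - ref + 1)
            clipped_q += take
            ref += take
            if take < l:
                ops[k][1] = l - take
                break
            k += 1
        elif op == "D":
            take = min(l, clip_end - ref + 1)
            ref += take
            if take < l:
                ops[k][1] = l - take
                break
            k += 1
        elif op == "I":
            clipped_q += l
            k += 1
        else:
            k += 1
    rest = [tuple(o) for o in ops[k:]]
    # an alignment may not begin with D/I after clipping
    while rest and rest[0][0] in "DI":
        op, l = rest[0]
        if op == "D":
            ref += l
        else:
            clipped_q += l
        rest = rest[1:]
    if clipped_q:
        new_ops.append(["S", clipped_q])
    new_cigar = _merge_ops([tuple(o) for o in new_ops] + rest)
    if not any(op in "MI" for op, _ in new_cigar):
        return replace(aln, cigar=new_cigar, pos=aln.pos)  # fully clipped
    return replace(aln, cigar=new_cigar, pos=ref)


def _clip_3prime(aln: Alignment, clip_start: int) -> Alignment:
    """Mirror of :func:`_clip_5prime` for reference positions >=
    clip_start at the record's 3' (right) end."""
    if aln.reference_end() < clip_start:
        return aln
    ops = [list(o) for o in aln.cigar]
    ref_end = aln.reference_end()
    clipped_q = 0
    k = len(ops) - 1
    while k >= 0 and ops[k][0] == "S":
        clipped_q += ops[k][1]
        k -= 1
    while k >= 0 and ref_end >= clip_start:
        op, l = ops[k]
        if op == "M":
            take = min(l, ref_end - clip_start + 1)
            clipped_q += take
            ref_end -= take
            if take < l:
                ops[k][1] = l - take
                break
            k -= 1
        elif op == "D":
            take = min(l, ref_end - clip_start + 1)
            ref_end -= take
            if take < l:
                ops[k][1] = l - take
                break
            k -= 1
        elif op == "I":
            clipped_q += l
            k -= 1
        else:
            k -= 1
    rest = [tuple(o) for o in ops[:k + 1]]
    while rest and rest[-1][0] in "DI":
        op, l = rest[-1]
        if op == "I":
            clipped_q += l
        rest = rest[:-1]
    tail = [("S", clipped_q)] if clipped_q else []
    new_cigar = _merge_ops(rest + tail)
    return replace(aln, cigar=new_cigar)


def clip_primers(aln: Alignment, scheme: PrimerScheme,
                 amplicon: str | None = "auto") -> Alignment:
    """Soft-clip aligned bases that fall inside primer intervals.

    With ``amplicon="auto"`` the record's own amplicon's primers are
    used when the assignment is known; records without an assignment
    are clipped against every primer interval overlapping their ends
    (conservative).  Re-clipping a clipped record is a no-op.  A record
    that is entirely primer-derived ends up with no aligned bases and
    is dropped by :func:`filter_length`.
    """
    if aln.is_unmapped or not aln.cigar:
        return aln
    if amplicon == "auto":
        amplicon = aln.amplicon
    if amplicon is not None:
        try:
            amp = scheme.get(amplicon)
            primers = [amp.left, amp.right]
        except KeyError:
            primers = scheme.primers
    else:
        primers = scheme.primers

    out = aln
    for p in sorted(primers, key=lambda p: p.start):
        if not out.cigar or not any(op in "MI" for op, _ in out.cigar):
            break
        if p.start <= out.pos <= p.end:
            out = _clip_5prime(out, p.end)
    for p in sorted(primers, key=lambda p: -p.end):
        if not out.cigar or not any(op in "MI" for op, _ in out.cigar):
            break
        if not out.is_unmapped and any(op in "MD" for op, _ in out.cigar):
            if p.start <= out.reference_end() <= p.end:
                out = _clip_3prime(out, p.start)
    out.validate()
    return out


def clip_all(alignments: list[Alignment], scheme: PrimerScheme,
             ) -> list[Alignment]:
    return [clip_primers(a, scheme) for a in alignments]


def filter_length(alignments: list[Alignment],
                  cfg: FilterConfig | None = None) -> list[Alignment]:
    """Keep records whose aligned (non-clipped) query length >= floor."""
    cfg = cfg or FilterConfig()
    return [a for a in alignments
            if a.aligned_query_length() >= cfg.min_post_clip_len]


def apply_filters(alignments: list[Alignment], scheme: PrimerScheme,
                  cfg: FilterConfig | None = None) -> list[Alignment]:
    """Flag/MAPQ filter, primer clipping, then post-clip length filter."""
    cfg = cfg or FilterConfig()
    kept = filter_flags_mapq(alignments, cfg)
    return filter_length(clip_all(kept, scheme), cfg)
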