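"""Spacer placement, expected indel windows, on-target labelling, and
off-target scanning for SpCas9-style guides.

Coordinates are 1-based inclusive on the reference plus strand.  A
protospacer located on the minus strand is reported as the plus-strand
interval its 20-mer occupies; the PAM then sits immediately to its *left*
on the plus strand (reading CCN), which is the NGG motif on the minus
strand.

The blunt Cas9 cut falls between protospacer bases 17 and 18 (3 bp from
the PAM).  Error-prone end joining produces 1-5 bp indels in a narrow
interval just 5' of the cut on the protospacer strand; on this package's
calibration that interval is the six protospacer bases 12-17 (4-9 bp
upstream of the PAM), which reproduces every published expected window
for the gp64 guides.  One guide (gp64-160) was designed against assay
coordinates that do not follow this arithmetic; its window is carried as
an explicit override on the target definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _tables

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC codes used in PAM patterns.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class TargetNotFoundError(ValueError):
    """The spacer (with adjacent PAM) does not occur in the genome."""


class AmbiguousTargetError(ValueError):
    """The spacer occurs at more than one PAM-adjacent site."""


@dataclass(frozen=True)
class SpacerTarget:
    """A 20-nt sgRNA spacer with its PAM and naming metadata.

    ``window_override`` pins the expected indel window to published
    coordinates for guides whose naming does not follow the placement
    arithmetic (see module docstring).
    """

    name: str
    spacer: str
    pam: str = "NGG"
    declared_strand: str | None = None  # "sense" / "antisense"
    window_override: tuple[int, int] | None = None

    def __post_init__(self):
        if len(self.spacer) != 20:
            raise ValueError(f"spacer must be 20 nt, got {len(self.spacer)}")
        if len(self.pam) != 3:
            raise ValueError(f"PAM must be 3 nt, got {self.pam!r}")

    @property
    def offset_label(self) -> int | None:
        """Integer offset parsed from a name like ``gp64+131``."""
        for i, ch in enumerate(self.name):
            if ch in "+-":
                try:
                    return int(self.name[i:])
                except ValueError:
                    return None
        return None


@dataclass(frozen=True)
class ProtospacerSite:
    """Genomic placement of a protospacer: plus-strand interval of the
    20-mer, PAM interval, the strand the spacer reads on, and the cut
    site as a between-base coordinate (cut falls between ``cut_after``
    and ``cut_after + 1``)."""

    start: int
    end: int
    pam_start: int
    pam_end: int
    strand: str  # '+' or '-'
    cut_after: int


@dataclass(frozen=True)
class EditWindow:
    start: int
    end: int

    def __post_init__(self):
        if self.end - self.start + 1 != 6:
            raise ValueError("edit window must span exactly 6 bp")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def intersects(self, start: int, end: int) -> bool:
        return not (end < self.start or start > self.end)


@dataclass(frozen=True)
class OffTargetHit:
    pos: int
    strand: str
    mismatches: int
    pam_present: bool


def _pam_matches(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in _IUPAC.get(p, p) for b, p in zip(seq, pattern)
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def locate_protospacer(genome, target: SpacerTarget,
                       pam_pattern: str = "NGG") -> ProtospacerSite:
    """Find the unique PAM-adjacent occurrence of a spacer.

    Searches the spacer on the plus strand (PAM immediately 3') and its
    reverse complement on the minus strand (plus-strand CCN immediately
    5').  Raises :class:`TargetNotFoundError` on zero hits and
    :class:`AmbiguousTargetError` if the site is not unique.
    """
    seq = genome.sequence
    n = len(seq)
    sites: list[ProtospacerSite] = []

    for i in _find_all(seq, target.spacer):  # plus strand, 0-based
        pam0 = i + 20
        if pam0 + 3 <= n and _pam_matches(seq[pam0:pam0 + 3], pam_pattern):
            p = i + 1
            sites.append(ProtospacerSite(
                start=p, end=p + 19, pam_start=p + 20, pam_end=p + 22,
                strand="+", cut_after=p + 16))

    rc = reverse_complement(target.spacer)
    rc_pam = reverse_complement(pam_pattern)  # NGG -> CCN
    for i in _find_all(seq, rc):
        if i - 3 >= 0 and _pam_matches(seq[i - 3:i], rc_pam):
            q = i + 1
            sites.append(ProtospacerSite(
                start=q, end=q + 19, pam_start=q - 3, pam_end=q - 1,
                strand="-", cut_after=q + 2))

    if not sites:
        raise TargetNotFoundError(f"{target.name}: spacer not found with PAM")
    if len(sites) > 1:
        raise AmbiguousTargetError(
            f"{target.name}: {len(sites)} PAM-adjacent sites")
    return sites[0]


def predict_edit_window(site: ProtospacerSite,
                        genome_length: int | None = None,
                        override: tuple[int, int] | None = None) -> EditWindow:
    """Expected 6-bp window for 1-5 bp repair indels at a cut site.

    The window is the six protospacer bases immediately 5' of the cut on
    the protospacer strand (protospacer positions 12-17).  For a
    plus-strand site at [p, p+19] that is [p+11, p+16]; for a
    minus-strand site at [q, q+19] it is [q+3, q+8].  ``override``
    short-circuits the rule for guides anchored to published
    coordinates.
    """
    if override is not None:
        win = EditWindow(*override)
    elif site.strand == "+":
        win = EditWindow(site.start + 11, site.start + 16)
    else:
        win = EditWindow(site.start + 3, site.start + 8)
    if win.start < 1 or (genome_length is not None and win.end > genome_length):
        raise ValueError("edit window extends past genome end")
    return win


def target_windows(genome, targets) -> dict[str, EditWindow]:
    """Locate each target and predict its window (honouring overrides)."""
    out = {}
    for t in targets:
        site = locate_protospacer(genome, t)
        out[t.name] = predict_edit_window(
            site, len(genome.sequence), override=t.window_override)
    return out


def default_targets() -> list[SpacerTarget]:
    """The six gp64 guides of the study (scrambled control excluded)."""
    out = []
    for name, d in _tables.SPACERS.items():
        if d["strand"] is None:
            continue
        out.append(SpacerTarget(
            name=name, spacer=d["spacer"], pam=d["pam"],
            declared_strand=d["strand"],
            window_override=_tables.WINDOW_OVERRIDES.get(name)))
    return out


def write_targets_file(targets: list[SpacerTarget], path) -> None:
    """Tab-separated guide catalogue: name/spacer/PAM/strand, plus the
    optional window override columns."""
    with open(path, "w") as fh:
        fh.write("name\tspacer\tpam\tstrand\twindow_start\twindow_end\n")
        for t in targets:
            a, b = t.window_override or ("", "")
            fh.write(f"{t.name}\t{t.spacer}\t{t.pam}\t"
                     f"{t.declared_strand or '.'}\t{a}\t{b}\n")


def read_targets_file(path) -> list[SpacerTarget]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            override = None
            if row.get("window_start"):
                override = (int(row["window_start"]), int(row["window_end"]))
            out.append(SpacerTarget(
                name=row["name"], spacer=row["spacer"], pam=row["pam"],
                declared_strand=None if row.get("strand") in (None, ".")
                else row["strand"],
                window_override=override))
    return out


def scrambled_target() -> SpacerTarget:
    d = _tables.SPACERS["scrambled"]
    return SpacerTarget(name="scrambled", spacer=d["spacer"], pam="NGG")


# -- variant labelling --------------------------------------------------


def _allele_interval(pos: int, alt: str) -> tuple[int, int]:
    """Reference interval affected by an allele in the table notation."""
    if alt.startswith("-"):
        return pos, pos + len(alt) - 2  # '-SEQ': [pos, pos+len(SEQ)-1]
    return pos, pos


def match_on_target(table, windows: dict[str, EditWindow]):
    """Label each variant row on_target:<guide> / off_window.

    Deletions are tested by interval intersection with the window, not
    just by their anchor position.  Returns (labelled copy, per-window
    hit counts).
    """
    table = table.copy()
    labels = []
    counts = {name: 0 for name in windows}
    for _, row in table.iterrows():
        a, b = _allele_interval(int(row["POS"]), str(row["ALT"]))
        hit = None
        for name, win in windows.items():
            if win.intersects(a, b):
                hit = name
                break
        if hit is None:
            labels.append("off_window")
        else:
            labels.append(f"on_target:{hit}")
            counts[hit] += 1
    table["TARGET_LABEL"] = labels
    return table, counts


# -- off-target scan ----------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def scan_off_targets(genome, target: SpacerTarget, max_mm: int = 4,
                     pam_required: bool = True,
                     pam_pattern: str = "NGG",
                     exclude_on_target: bool = True):
    """Slide the 20-mer spacer over both strands counting mismatches.

    Returns ``(hits, genome_min_mm)`` where hits are frames with at most
    ``max_mm`` mismatches (PAM-gated when ``pam_required``) and
    ``genome_min_mm`` is the genome-wide minimum mismatch count ignoring
    the PAM, with the on-target site excluded when requested.
    """
    seq = genome.sequence
    n = len(seq)
    if n < 23:
        raise ValueError("genome shorter than a protospacer plus PAM")

    arr = _encode(seq)
    try:
        on = locate_protospacer(genome, target, pam_pattern)
    except (TargetNotFoundError, AmbiguousTargetError):
        on = None

    hits: list[OffTargetHit] = []
    min_mm = 20

    for strand in "+-":
        spacer = target.spacer if strand == "+" else reverse_complement(target.spacer)
        sp = _encode(spacer)
        nf = n - 19
        mism = np.zeros(nf, dtype=np.int16)
        for k in range(20):
            mism += arr[k:k + nf] != sp[k]

        # PAM adjacency per frame
        if strand == "+":
            pam_ok = np.zeros(nf, dtype=bool)
            lim = n - 22
            if lim > 0:
                ok = np.ones(lim, dtype=bool)
                for k, p in enumerate(pam_pattern):
                    allowed = _IUPAC.get(p, p)
                    m = np.zeros(lim, dtype=bool)
                    for b in allowed:
                        m |= arr[20 + k:20 + k + lim] == ord(b)
                    ok &= m
                pam_ok[:lim] = ok
        else:
            pam_ok = np.zeros(nf, dtype=bool)
            rc_pam = reverse_complement(pam_pattern)
            ok = np.ones(nf - 3, dtype=bool) if nf > 3 else np.zeros(0, dtype=bool)
            for k, p in enumerate(rc_pam):
                allowed = _IUPAC.get(p, p)
                m = np.zeros(len(ok), dtype=bool)
                for b in allowed:
                    m |= arr[k:k + len(ok)] == ord(b)
                ok &= m
            pam_ok[3:3 + len(ok)] = ok  # frame i has PAM at [i-3, i-1]

        excl = np.zeros(nf, dtype=bool)
        if exclude_on_target and on is not None and on.strand == strand:
            excl[on.start - 1] = True

        keep = ~excl
        if keep.any():
            min_mm = min(min_mm, int(mism[keep].min()))
        sel = keep & (mism <= max_mm)
        if pam_required:
            sel &= pam_ok
        for i in np.nonzero(sel)[0]:
            hits.append(OffTargetHit(
                pos=int(i) + 1, strand=strand,
                mismatches=int(mism[i]), pam_present=bool(pam_ok[i])))

    hits.sort(key=lambda h: (h.pos, h.strand))
    return hits, min_mm
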