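"""Deterministic fixture genome, tiled primer scheme, and paired-end read
simulator with spiked low-frequency haplotype variants.

The generator emulates the study system: a ~120 kb AT-rich dsDNA viral
genome carrying a reverse-strand envelope gene (gp64) with six planted
sgRNA protospacers, homologous-repeat (hr) arrays acting as mutation
hotspots, a two-pool tiled-amplicon scheme, and 400x paired-end
sequencing in technical duplicate.  Printed study coordinates (the
gp64+131 window anchor, the guide spacers, the conserved-variant
catalogue) are planted so that every published number that depends on
coordinates reproduces without access to the restricted raw data.

All coordinates are 1-based inclusive except BED emission (0-based
half-open, per the format).
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import _tables
from .crispr_targeting import SpacerTarget, default_targets, reverse_complement

_BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _to_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _to_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Genome:
    id: str
    sequence: str

    def __post_init__(self):
        if set(self.sequence) - set("ACGT"):
            raise ValueError("genome alphabet must be A/C/G/T")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive substring."""
        return self.sequence[start - 1:end]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.id}\n")
            s = self.sequence
            for i in range(0, len(s), 70):
                fh.write(s[i:i + 70] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        name, chunks = None, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        break
                    name = line[1:].split()[0]
                elif line:
                    chunks.append(line.upper())
        if name is None:
            raise ValueError(f"no FASTA record in {path}")
        return cls(id=name, sequence="".join(chunks))


_FEATURE_CLASSES = {"hr", "orf", "promoter", "utr", "intergenic"}


@dataclass(frozen=True)
class Feature:
    label: str
    feat_class: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.feat_class not in _FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feat_class!r}")
        if self.start > self.end:
            raise ValueError("feature start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FeatureAnnotation:
    features: tuple[Feature, ...]

    def __post_init__(self):
        labels = [f.label for f in self.features]
        if len(labels) != len(set(labels)):
            raise ValueError("feature labels must be unique")

    def of_class(self, feat_class: str) -> list[Feature]:
        return [f for f in self.features if f.feat_class == feat_class]

    def to_bed(self, path, ref_id: str) -> None:
        with open(path, "w") as fh:
            for f in self.features:
                fh.write(f"{ref_id}\t{f.start - 1}\t{f.end}\t"
                         f"{f.label}_{f.feat_class}\t0\t{f.strand}\n")

    @classmethod
    def from_bed(cls, path) -> "FeatureAnnotation":
        feats = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                c = line.rstrip("\n").split("\t")
                label, _, fclass = c[3].rpartition("_")
                strand = c[5] if len(c) > 5 else "."
                feats.append(Feature(label, fclass, int(c[1]) + 1,
                                     int(c[2]), strand))
        return cls(tuple(feats))


@dataclass(frozen=True)
class Primer:
    name: str
    start: int
    end: int
    strand: str
    pool: int
    seq: str | None = None


@dataclass(frozen=True)
class Amplicon:
    name: str
    number: int
    left: Primer
    right: Primer

    @property
    def pool(self) -> int:
        return self.left.pool

    @property
    def start(self) -> int:
        return self.left.start

    @property
    def end(self) -> int:
        return self.right.end

    @property
    def insert_start(self) -> int:
        return self.left.end + 1

    @property
    def insert_end(self) -> int:
        return self.right.start - 1


@dataclass(frozen=True)
class PrimerScheme:
    ref_id: str
    amplicons: tuple[Amplicon, ...]

    @property
    def primers(self) -> list[Primer]:
        out = []
        for a in self.amplicons:
            out.extend([a.left, a.right])
        return out

    def get(self, name: str) -> Amplicon:
        for a in self.amplicons:
            if a.name == name:
                return a
        raise KeyError(name)

    def overlapping(self, start: int, end: int) -> list[Amplicon]:
        return [a for a in self.amplicons
                if not (a.insert_end < start or a.insert_start > end)]

    def to_bed(self, path) -> None:
        """ARTIC-dialect 6-column BED: chrom/start/end/name/pool/strand."""
        with open(path, "w") as fh:
            for a in self.amplicons:
                for p, suffix in ((a.left, "LEFT"), (a.right, "RIGHT")):
                    fh.write(f"{self.ref_id}\t{p.start - 1}\t{p.end}\t"
                             f"{a.name}_{suffix}\t{p.pool}\t{p.strand}\n")

    @classmethod
    def from_bed(cls, path) -> "PrimerScheme":
        rows = {}
        ref_id = None
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                c = line.rstrip("\n").split("\t")
                ref_id = c[0]
                name, _, side = c[3].rpartition("_")
                rows.setdefault(name, {})[side] = Primer(
                    name=c[3], start=int(c[1]) + 1, end=int(c[2]),
                    strand=c[5], pool=int(c[4]))
        amps = []
        for i, (name, d) in enumerate(sorted(
                rows.items(), key=lambda kv: kv[1]["LEFT"].start)):
            amps.append(Amplicon(name=name, number=i + 1,
                                 left=d["LEFT"], right=d["RIGHT"]))
        return cls(ref_id=ref_id, amplicons=tuple(amps))


@dataclass(frozen=True)
class VariantSpec:
    """A spiked haplotype variant in table notation: SNV alt is a single
    base, insertion '+SEQ' anchored at pos, deletion '-SEQ' with pos at
    the first deleted base."""
    pos: int
    alt: str
    frequency: float
    conserved: bool = False

    def interval(self) -> tuple[int, int]:
        if self.alt.startswith("-"):
            return self.pos, self.pos + len(self.alt) - 2
        return self.pos, self.pos


@dataclass
class ScenarioSpec:
    sample_name: str
    fraction: str  # cell_pellet | supernatant | stock
    variants: list[VariantSpec] = field(default_factory=list)
    background_variants: list[VariantSpec] = field(default_factory=list)
    depth: int = 400
    read_length: int = 300
    replicates: int = 2
    seeds: list[int] = field(default_factory=lambda: [11, 12])
    region: tuple[int, int] | None = None
    indel_error_rate: float = 1e-5
    qual_mean: float = 32.0
    qual_sd: float = 3.0
    error_scale: float = 1.0  # 0 disables substitution errors

    def __post_init__(self):
        if len(self.seeds) != self.replicates:
            raise ValueError("one seed per replicate required")
        for v in self.all_variants():
            if not 0 < v.frequency < 1:
                raise ValueError(f"frequency out of (0,1): {v}")
        by_pos: dict[int, float] = {}
        for v in self.all_variants():
            by_pos[v.pos] = by_pos.get(v.pos, 0.0) + v.frequency
        bad = {p: f for p, f in by_pos.items() if f >= 1}
        if bad:
            raise ValueError(f"summed alt frequency >= 1 at {bad}")

    def all_variants(self) -> list[VariantSpec]:
        return list(self.variants) + list(self.background_variants)

    def to_yaml(self, path) -> None:
        def vdump(vs):
            return [{"pos": v.pos, "alt": v.alt, "frequency": v.frequency,
                     "conserved": v.conserved} for v in vs]
        doc = {
            "sample_name": self.sample_name,
            "fraction": self.fraction,
            "depth": self.depth,
            "read_length": self.read_length,
            "replicates": self.replicates,
            "seeds": list(self.seeds),
            "region": list(self.region) if self.region else None,
            "indel_error_rate": self.indel_error_rate,
            "qual_mean": self.qual_mean,
            "qual_sd": self.qual_sd,
            "error_scale": self.error_scale,
            "variants": vdump(self.variants),
            "background_variants": vdump(self.background_variants),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        def vload(rows):
            return [VariantSpec(pos=int(r["pos"]), alt=str(r["alt"]),
                                frequency=float(r["frequency"]),
                                conserved=bool(r.get("conserved", False)))
                    for r in rows or []]
        return cls(
            sample_name=doc["sample_name"], fraction=doc["fraction"],
            variants=vload(doc.get("variants")),
            background_variants=vload(doc.get("background_variants")),
            depth=int(doc.get("depth", 400)),
            read_length=int(doc.get("read_length", 300)),
            replicates=int(doc.get("replicates", 2)),
            seeds=[int(s) for s in doc["seeds"]],
            region=tuple(doc["region"]) if doc.get("region") else None,
            indel_error_rate=float(doc.get("indel_error_rate", 1e-5)),
            qual_mean=float(doc.get("qual_mean", 32.0)),
            qual_sd=float(doc.get("qual_sd", 3.0)),
            error_scale=float(doc.get("error_scale", 1.0)))


@dataclass(frozen=True)
class ReadPair:
    name: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    amplicon_of_origin: str | None = None

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError("sequence/quality length mismatch")


# ---------------------------------------------------------------------------
# reference construction


@dataclass(frozen=True)
class HrSpec:
    name: str
    start: int
    length: int
    unit_length: int = 30
    at_fraction: float = 0.7


_DEFAULT_HRS = (
    HrSpec("hr1", 16_000, 300),
    HrSpec("hr1a", 18_500, 18),
    HrSpec("hr2", 33_000, 300),
    HrSpec("hr2a", 35_500, 24),
    HrSpec("hr3", 52_000, 300),
    HrSpec("hr4a", 60_000, 180),
    HrSpec("hr4c", 63_000, 30),
    HrSpec("hr4b", 66_000, 210),
    HrSpec("hr5", 85_000, 240),
)

_DEFAULT_ORFS = (
    ("AcOrf-603", "orf", 3_500, 4_405, "+"),
    ("AcOrf-1629", "orf", 5_900, 7_500, "+"),
    ("egt", "orf", 11_800, 13_300, "+"),
    ("fgf-3UTR", "utr", 27_400, 27_600, "+"),
    ("AcOrf-51", "orf", 43_800, 44_500, "+"),
    ("lef10", "orf", 45_400, 46_100, "+"),
    ("AcOrf-84-promoter", "promoter", 71_350, 71_500, "+"),
    ("AcOrf-91", "orf", 78_300, 79_200, "+"),
    ("gp64", "orf", *_tables.GP64_INTERVAL, "-"),
)


@dataclass
class ReferenceConfig:
    genome_id: str = "rbev_fixture"
    length: int = _tables.DEFAULT_GENOME_LENGTH
    seed: int = 20_240_617
    anchor_window_start: int = _tables.DEFAULT_ANCHOR_WINDOW_START
    sense_plant_start: int = 107_493
    hrs: tuple[HrSpec, ...] = _DEFAULT_HRS
    orfs: tuple = _DEFAULT_ORFS
    at_fraction: float = 0.59  # background composition of the genome


class PlantingError(ValueError):
    """A planted feature conflicts with previously planted sequence."""


class _Planter:
    def __init__(self, codes: np.ndarray):
        self.codes = codes
        self.planted = np.zeros(len(codes), dtype=bool)

    def plant(self, start: int, seq: str, what: str) -> None:
        """Plant ``seq`` at 1-based ``start``; error on edge overrun or a
        conflicting overlap with earlier plants."""
        i0 = start - 1
        if i0 < 0 or i0 + len(seq) > len(self.codes):
            raise PlantingError(f"{what}: plant runs past genome edge")
        new = _to_codes(seq)
        old = self.codes[i0:i0 + len(seq)]
        mask = self.planted[i0:i0 + len(seq)]
        if np.any(mask & (old != new)):
            raise PlantingError(f"{what}: collides with another planted feature")
        self.codes[i0:i0 + len(seq)] = new
        self.planted[i0:i0 + len(seq)] = True


def _random_codes(rng, n: int, at_fraction: float) -> np.ndarray:
    pat = at_fraction / 2
    pgc = (1 - at_fraction) / 2
    return rng.choice(4, size=n, p=[pat, pgc, pgc, pat]).astype(np.uint8)


def _hr_unit(rng, spec: HrSpec) -> str:
    # resample until the unit meets the AT floor; bounded, deterministic
    for _ in range(50):
        codes = _random_codes(rng, spec.unit_length, max(spec.at_fraction, 0.6))
        at = np.isin(codes, [0, 3]).mean()
        if at >= spec.at_fraction:
            return _to_seq(codes)
    raise RuntimeError("could not draw an AT-rich repeat unit")


def build_reference(config: ReferenceConfig | None = None):
    """Build the fixture genome, its annotation, and the guide targets.

    Every guide protospacer+PAM is embedded exactly once, positioned so
    the predicted edit windows land on the published coordinates; hr
    arrays are AT-rich tandem repeats; the conserved-variant reference
    contexts (ref alleles for published SNVs/indels) are planted
    verbatim.  Deterministic for a given config.
    """
    cfg = config or ReferenceConfig()
    rng = np.random.default_rng(cfg.seed)
    codes = _random_codes(rng, cfg.length, cfg.at_fraction)
    planter = _Planter(codes)

    # hr tandem arrays
    for hr in cfg.hrs:
        unit = _hr_unit(rng, hr)
        reps = (unit * math.ceil(hr.length / len(unit)))[:hr.length]
        planter.plant(hr.start, reps, hr.name)

    # guide protospacers.  Antisense guides sit on the minus strand with
    # the window at anchor - (offset - 131); the sense guide is planted
    # upstream of the gene and its window context planted separately.
    targets = default_targets()
    for t in targets:
        off = t.offset_label
        if t.declared_strand == "antisense":
            win_start = cfg.anchor_window_start - (off - 131)
            q = win_start - 3
            planter.plant(q - 3, reverse_complement(t.spacer + t.pam), t.name)
        else:
            planter.plant(cfg.sense_plant_start, t.spacer + t.pam, t.name)

    ctx_pos, ctx_seq = _tables.SENSE_TARGET_CONTEXT
    planter.plant(ctx_pos, ctx_seq, "sense-target context")

    # conserved-variant reference contexts (SNV ref bases, indel anchors)
    for label, _cls, ref, alt, pos in _tables.CONSERVED_OUTSIDE_HR:
        if ref is not None:
            planter.plant(pos, ref, f"{label}@{pos}")
    planter.plant(12_426, "G", "egt deletion left flank")   # blocks left shift
    planter.plant(78_925, "C", "orf91 deletion left flank")
    planter.plant(7_304, "A", "orf1629 insertion anchor")   # != last inserted base
    planter.plant(44_073, "C", "orf51 insertion anchor")

    genome = Genome(id=cfg.genome_id, sequence=_to_seq(codes))

    # each spacer must occur exactly once genome-wide (either strand)
    for t in targets:
        n_hits = (genome.sequence.count(t.spacer)
                  + genome.sequence.count(reverse_complement(t.spacer)))
        if n_hits == 0:
            raise PlantingError(f"{t.name}: spacer not embedded")
        if n_hits > 1:
            raise PlantingError(f"{t.name}: spacer occurs {n_hits} times")

    feats = [Feature(h.name, "hr", h.start, h.start + h.length - 1)
             for h in cfg.hrs]
    feats += [Feature(label, fclass, start, end, strand)
              for label, fclass, start, end, strand in cfg.orfs]
    annotation = FeatureAnnotation(tuple(feats))
    for f in annotation.features:
        if f.end > cfg.length:
            raise PlantingError(f"{f.label}: feature outside genome")
    return genome, annotation, targets


# ---------------------------------------------------------------------------
# primer scheme


def design_tiling(genome: Genome, amplicon_len: int = 1000,
                  overlap: int = 100, primer_len: int = 22) -> PrimerScheme:
    """Arithmetic two-pool tiling of the genome.

    Consecutive amplicon *inserts* overlap by ``overlap`` bases (so an
    overlap of 0 makes inserts abut); odd-numbered amplicons go to pool
    1, even-numbered to pool 2.  The final amplicon is right-anchored at
    the genome end.  This is deliberately arithmetic tiling, not
    thermodynamic primer design.
    """
    n = len(genome)
    if amplicon_len <= 2 * primer_len + overlap:
        raise ValueError("amplicon_len must exceed 2*primer_len + overlap")
    if n < 2 * primer_len + 1:
        raise ValueError("genome shorter than one amplicon")

    step = amplicon_len - 2 * primer_len - overlap
    starts: list[int] = []
    if n <= amplicon_len:
        starts = [1]
    else:
        s = 1
        while s + amplicon_len - 1 < n:
            starts.append(s)
            s += step
        starts.append(n - amplicon_len + 1)

    amps = []
    for i, s in enumerate(starts):
        e = min(s + amplicon_len - 1, n)
        num = i + 1
        name = f"amp_{num:03d}"
        left = Primer(f"{name}_LEFT", s, s + primer_len - 1, "+",
                      1 if num % 2 else 2, seq=genome.slice(s, s + primer_len - 1))
        right = Primer(f"{name}_RIGHT", e - primer_len + 1, e, "-",
                       1 if num % 2 else 2,
                       seq=reverse_complement(genome.slice(e - primer_len + 1, e)))
        amps.append(Amplicon(name=name, number=num, left=left, right=right))
    return PrimerScheme(ref_id=genome.id, amplicons=tuple(amps))


def attach_primer_sequences(scheme: PrimerScheme, genome: Genome) -> PrimerScheme:
    """Fill primer sequences from the genome (needed after BED round-trip)."""
    amps = []
    for a in scheme.amplicons:
        left = replace(a.left, seq=genome.slice(a.left.start, a.left.end))
        right = replace(a.right, seq=reverse_complement(
            genome.slice(a.right.start, a.right.end)))
        amps.append(Amplicon(a.name, a.number, left, right))
    return PrimerScheme(ref_id=scheme.ref_id, amplicons=tuple(amps))


# ---------------------------------------------------------------------------
# read simulation


def _apply_variant(frag: str, amp_start: int, v: VariantSpec) -> str:
    """Apply a variant (genome coordinates) to an amplicon fragment."""
    i = v.pos - amp_start  # 0-based offset in fragment
    if v.alt.startswith("-"):
        deleted = v.alt[1:]
        if frag[i:i + len(deleted)] != deleted:
            raise ValueError(
                f"reference at {v.pos} is {frag[i:i + len(deleted)]!r}, "
                f"scenario deletes {deleted!r}")
        return frag[:i] + frag[i + len(deleted):]
    if v.alt.startswith("+"):
        return frag[:i + 1] + v.alt[1:] + frag[i + 1:]
    if len(v.alt) != 1:
        raise ValueError(f"SNV alt must be one base: {v.alt!r}")
    return frag[:i] + v.alt + frag[i + 1:]


def pairs_per_amplicon(depth: int, amplicon: Amplicon, read_length: int,
                       primer_len: int | None = None) -> int:
    """Read pairs needed for mean insert coverage >= depth."""
    plen = primer_len if primer_len is not None else (
        amplicon.left.end - amplicon.left.start + 1)
    span = amplicon.end - amplicon.start + 1
    insert = amplicon.insert_end - amplicon.insert_start + 1
    per_read = max(0, min(read_length, span) - plen)
    per_read = min(per_read, insert)
    if per_read == 0:
        raise ValueError(f"{amplicon.name}: reads never leave the primer")
    return math.ceil(depth * insert / (2 * per_read))


def _sample_reads(rng, frag_codes: np.ndarray, n: int, read_len: int,
                  indel_rate: float, qual_mean: float = 32.0,
                  qual_sd: float = 3.0, error_scale: float = 1.0):
    """Draw n error-bearing copies of one read template.

    Returns (list of code arrays, list of int quality arrays).  The
    common no-indel-error case is fully vectorised; the rare indel
    errors are applied per read.
    """
    L = min(read_len, len(frag_codes))
    quals = np.clip(np.rint(rng.normal(qual_mean, qual_sd, size=(n, L))),
                    2, 41).astype(np.int16)
    p_err = error_scale * 10.0 ** (-quals / 10.0)
    err = rng.random((n, L)) < p_err
    shift = rng.integers(1, 4, size=(n, L), dtype=np.uint8)
    mat = np.broadcast_to(frag_codes[:L], (n, L)).copy()
    mat[err] = (mat[err] + shift[err]) % 4

    seqs = list(mat)
    qlist = list(quals)
    if indel_rate > 0:
        hit = np.nonzero(rng.random(n) < indel_rate * L)[0]
        for i in hit:
            j = int(rng.integers(0, L))
            if rng.random() < 0.5 and L > 1:   # 1-bp deletion artefact
                seqs[i] = np.delete(seqs[i], j)
                qlist[i] = np.delete(qlist[i], j)
            else:                               # 1-bp insertion artefact
                b = np.uint8(rng.integers(0, 4))
                q = np.int16(rng.integers(20, 41))
                seqs[i] = np.insert(seqs[i], j, b)
                qlist[i] = np.insert(qlist[i], j, q)
    return seqs, qlist


def _qual_str(q: np.ndarray) -> str:
    return (q + 33).astype(np.uint8).tobytes().decode()


def simulate_reads(genome: Genome, scheme: PrimerScheme,
                   scenario: ScenarioSpec) -> list[list[ReadPair]]:
    """Simulate technical-replicate paired-end amplicon reads.

    Per amplicon, each fragment independently draws one haplotype (a
    single spiked variant with its scenario frequency, else reference),
    the full primer-to-primer fragment is "sequenced" from both ends,
    and per-base substitution errors are realised at the rate implied by
    each base's drawn Phred quality.  Deterministic per replicate seed.
    """
    variants = scenario.all_variants()
    for v in variants:
        a, b = v.interval()
        if a < 1 or b > len(genome):
            raise ValueError(f"variant at {v.pos} outside genome")
        if not any(am.insert_start <= a and b <= am.insert_end
                   for am in scheme.amplicons):
            warnings.warn(f"variant at {v.pos} outside every amplicon insert; "
                          "it will be undetectable", stacklevel=2)

    if scenario.region is not None:
        amplicons = scheme.overlapping(*scenario.region)
    else:
        amplicons = list(scheme.amplicons)
    if not amplicons:
        raise ValueError("no amplicons overlap the scenario region")

    replicates: list[list[ReadPair]] = []
    for rep_idx, seed in enumerate(scenario.seeds, start=1):
        rng = np.random.default_rng(seed)
        pairs: list[ReadPair] = []
        for amp in amplicons:
            local = [v for v in variants
                     if amp.start <= v.interval()[0]
                     and v.interval()[1] <= amp.end]
            probs = [v.frequency for v in local]
            p_ref = 1.0 - sum(probs)
            if p_ref <= 0:
                raise ValueError(
                    f"{amp.name}: summed variant frequency >= 1")

            ref_frag = genome.slice(amp.start, amp.end)
            frags = [ref_frag] + [_apply_variant(ref_frag, amp.start, v)
                                  for v in local]
            n_pairs = pairs_per_amplicon(scenario.depth, amp,
                                         scenario.read_length)
            hap = rng.choice(len(frags), size=n_pairs,
                             p=[p_ref] + probs)

            seq1 = [None] * n_pairs
            seq2 = [None] * n_pairs
            q1 = [None] * n_pairs
            q2 = [None] * n_pairs
            for h in range(len(frags)):
                idx = np.nonzero(hap == h)[0]
                if idx.size == 0:
                    continue
                fwd = _to_codes(frags[h])
                rev = _to_codes(reverse_complement(frags[h]))
                s1, qq1 = _sample_reads(rng, fwd, idx.size,
                                        scenario.read_length,
                                        scenario.indel_error_rate,
                                        scenario.qual_mean, scenario.qual_sd,
                                        scenario.error_scale)
                s2, qq2 = _sample_reads(rng, rev, idx.size,
                                        scenario.read_length,
                                        scenario.indel_error_rate,
                                        scenario.qual_mean, scenario.qual_sd,
                                        scenario.error_scale)
                for k, i in enumerate(idx):
                    seq1[i], q1[i] = s1[k], qq1[k]
                    seq2[i], q2[i] = s2[k], qq2[k]

            for i in range(n_pairs):
                pairs.append(ReadPair(
                    name=f"{scenario.sample_name}_{scenario.fraction}"
                         f"_rep{rep_idx}_{amp.name}_{i:05d}",
                    seq1=_to_seq(seq1[i]), seq2=_to_seq(seq2[i]),
                    qual1=_qual_str(q1[i]), qual2=_qual_str(q2[i]),
                    amplicon_of_origin=amp.name))
        replicates.append(pairs)
    return replicates


def write_fastq_pairs(pairs: list[ReadPair], r1_path, r2_path) -> None:
    """Write paired FASTQ (gzipped when the path ends in .gz)."""
    def opener(p):
        return gzip.open(p, "wt") if str(p).endswith(".gz") else open(p, "w")
    with opener(r1_path) as f1, opener(r2_path) as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual2}\n")


def read_fastq_pairs(r1_path, r2_path) -> list[ReadPair]:
    import pysam
    pairs = []
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for e1, e2 in zip(f1, f2):
            name = e1.name[:-2] if e1.name.endswith("/1") else e1.name
            pairs.append(ReadPair(name=name, seq1=e1.sequence, seq2=e2.sequence,
                                  qual1=e1.quality, qual2=e2.quality))
    return pairs


# ---------------------------------------------------------------------------
# bundled scenarios (published per-sample variant sets)

#: Region the gp64 scenarios restrict simulation to: spans every expected
#: edit window with margin, so only the amplicons that could carry an edit
#: are sequenced.
GP64_REGION = (106_900, 107_260)


def _seeds(base: int, k: int, replicates: int = 2) -> list[int]:
    return [(base * 1_000 + k * 10 + r) % (2**31 - 1)
            for r in range(1, replicates + 1)]


def table1_scenarios(base_seed: int = 1) -> dict[str, ScenarioSpec]:
    """One scenario per published sample x fraction cell with the printed
    deletion positions, alleles, and haplotype frequencies."""
    out = {}
    for k, ((target, fraction), rows) in enumerate(
            sorted(_tables.OBSERVED_DELETIONS.items())):
        name = f"{target}_{fraction}"
        out[name] = ScenarioSpec(
            sample_name=target, fraction=fraction,
            variants=[VariantSpec(pos=p, alt="-" + seq, frequency=f)
                      for p, seq, f in rows],
            seeds=_seeds(base_seed, k), region=GP64_REGION)
    return out


def control_scenarios(base_seed: int = 1) -> dict[str, ScenarioSpec]:
    """Scrambled and infected-only controls: no gp64 variants."""
    out = {}
    for k, name in enumerate(("scrambled", "infected_only")):
        out[name] = ScenarioSpec(
            sample_name=name, fraction="cell_pellet", variants=[],
            seeds=_seeds(base_seed, 100 + k), region=GP64_REGION)
    return out


def _hr_positions(annotation: FeatureAnnotation, names, count: int,
                  step: int, phase: int) -> list[tuple[str, int]]:
    """Deterministic distinct positions inside named hr intervals."""
    out = []
    feats = {f.label: f for f in annotation.features}
    per = math.ceil(count / len(names))
    for nm in names:
        f = feats[nm]
        for i in range(per):
            if len(out) >= count:
                break
            pos = f.start + phase + step * i
            if pos > f.end:
                raise ValueError(f"{nm} too short for fixture variants")
            out.append((nm, pos))
    return out


def stock_variants(genome: Genome,
                   annotation: FeatureAnnotation) -> list[VariantSpec]:
    """The virus-stock variant catalogue: 141 true variants, 97 of which
    are flagged as carried over into the passage assay; carried-over
    variants concentrate in hr1-hr3 with 14 residing outside the
    repeats."""
    rows: list[VariantSpec] = []
    n_hr_conserved = (_tables.STOCK_CARRIED_OVER
                      - _tables.CARRIED_OVER_OUTSIDE_HR)  # 83
    n_unique = (_tables.STOCK_TOTAL_VARIANTS
                - _tables.STOCK_CARRIED_OVER)             # 44

    for i, (_nm, pos) in enumerate(_hr_positions(
            annotation, ("hr1", "hr2", "hr3"), n_hr_conserved, 3, 0)):
        ref = genome.slice(pos, pos)
        alt = _BASES[(_BASES.index(ref) + 1) % 4]
        rows.append(VariantSpec(pos=pos, alt=alt,
                                frequency=0.02 + 0.0005 * (i % 40),
                                conserved=True))
    for _lab, _cls, _ref, alt, pos in _tables.CONSERVED_OUTSIDE_HR:
        rows.append(VariantSpec(pos=pos, alt=alt, frequency=0.03,
                                conserved=True))
    for i, (_nm, pos) in enumerate(_hr_positions(
            annotation, ("hr1", "hr2", "hr3"), n_unique, 3, 1)):
        ref = genome.slice(pos, pos)
        alt = _BASES[(_BASES.index(ref) + 2) % 4]
        rows.append(VariantSpec(pos=pos, alt=alt,
                                frequency=0.015 + 0.001 * (i % 20),
                                conserved=False))
    assert len(rows) == _tables.STOCK_TOTAL_VARIANTS
    return rows


def stock_scenario(genome: Genome, annotation: FeatureAnnotation,
                   base_seed: int = 1) -> ScenarioSpec:
    return ScenarioSpec(
        sample_name="virus_stock", fraction="stock",
        variants=[], background_variants=stock_variants(genome, annotation),
        seeds=_seeds(base_seed, 200))


def write_table1_scenarios(out_dir, genome: Genome | None = None,
                           annotation: FeatureAnnotation | None = None,
                           base_seed: int = 1) -> dict[str, str]:
    """Emit every bundled scenario as a YAML file; returns name -> path."""
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if genome is None or annotation is None:
        genome, annotation, _ = build_reference()
    scenarios = dict(table1_scenarios(base_seed))
    scenarios.update(control_scenarios(base_seed))
    scenarios["virus_stock"] = stock_scenario(genome, annotation, base_seed)
    paths = {}
    for name, sc in scenarios.items():
        p = out_dir / f"{name}.yaml"
        sc.to_yaml(p)
        paths[name] = str(p)
    return paths


# ---------------------------------------------------------------------------
# conservation worked-example tables


def _variant_row(genome: Genome, v: VariantSpec, sample: str) -> dict:
    ref = genome.slice(v.pos, v.pos)
    return {"REGION": genome.id, "POS": v.pos, "REF": ref, "ALT": v.alt,
            "REF_DP": 380, "REF_RV": 190, "REF_QUAL": 33.0,
            "ALT_DP": int(round(400 * v.frequency)), "ALT_RV": 0,
            "ALT_QUAL": 32.0, "ALT_FREQ": v.frequency, "TOTAL_DP": 400,
            "PVAL": 0.001, "PASS": True, "GFF_FEATURE": "",
            "SAMPLE": sample}


def conservation_fixture(genome: Genome | None = None,
                         annotation: FeatureAnnotation | None = None):
    """Variant tables reproducing the passage-conservation bookkeeping.

    Returns ``(stock, ti_tables, control_tables)`` where the stock table
    has 141 variant keys, the union of the passage (T-I) tables carries
    exactly the 97 stock keys flagged conserved, and the T-I tables also
    contain control-shared and sample-unique keys so every label class
    is populated.
    """
    if genome is None or annotation is None:
        genome, annotation, _ = build_reference()
    stock = stock_variants(genome, annotation)
    conserved = [v for v in stock if v.conserved]
    assert len(conserved) == _tables.STOCK_CARRIED_OVER

    # keys absent from the stock: shared with controls (hr4a/hr5) and
    # unique to targeted samples
    shared = [VariantSpec(pos=p, alt="T" if genome.slice(p, p) != "T" else "A",
                          frequency=0.02)
              for (_nm, p) in _hr_positions(annotation, ("hr4a", "hr5"), 6, 4, 2)]
    unique = [VariantSpec(pos=p, alt="G" if genome.slice(p, p) != "G" else "C",
                          frequency=0.015)
              for p in (3_970, 6_390, 12_500, 78_700)]

    def table(vs, sample):
        return pd.DataFrame([_variant_row(genome, v, sample) for v in vs])

    stock_tbl = table(stock, "virus_stock")
    ti_tables = {
        "gp64+131_cell_pellet": table(conserved[:60] + shared[:3] + unique[:2],
                                      "gp64+131_cell_pellet"),
        "gp64-160_supernatant": table(conserved[40:] + shared[3:] + unique[2:],
                                      "gp64-160_supernatant"),
    }
    control_tables = {
        "scrambled": table(shared[:4], "scrambled"),
        "infected_only": table(shared[2:], "infected_only"),
    }
    return stock_tbl, ti_tables, control_tables
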