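"""End-to-end orchestration: simulate (or load) reads, align, clip,
filter, call, replicate-filter, and run the targeting/conservation
analyses from a single configuration.

Every stage writes its interchange artefact (SAM, TSV) into the run
directory, and the log records each threshold and seed so every number
in a report traces back to a config value.  Re-running with the same
config is bit-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import synthetic_data as sd
from .amplicon_alignment import (AlignConfig, align_pairs, emit_sam,
                                 left_normalize_indels, parse_sam)
from .crispr_targeting import default_targets, target_windows, match_on_target
from .read_filtering import FilterConfig, apply_filters
from .replicate_concordance import intersect_replicates, true_mutations
from .variant_calling import (CallConfig, build_pileup, call_variants,
                              read_variant_tsv, write_variant_tsv)
from .variant_comparison import annotate_regions, compare_to_stock

log = logging.getLogger("ampedit")


@dataclass
class PipelineConfig:
    outdir: str = "ampedit_run"
    amplicon_len: int = 400
    overlap: int = 100
    primer_len: int = 22
    filters: FilterConfig = field(default_factory=FilterConfig)
    calling: CallConfig = field(default_factory=CallConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    base_seed: int = 1
    write_fastq: bool = False
    reference: sd.ReferenceConfig = field(default_factory=sd.ReferenceConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("outdir", "amplicon_len", "overlap", "primer_len",
                    "base_seed", "write_fastq"):
            if key in doc:
                setattr(cfg, key, doc[key])
        if "filters" in doc:
            cfg.filters = FilterConfig(**doc["filters"])
        if "calling" in doc:
            cfg.calling = CallConfig(**doc["calling"])
        if "align" in doc:
            cfg.align = AlignConfig(**doc["align"])
        if "reference" in doc:
            cfg.reference = sd.ReferenceConfig(**doc["reference"])
        return cfg


def _log_thresholds(cfg: PipelineConfig) -> None:
    log.info("filters: mapq>=%d, flag mask %d, post-clip length >=%d",
             cfg.filters.mapq_min, cfg.filters.flag_mask,
             cfg.filters.min_post_clip_len)
    log.info("calling: baseQ>=%d, frequency>=%g, alpha=%g",
             cfg.calling.min_baseq, cfg.calling.min_freq, cfg.calling.alpha)


def call_replicate(pairs, genome, scheme, cfg: PipelineConfig,
                   sam_path=None) -> pd.DataFrame:
    """Align one replicate's read pairs and call variants."""
    alns = align_pairs(pairs, scheme, genome, cfg.align)
    alns = [left_normalize_indels(a, genome) if not a.is_unmapped else a
            for a in alns]
    if sam_path is not None:
        emit_sam(alns, genome, sam_path)
    kept = apply_filters(alns, scheme, cfg.filters)
    if not kept:
        return _empty_table()
    pile = build_pileup(kept, genome, cfg.calling.min_baseq)
    return call_variants(pile, genome, cfg.calling)


def _empty_table() -> pd.DataFrame:
    from .variant_calling import TSV_COLUMNS
    return pd.DataFrame(columns=TSV_COLUMNS)


def run_scenario(genome, scheme, scenario: sd.ScenarioSpec,
                 cfg: PipelineConfig, outdir: Path | None = None) -> dict:
    """Simulate a scenario in technical replicates and produce
    per-replicate, merged, and true-mutation variant tables."""
    name = f"{scenario.sample_name}_{scenario.fraction}"
    log.info("scenario %s: depth %dx, %d replicates, seeds %s", name,
             scenario.depth, scenario.replicates, scenario.seeds)
    replicates = sd.simulate_reads(genome, scheme, scenario)
    rep_tables = []
    for r, pairs in enumerate(replicates, start=1):
        sam_path = None
        if outdir is not None:
            sam_path = outdir / f"{name}_rep{r}.sam"
            if cfg.write_fastq:
                sd.write_fastq_pairs(pairs, outdir / f"{name}_rep{r}_R1.fastq",
                                     outdir / f"{name}_rep{r}_R2.fastq")
        tbl = call_replicate(pairs, genome, scheme, cfg, sam_path)
        rep_tables.append(tbl)
        if outdir is not None:
            write_variant_tsv(tbl, outdir / f"{name}_rep{r}.tsv")

    nonempty = [t for t in rep_tables]
    merged = (intersect_replicates(nonempty)
              if all(len(t) for t in nonempty) and len(nonempty) >= 2
              else _empty_table())
    true = true_mutations(merged, cfg.calling.alpha) if len(merged) else merged
    if outdir is not None:
        write_variant_tsv(merged, outdir / f"{name}.merged.tsv")
        write_variant_tsv(true, outdir / f"{name}.true.tsv")
    return {"name": name, "replicates": rep_tables, "merged": merged,
            "true": true}


def run_pipeline(config: PipelineConfig,
                 scenarios: dict[str, sd.ScenarioSpec] | None = None) -> dict:
    """Full study run: build the fixture reference and scheme, process
    every scenario, and write targeting and conservation reports.

    Returns a results dict with the genome, scheme, per-scenario tables,
    the on-target match report, and the conservation report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        _log_thresholds(config)
        genome, annotation, targets = sd.build_reference(config.reference)
        genome.to_fasta(outdir / "reference.fasta")
        scheme = sd.design_tiling(genome, config.amplicon_len,
                                  config.overlap, config.primer_len)
        scheme.to_bed(outdir / "scheme.bed")
        annotation.to_bed(outdir / "features.bed", genome.id)
        windows = target_windows(genome, targets)
        log.info("edit windows: %s",
                 {n: (w.start, w.end) for n, w in windows.items()})

        if scenarios is None:
            scenarios = dict(sd.table1_scenarios(config.base_seed))
            scenarios.update(sd.control_scenarios(config.base_seed))

        results = {}
        for key, scen in scenarios.items():
            results[key] = run_scenario(genome, scheme, scen, config, outdir)

        on_target_rows = []
        for key, res in results.items():
            labelled, counts = match_on_target(res["true"], windows)
            write_variant_tsv(labelled, outdir / f"{res['name']}.matched.tsv")
            on_target = labelled[
                labelled["TARGET_LABEL"].str.startswith("on_target")]
            for _, row in on_target.iterrows():
                on_target_rows.append({"SCENARIO": key, **row.to_dict()})
            log.info("%s: %d true variant(s), window hits %s",
                     key, len(res["true"]),
                     {k: v for k, v in counts.items() if v})
        on_target_table = pd.DataFrame(on_target_rows)
        if len(on_target_table):
            on_target_table.to_csv(outdir / "on_target_report.tsv",
                                   sep="\t", index=False)

        stock_tbl, ti_tables, control_tables = sd.conservation_fixture(
            genome, annotation)
        report = compare_to_stock(list(ti_tables.values()), stock_tbl,
                                  list(control_tables.values()))
        with open(outdir / "conservation_report.txt", "w") as fh:
            fh.write(f"percent_conserved\t{report.percent_conserved:.1f}\n")
            for lab, n in sorted(report.counts.items()):
                fh.write(f"{lab}\t{n}\n")
        log.info("conservation: %.1f%% of stock variants carried over",
                 report.percent_conserved)

        return {"genome": genome, "annotation": annotation,
                "scheme": scheme, "windows": windows,
                "scenarios": results, "on_target": on_target_table,
                "conservation": report}
    finally:
        log.removeHandler(handler)
        handler.close()


def recover_table1(base_seed: int = 1, config: PipelineConfig | None = None,
                   genome=None, scheme=None):
    """Simulate every bundled published scenario, run the full pipeline,
    and pool the true on-target deletion calls.

    Returns ``(windows, true_tables, pooled)`` where ``pooled`` holds
    one row per recovered on-target deletion with its scenario of
    origin and merged statistics.
    """
    cfg = config or PipelineConfig(base_seed=base_seed)
    if genome is None or scheme is None:
        genome, _annotation, targets = sd.build_reference(cfg.reference)
        scheme = sd.design_tiling(genome, cfg.amplicon_len, cfg.overlap,
                                  cfg.primer_len)
    else:
        targets = default_targets()
    windows = target_windows(genome, targets)

    true_tables: dict[str, pd.DataFrame] = {}
    pooled = []
    for name, scen in sd.table1_scenarios(base_seed).items():
        res = run_scenario(genome, scheme, scen, cfg, None)
        true_tables[name] = res["true"]
        if res["true"].empty:
            continue
        labelled, _ = match_on_target(res["true"], windows)
        dele = labelled[labelled["ALT"].str.startswith("-")
                        & labelled["TARGET_LABEL"].str.startswith("on_target")]
        if len(dele):
            pooled.append(dele.assign(SCENARIO=name))
    pooled = (pd.concat(pooled, ignore_index=True) if pooled
              else _empty_table().assign(SCENARIO=""))
    return windows, true_tables, pooled


def checksum_tables(outdir) -> dict[str, str]:
    """MD5 of every TSV in a run directory (determinism checks)."""
    out = {}
    for p in sorted(Path(outdir).glob("*.tsv")):
        out[p.name] = hashlib.md5(p.read_bytes()).hexdigest()
    return out
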