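"""Cross-sample and cross-passage variant comparison.

Classifies passage-assay (T-I) variants as conserved-from-stock,
shared-with-controls, or unique; annotates variants with the genomic
feature they fall in (homologous repeats vs ORFs vs regulatory
regions); and produces per-repeat mutation summaries in "total" and
"filtered" (controls and stock carry-overs removed) flavours.

Variant identity across samples and passages is exact key match
(region, position, ref, alt) after upstream left-normalisation; no
positional tolerance is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .replicate_concordance import KEY
from .synthetic_data import FeatureAnnotation


def variant_keys(table: pd.DataFrame) -> set[tuple]:
    if table.empty:
        return set()
    return set(map(tuple, table[KEY].itertuples(index=False)))


@dataclass
class ConservationReport:
    labels: pd.DataFrame        # T-I variant keys with their label
    counts: dict[str, int]      # per-label counts over T-I variants
    percent_conserved: float    # carried-over stock variants, percent


def compare_to_stock(ti_tables: list[pd.DataFrame], stock: pd.DataFrame,
                     controls: list[pd.DataFrame] | None = None,
                     ) -> ConservationReport:
    """Label every passage-assay variant and quantify stock carry-over.

    A T-I variant key found in the stock is ``conserved_from_stock``;
    otherwise a key found in any control table is ``control_shared``;
    the rest are ``unique``.  ``percent_conserved`` is the share of
    stock keys re-observed in the union of the T-I tables.
    """
    stock_keys = variant_keys(stock)
    if not stock_keys:
        raise ValueError("stock table is empty; percent conserved undefined")
    control_keys: set[tuple] = set()
    for c in controls or []:
        control_keys |= variant_keys(c)

    ti_keys: set[tuple] = set()
    for t in ti_tables:
        ti_keys |= variant_keys(t)

    rows = []
    for key in sorted(ti_keys, key=lambda k: (k[1], k[3])):
        if key in stock_keys:
            label = "conserved_from_stock"
        elif key in control_keys:
            label = "control_shared"
        else:
            label = "unique"
        rows.append((*key, label))
    labels = pd.DataFrame(rows, columns=KEY + ["LABEL"])
    counts = labels["LABEL"].value_counts().to_dict()
    for lab in ("conserved_from_stock", "control_shared", "unique"):
        counts.setdefault(lab, 0)
    percent = 100.0 * len(stock_keys & ti_keys) / len(stock_keys)
    return ConservationReport(labels=labels, counts=counts,
                              percent_conserved=percent)


def _allele_interval(pos: int, alt: str) -> tuple[int, int]:
    if alt.startswith("-"):
        return pos, pos + len(alt) - 2
    return pos, pos


def _classify(pos_a: int, pos_b: int, annotation: FeatureAnnotation) -> str:
    """Feature label for an interval: majority overlap, ties to the
    leftmost feature; intergenic if nothing overlaps."""
    best = None  # (overlap, -start, label)
    for f in annotation.features:
        ov = min(pos_b, f.end) - max(pos_a, f.start) + 1
        if ov > 0:
            cand = (ov, -f.start, f)
            if best is None or cand[:2] > best[:2]:
                best = cand
    if best is None:
        return "intergenic"
    f = best[2]
    return f"{f.feat_class}:{f.label}"


def annotate_regions(table: pd.DataFrame, annotation: FeatureAnnotation,
                     target_windows: dict | None = None) -> pd.DataFrame:
    """Add a REGION_CLASS column (hr:/orf:/promoter:/utr:<name> or
    intergenic); variants inside a guide's expected edit window are
    labelled on_target:<guide> instead."""
    table = table.copy()
    labels = []
    for _, row in table.iterrows():
        a, b = _allele_interval(int(row["POS"]), str(row["ALT"]))
        hit = None
        for name, win in (target_windows or {}).items():
            if win.intersects(a, b):
                hit = f"on_target:{name}"
                break
        labels.append(hit or _classify(a, b, annotation))
    table["REGION_CLASS"] = labels
    return table


def summarize_hr_counts(tables: dict[tuple[str, str], pd.DataFrame],
                        annotation: FeatureAnnotation,
                        stock: pd.DataFrame | None = None,
                        controls: list[pd.DataFrame] | None = None):
    """Per-sample, per-fraction mutation counts in each repeat region.

    Returns ``(total, filtered, non_hr)``: ``total`` counts every true
    hr mutation, ``filtered`` drops keys present in any control or in
    the stock (unique new mutations), and ``non_hr`` lists variants
    outside both the repeats and the guide windows with their feature
    label.  ``tables`` maps (sample, fraction) to a labelled table (see
    :func:`annotate_regions`).
    """
    drop_keys: set[tuple] = set()
    for c in controls or []:
        drop_keys |= variant_keys(c)
    if stock is not None:
        drop_keys |= variant_keys(stock)

    total_rows, filtered_rows, nonhr_rows = [], [], []
    for (sample, fraction), tbl in tables.items():
        if tbl.empty:
            continue
        if "REGION_CLASS" not in tbl.columns:
            tbl = annotate_regions(tbl, annotation)
        for _, row in tbl.iterrows():
            cls = row["REGION_CLASS"]
            key = tuple(row[k] for k in KEY)
            if cls.startswith("hr:"):
                hr = cls.split(":", 1)[1]
                total_rows.append((sample, fraction, hr, *key))
                if key not in drop_keys:
                    filtered_rows.append((sample, fraction, hr, *key))
            elif not cls.startswith("on_target:"):
                if key not in drop_keys:
                    nonhr_rows.append((sample, fraction, cls, *key))

    cols = ["SAMPLE", "FRACTION", "HR"] + KEY

    def summarise(rows):
        df = pd.DataFrame(rows, columns=cols)
        return (df.groupby(["SAMPLE", "FRACTION", "HR"])
                .size().rename("N_MUTATIONS").reset_index())

    non_hr = pd.DataFrame(
        nonhr_rows, columns=["SAMPLE", "FRACTION", "REGION_CLASS"] + KEY)
    return summarise(total_rows), summarise(filtered_rows), non_hr
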