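"""Technical-replicate concordance filtering of variant tables.

A variant is kept only when its key (region, position, ref, alt) is
called in every replicate; upstream left-normalisation makes the key
comparison exact.  Merge statistics are conservative: mean frequency,
maximum p-value, PASS only if every replicate passes.
"""

from __future__ import annotations

import pandas as pd

KEY = ["REGION", "POS", "REF", "ALT"]


def intersect_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Intersect >=2 per-replicate variant tables into one merged table.

    Output rows are exactly the keys present in all inputs with
    ALT_FREQ averaged, PVAL maximised, PASS and-ed, and depth columns
    averaged across replicates; N_REPS records the evidence count.
    """
    if len(tables) < 2:
        raise ValueError("need at least two replicate tables")
    for t in tables:
        if t.duplicated(KEY).any():
            raise ValueError("duplicate variant keys within a replicate")

    keys = None
    for t in tables:
        k = set(map(tuple, t[KEY].itertuples(index=False)))
        keys = k if keys is None else keys & k
    if not keys:
        return tables[0].iloc[0:0].copy()

    frames = []
    for i, t in enumerate(tables):
        sel = t[t[KEY].apply(tuple, axis=1).isin(keys)].copy()
        frames.append(sel.set_index(KEY))
    merged = frames[0].copy()
    mean_cols = [c for c in ("REF_DP", "REF_RV", "REF_QUAL", "ALT_DP",
                             "ALT_RV", "ALT_QUAL", "ALT_FREQ", "TOTAL_DP")
                 if c in merged.columns]
    for c in mean_cols:
        merged[c] = sum(f[c] for f in frames) / len(frames)
    merged["PVAL"] = pd.concat([f["PVAL"] for f in frames], axis=1).max(axis=1)
    merged["PASS"] = pd.concat([f["PASS"] for f in frames],
                               axis=1).all(axis=1)
    merged["N_REPS"] = len(frames)
    out = merged.reset_index()
    return out.sort_values(["POS", "ALT"], kind="mergesort",
                           ignore_index=True)


def true_mutations(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows meeting the true-mutation criterion (p <= alpha, boundary
    inclusive, as recorded in PASS at call time)."""
    if table.empty:
        return table.copy()
    keep = table["PVAL"] <= alpha
    return table[keep].reset_index(drop=True)
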