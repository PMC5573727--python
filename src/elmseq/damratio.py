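"""CPM normalization, the DAMRatio statistic, read filtering, replicates.

The DAMRatio for a variant is the ratio of its pseudo-counted
counts-per-million in the MboI-digestion survivor pool to that in the
DpnI-digestion survivor pool:

    CPM = (X + 1) / (N + 1) * 1e6
    DAMRatio = CPM_mbo / CPM_dpn

MboI cuts unmethylated GATC and DpnI cuts methylated GATC, so a high ratio
means the variant's construct was heavily adenine-methylated, i.e. it
expressed more Dam methyltransferase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .readproc import CountTable


def cpm(x, n):
    """Pseudo-counted counts per million: (x + 1) / (n + 1) * 1e6."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(x < 0) or np.any(n < x):
        raise ValueError("need 0 <= x <= n")
    return (x + 1.0) / (n + 1.0) * 1e6


def dam_ratio(cpm_mbo, cpm_dpn):
    """DAMRatio = CPM(MboI pool) / CPM(DpnI pool)."""
    cpm_mbo = np.asarray(cpm_mbo, dtype=float)
    cpm_dpn = np.asarray(cpm_dpn, dtype=float)
    if np.any(cpm_mbo <= 0) or np.any(cpm_dpn <= 0):
        raise ValueError("CPM values must be positive")
    return cpm_mbo / cpm_dpn


def apply_read_filter(table: CountTable, threshold: int = 100) -> CountTable:
    """Keep variants seen more than ``threshold`` times in either digestion.

    Strictly more than ``threshold`` reads in the DpnI or the MboI pool; the
    uncut pool is not consulted. Idempotent.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    keep = (table.counts["dpn"] > threshold) | (table.counts["mbo"] > threshold)
    filtered = CountTable(counts=table.counts.loc[keep].copy(),
                          rejected=dict(table.rejected))
    filtered.rejected = dict(filtered.rejected)
    filtered.rejected["read_filter"] = {
        "threshold": threshold,
        "retained": int(keep.sum()),
        "removed": int((~keep).sum()),
    }
    return filtered


def dam_table(table: CountTable, threshold: int = 100) -> pd.DataFrame:
    """Per-variant CPMs, DAMRatio and log10 DAMRatio with the read filter.

    CPMs use the *unfiltered* condition totals (accepted reads per pool);
    the filter only flags/removes low-support variants.
    """
    totals = table.totals
    df = pd.DataFrame(index=table.counts.index)
    for cond in ("uncut", "dpn", "mbo"):
        df[f"cpm_{cond}"] = cpm(table.counts[cond], totals[cond])
    df["damratio"] = dam_ratio(df["cpm_mbo"], df["cpm_dpn"])
    df["log10_damratio"] = np.log10(df["damratio"])
    df["pass_filter"] = (table.counts["dpn"] > threshold) | (
        table.counts["mbo"] > threshold
    )
    for cond in ("uncut", "dpn", "mbo"):
        df[f"reads_{cond}"] = table.counts[cond]
    return df


def combine_replicates(
    rep_a: pd.DataFrame,
    rep_b: pd.DataFrame,
    column: str = "log10_damratio",
    min_shared: int = 50,
) -> tuple[pd.DataFrame, dict]:
    """Put replicate B on replicate A's log10 scale and average.

    Ordinary least squares of B on A over shared variants gives
    ``B = slope * A + intercept``; B's values are mapped back through the
    fitted line (``(B - intercept) / slope``) and the combined value is the
    mean of the available values per variant. Variants present in a single
    replicate keep that (mapped) value.
    """
    shared = rep_a.index.intersection(rep_b.index)
    if len(shared) < min_shared:
        raise ValueError(
            f"insufficient_overlap: {len(shared)} shared variants < {min_shared}"
        )
    a = rep_a.loc[shared, column].to_numpy(dtype=float)
    b = rep_b.loc[shared, column].to_numpy(dtype=float)
    slope, intercept = np.polyfit(a, b, 1)
    if abs(slope) < 1e-12:
        raise ValueError("degenerate regression: slope ~ 0")
    r = float(np.corrcoef(a, b)[0, 1])

    b_mapped = (rep_b[column] - intercept) / slope
    all_idx = rep_a.index.union(rep_b.index)
    stacked = pd.concat(
        [rep_a[column].reindex(all_idx), b_mapped.reindex(all_idx)], axis=1
    )
    combined = pd.DataFrame(index=all_idx)
    combined[column] = stacked.mean(axis=1)
    combined["n_replicates"] = stacked.notna().sum(axis=1)
    fit = {
        "slope": float(slope),
        "intercept": float(intercept),
        "pearson_r": r,
        "n_shared": int(len(shared)),
        "mapping": "ols_b_on_a_inverse_then_mean",
    }
    return combined, fit
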