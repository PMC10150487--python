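"""Target-group stratified comparisons.

Expression/half-life/TE values are stratified by target class and each
group is compared to a reference group (Non-targets by default) with a
two-sided Mann-Whitney U test; empirical CDFs of the same values are the
matching visual.  Also: translation efficiency (ribosome-footprint FPKM
over mRNA FPKM on genes expressed > 1 FPKM in both assays) and the
differential-expression threshold rule (fold change >= 2 in either
direction and p < 0.05) applied to supplied per-gene statistics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .targets import InputError


def log2_fold_change(mutant: pd.DataFrame, wt: pd.DataFrame) -> pd.Series:
    """Per-gene log2(mean mutant / mean WT) across replicate columns.

    Gene sets are intersected (with a warning if they differ); genes whose
    WT mean is zero are excluded.
    """
    common = mutant.index.intersection(wt.index)
    if len(common) != len(mutant.index) or len(common) != len(wt.index):
        warnings.warn("gene sets differ between tables; intersecting")
    mean_mut = mutant.loc[common].mean(axis=1)
    mean_wt = wt.loc[common].mean(axis=1)
    usable = mean_wt > 0
    out = np.log2(mean_mut[usable] / mean_wt[usable])
    out.name = "log2fc"
    return out


def mann_whitney_group_test(
    values: pd.Series,
    assignments: pd.Series,
    reference: str = "Non-target",
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U of each group against the reference group.

    Midrank tie handling; exact enumeration for small untied samples and
    the tie-corrected normal approximation otherwise (scipy
    ``method="auto"``).  Groups with < 2 members are skipped.
    """
    values = values.dropna()
    assignments = assignments.loc[assignments.index.intersection(values.index)]
    ref_vals = values[assignments.index[assignments == reference]]
    if len(ref_vals) == 0:
        raise InputError(f"reference group {reference!r} is empty")
    labels = groups if groups is not None else [
        g for g in assignments.unique() if g != reference
    ]
    rows = []
    for label in labels:
        grp = values[assignments.index[assignments == label]]
        if len(grp) < 2:
            rows.append({"group": label, "n": len(grp), "n_ref": len(ref_vals),
                         "U": np.nan, "p_value": np.nan, "median_shift": np.nan,
                         "skipped": True})
            continue
        u, p = stats.mannwhitneyu(grp, ref_vals, alternative="two-sided", method="auto")
        rows.append({
            "group": label,
            "n": len(grp),
            "n_ref": len(ref_vals),
            "U": float(u),
            "p_value": float(p),
            "median_shift": float(grp.median() - ref_vals.median()),
            "skipped": False,
        })
    return pd.DataFrame(rows).set_index("group")


def translation_efficiency(
    ribo: pd.DataFrame,
    rna: pd.DataFrame,
    min_fpkm: float = 1.0,
    fpkm_column: str = "FPKM",
) -> pd.DataFrame:
    """TE = FPKM_ribo / FPKM_RNA on genes with FPKM strictly > ``min_fpkm``
    in both assays."""
    common = ribo.index.intersection(rna.index)
    fr = ribo.loc[common, fpkm_column]
    fn = rna.loc[common, fpkm_column]
    keep = (fr > min_fpkm) & (fn > min_fpkm)
    return pd.DataFrame(
        {"fpkm_ribo": fr[keep], "fpkm_rna": fn[keep], "te": fr[keep] / fn[keep]}
    )


def de_filter(
    table: pd.DataFrame,
    min_fc: float = 2.0,
    alpha: float = 0.05,
    fc_column: str = "fold_change",
    p_column: str = "p_value",
) -> pd.DataFrame:
    """Differential-expression rule on a supplied statistics table.

    Keeps genes with fold change >= ``min_fc`` or <= 1/``min_fc`` (ratio
    scale, either direction) and p < ``alpha``; adds a ``direction`` column
    (up/down).  The p-values are inputs — typically from the upstream DE
    package — not recomputed here.
    """
    missing = [c for c in (fc_column, p_column) if c not in table.columns]
    if missing:
        raise InputError(f"DE table missing column(s) {missing}")
    fc = table[fc_column]
    if (fc <= 0).any():
        raise InputError("fold changes must be positive ratios")
    keep = ((fc >= min_fc) | (fc <= 1.0 / min_fc)) & (table[p_column] < alpha)
    out = table[keep].copy()
    out["direction"] = np.where(out[fc_column] >= min_fc, "up", "down")
    return out


def welch_pvalues(mutant: pd.DataFrame, wt: pd.DataFrame) -> pd.Series:
    """Fallback per-gene Welch t-test across replicate columns (for use
    when no upstream DE p-values are available)."""
    common = mutant.index.intersection(wt.index)
    res = stats.ttest_ind(
        mutant.loc[common].to_numpy(dtype=float),
        wt.loc[common].to_numpy(dtype=float),
        axis=1,
        equal_var=False,
    )
    return pd.Series(res.pvalue, index=common, name="p_value")


def ecdf_frame(values: pd.Series, assignments: pd.Series) -> pd.DataFrame:
    """Long-format right-continuous ECDF coordinates per group (for plots)."""
    rows = []
    for label, idx in assignments.groupby(assignments).groups.items():
        v = np.sort(values.loc[values.index.intersection(idx)].dropna().to_numpy())
        if len(v) == 0:
            continue
        rows.append(pd.DataFrame({
            "group": label, "value": v, "ecdf": np.arange(1, len(v) + 1) / len(v),
        }))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["group", "value", "ecdf"])


def plot_ecdf(values: pd.Series, assignments: pd.Series, path: str, xlabel: str = "value") -> None:
    """Write an ECDF figure (convenience artifact; the tests' surface is
    the U statistics, not the drawing)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for label, grp in ecdf_frame(values, assignments).groupby("group"):
        ax.step(grp["value"], grp["ecdf"], where="post", label=f"{label} (n={len(grp)})")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("cumulative fraction")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
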