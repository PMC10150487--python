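"""Target-gene classification from reader/mark peak intervals.

Genes are stratified by m6A-reader binding: any ECT2 peak makes a gene an
ECT2 target; an ECT2 peak overlapping (>= 1 nt, same strand) an m6A peak on
the same gene upgrades it to an ECT2 & m6A target; genes with neither an
ECT2 peak nor an m6A site are Non-targets.  Genes carrying only an m6A site
belong to none of the three classes and are reported as excluded.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

LABEL_NON = "Non-target"
LABEL_ECT2 = "ECT2 target"
LABEL_ECT2_M6A = "ECT2 & m6A target"
LABEL_EXCLUDED = "excluded"

_PEAK_COLS = ("chrom", "start", "end", "strand", "gene_id")


class InputError(ValueError):
    pass


def _check_peaks(peaks: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = [c for c in _PEAK_COLS if c not in peaks.columns]
    if missing:
        raise InputError(f"{name} peak table missing column(s) {missing}")
    if len(peaks) and (peaks["end"] <= peaks["start"]).any():
        raise InputError(f"{name} peak table has intervals with end <= start")
    return peaks


def classify_targets(
    gene_ids: list[str],
    ect2: pd.DataFrame,
    m6a: pd.DataFrame,
    pab2: pd.DataFrame | None = None,
    pab4: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene target classification table.

    Peaks must carry ``gene_id`` (peaks on genes absent from ``gene_ids``
    are skipped with a warning).  Returns one row per gene with ``label``,
    ``ect2_site_count``, ``has_m6a`` and optional PAB2/PAB4 partner flags.
    """
    known = set(gene_ids)

    def _by_gene(peaks: pd.DataFrame, name: str) -> dict[str, pd.DataFrame]:
        peaks = _check_peaks(peaks, name)
        unknown = set(peaks["gene_id"]) - known
        if unknown:
            warnings.warn(f"{name}: skipping {len(unknown)} peak gene(s) not in annotation")
            peaks = peaks[peaks["gene_id"].isin(known)]
        return {gid: grp for gid, grp in peaks.groupby("gene_id")}

    ect2_by = _by_gene(ect2, "ECT2")
    m6a_by = _by_gene(m6a, "m6A")
    pab2_genes = set(_by_gene(pab2, "PAB2")) if pab2 is not None else set()
    pab4_genes = set(_by_gene(pab4, "PAB4")) if pab4 is not None else set()

    rows = []
    for gid in gene_ids:
        e = ect2_by.get(gid)
        m = m6a_by.get(gid)
        n_sites = 0 if e is None else len(e)
        overlap = False
        if e is not None and m is not None:
            tree = IntervalTree()
            for s, en, st in zip(m["start"], m["end"], m["strand"]):
                tree.addi(int(s), int(en), st)
            for s, en, st in zip(e["start"], e["end"], e["strand"]):
                if any(iv.data == st for iv in tree.overlap(int(s), int(en))):
                    overlap = True
                    break
        if n_sites and overlap:
            label = LABEL_ECT2_M6A
        elif n_sites:
            label = LABEL_ECT2
        elif m is not None:
            label = LABEL_EXCLUDED
        else:
            label = LABEL_NON
        rows.append(
            {
                "gene_id": gid,
                "label": label,
                "ect2_site_count": n_sites,
                "has_m6a": m is not None,
                "PAB2": gid in pab2_genes,
                "PAB4": gid in pab4_genes,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def bin_by_site_count(assignments: pd.DataFrame) -> pd.DataFrame:
    """Add a ``site_count_bin`` column partitioning ECT2 targets into
    {1, 2, >2} binding sites (non-targets get NA)."""
    out = assignments.copy()
    n = out["ect2_site_count"]
    bins = pd.Series(pd.NA, index=out.index, dtype="object")
    bins[n == 1] = "1"
    bins[n == 2] = "2"
    bins[n > 2] = ">2"
    out["site_count_bin"] = bins
    return out


def intersect_targets(set_a, set_b, decimals: int = 1) -> tuple[list[str], float]:
    """Intersection of two target-gene sets and the percent of A found in B.

    Returns ``(sorted common ids, percent)`` with the percent rounded to
    ``decimals`` places; an empty A gives NaN.
    """
    a, b = set(set_a), set(set_b)
    common = sorted(a & b)
    if not a:
        return common, math.nan
    return common, round(100.0 * len(common) / len(a), decimals)


def site_distance_distribution(
    peaks_a: pd.DataFrame,
    peaks_b: pd.DataFrame,
    genes: list[str] | None = None,
) -> pd.Series:
    """Per-gene minimal midpoint distance (nt) between two peak sets.

    Peak midpoint = floor((start + end) / 2); the per-gene distance is the
    minimum of ``|midpoint_a - midpoint_b|`` over all peak pairs.  Genes
    missing from either set are skipped.
    """
    _check_peaks(peaks_a, "A")
    _check_peaks(peaks_b, "B")
    mids_a = peaks_a.assign(mid=(peaks_a["start"] + peaks_a["end"]) // 2).groupby("gene_id")["mid"]
    mids_b = peaks_b.assign(mid=(peaks_b["start"] + peaks_b["end"]) // 2).groupby("gene_id")["mid"]
    a_map = {g: v.to_numpy() for g, v in mids_a}
    b_map = {g: v.to_numpy() for g, v in mids_b}
    common = sorted(set(a_map) & set(b_map))
    if genes is not None:
        common = [g for g in common if g in set(genes)]
    out = {g: int(np.min(np.abs(a_map[g][:, None] - b_map[g][None, :]))) for g in common}
    return pd.Series(out, name="min_distance", dtype="int64" if out else "float64")


def filter_pab_targets(
    table: pd.DataFrame,
    min_enrichment: float = 1.0,
    alpha: float = 0.05,
    min_fpkm: float = 1.0,
) -> pd.DataFrame:
    """Apply the PAB target thresholds: IP/input >= 1, p < 0.05, FPKM > 1
    (comparisons as printed: inclusive, strict, strict)."""
    required = ["ip_over_input", "p_value", "fpkm"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise InputError(f"PAB table missing column(s) {missing}")
    keep = (
        (table["ip_over_input"] >= min_enrichment)
        & (table["p_value"] < alpha)
        & (table["fpkm"] > min_fpkm)
    )
    return table[keep]
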