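"""Poly(A)-cluster construction and alternative-polyadenylation shift tests.

Cleavage microheterogeneity produces clusters of related poly(A) sites, so
individual 3'-end sites are merged into poly(A) clusters (PACs): any two
sites within 25 nt of one another (single linkage, per chrom and strand)
join one PAC.  PACs are quantified as tags-per-million, filtered at
TPM >= 3, assigned to genes, and genes with >= 2 PACs are tested for
proximal<->distal usage shifts between two conditions with a two-sided
Fisher's exact test on pooled tag counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation import GeneModel, GeneModelSet
from .normalization import compute_tpm

FEATURE_UTR3 = "3'UTR"
FEATURE_TERMINAL_EXON = "terminal exon"
FEATURE_CDS = "CDS"
FEATURE_INTERGENIC = "intergenic"


@dataclass
class PAC:
    """A poly(A) cluster: merged 3'-end sites with per-sample tag counts.

    ``start``/``end`` span the member sites (0-based half-open);
    ``representative_position`` is the member site with the highest pooled
    tag count (5'-most on ties, in genomic order).
    """

    chrom: str
    strand: str
    start: int
    end: int
    representative_position: int
    counts: pd.Series
    tpm: pd.Series | None = None
    gene_id: str | None = None
    feature: str = FEATURE_INTERGENIC
    ambiguous: bool = False
    member_positions: list[int] = field(default_factory=list)

    def pooled_count(self) -> float:
        return float(self.counts.sum())


def cluster_sites(sites: pd.DataFrame, gap: int = 25) -> list[PAC]:
    """Single-linkage merge of poly(A) sites into PACs.

    Sites on the same chrom and strand whose consecutive positional
    distance is <= ``gap`` nt (inclusive) join one cluster; clustering runs
    on sites pooled across all sample columns.
    """
    value_cols = [c for c in sites.columns if c not in ("chrom", "position", "strand")]
    if (sites["position"] < 0).any():
        raise ValueError("poly(A)-site positions must be >= 0")
    pacs: list[PAC] = []
    ordered = sites.sort_values(["chrom", "strand", "position"], kind="stable")
    for (chrom, strand), grp in ordered.groupby(["chrom", "strand"], sort=True):
        pos = grp["position"].to_numpy()
        counts = grp[value_cols].to_numpy(dtype=float)
        breaks = np.nonzero(np.diff(pos) > gap)[0] + 1
        for block in np.split(np.arange(len(pos)), breaks):
            bpos = pos[block]
            bcounts = counts[block]
            pooled = bcounts.sum(axis=1)
            rep = int(bpos[int(np.argmax(pooled))])  # argmax takes first on ties
            pacs.append(
                PAC(
                    chrom=chrom,
                    strand=strand,
                    start=int(bpos.min()),
                    end=int(bpos.max()) + 1,
                    representative_position=rep,
                    counts=pd.Series(bcounts.sum(axis=0), index=value_cols),
                    member_positions=[int(p) for p in bpos],
                )
            )
    return pacs


def attach_tpm(pacs: list[PAC]) -> list[PAC]:
    """Compute per-sample TPM over the PAC set and attach it in place."""
    if not pacs:
        return pacs
    counts = pd.DataFrame([p.counts for p in pacs]).reset_index(drop=True)
    tpm = compute_tpm(counts)
    for p, (_, row) in zip(pacs, tpm.iterrows()):
        p.tpm = row
    return pacs


def filter_pacs(pacs: list[PAC], min_tpm: float = 3.0, all_samples: bool = False) -> list[PAC]:
    """High-confidence PACs: TPM >= ``min_tpm`` in at least one sample
    (or in every sample with ``all_samples=True``).  Comparison is >=."""
    out = []
    for p in pacs:
        if p.tpm is None:
            raise ValueError("attach_tpm must run before filter_pacs")
        ok = (p.tpm >= min_tpm).all() if all_samples else (p.tpm >= min_tpm).any()
        if ok:
            out.append(p)
    return out


def assign_features(pacs: list[PAC], annotation: GeneModelSet, extension: int = 500) -> list[PAC]:
    """Assign each PAC to a gene and genomic feature.

    A PAC belongs to the gene whose strand matches and whose span, extended
    ``extension`` nt past the 3' end, contains the representative position.
    If two genes qualify the one with the nearest stop codon wins; exact
    ties are flagged ambiguous.  Feature precedence: annotated 3'UTR >
    downstream extension (also labelled 3'UTR) > CDS > rest of the terminal
    exon; no gene -> intergenic.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in annotation:
        lo = g.start - (extension if g.strand == "-" else 0)
        hi = g.end + (extension if g.strand == "+" else 0)
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(lo, hi, g.gene_id)
    for p in pacs:
        tree = trees.get((p.chrom, p.strand))
        hits = sorted(iv.data for iv in tree[p.representative_position]) if tree else []
        if not hits:
            p.gene_id, p.feature = None, FEATURE_INTERGENIC
            continue
        if len(hits) > 1:
            dists = {gid: abs(annotation[gid].utr3_distance(p.representative_position)) for gid in hits}
            best = min(dists.values())
            winners = [gid for gid, d in dists.items() if d == best]
            p.ambiguous = len(winners) > 1
            gene = annotation[winners[0]]
        else:
            gene = annotation[hits[0]]
        p.gene_id = gene.gene_id
        pos = p.representative_position
        if gene.in_utr3(pos) or not (gene.start <= pos < gene.end):
            p.feature = FEATURE_UTR3  # annotated 3'UTR or downstream extension
        elif gene.cds_start <= pos < gene.cds_end:
            p.feature = FEATURE_CDS
        else:
            p.feature = FEATURE_TERMINAL_EXON
    return pacs


# ---------------------------------------------------------------------------
# Fisher's exact test

def _hypergeom_pmf(k: np.ndarray, n: int, r1: int, c1: int) -> np.ndarray:
    """Vectorized hypergeometric pmf via log-gamma (sequencing-scale tables
    make per-element exact evaluation prohibitively slow)."""
    from scipy.special import gammaln

    def log_comb(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    logpmf = log_comb(r1, k) + log_comb(n - r1, c1 - k) - log_comb(n, c1)
    return np.exp(logpmf)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test for a 2x2 table of counts.

    The p-value sums hypergeometric probabilities, over all tables with the
    observed margins, of outcomes no more probable than the observed one.
    Returns ``(odds_ratio, p)``; with any zero margin the table carries no
    information, so p = 1 and the odds ratio is NaN.
    """
    (a, b), (c, d) = np.asarray(table, dtype=np.int64)
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative integers")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if 0 in (r1, r2, c1, c2):
        return math.nan, 1.0
    support = np.arange(max(0, r1 - c2), min(r1, c1) + 1)
    pmf = _hypergeom_pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return odds, min(p, 1.0)


def display_odds_ratio(table) -> float:
    """Haldane-Anscombe continuity-corrected odds ratio (display only)."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


# ---------------------------------------------------------------------------
# PAC-shift testing

@dataclass
class ShiftResult:
    gene_id: str
    counts_a: tuple[int, int]  # (5' half, 3' half) pooled tags, condition A
    counts_b: tuple[int, int]
    odds_ratio: float
    p_value: float
    shifted: bool
    direction: str | None  # "distal" | "proximal"
    skipped: str | None = None  # "single-PAC" | "zero-half"


def _halves(pacs: list[PAC], strand: str) -> tuple[np.ndarray, float]:
    """Boolean mask of PACs in the 5' (proximal) half, transcript-oriented.

    The midpoint is the mean representative position of the 5'-most and
    3'-most PACs; a PAC exactly at the midpoint counts as 5'."""
    rep = np.array([p.representative_position for p in pacs], dtype=float)
    midpoint = (rep.min() + rep.max()) / 2.0
    proximal = rep <= midpoint if strand == "+" else rep >= midpoint
    return proximal, midpoint


def pac_shift_test(
    gene_id: str,
    pacs: list[PAC],
    samples_a: list[str],
    samples_b: list[str],
    alpha: float = 0.05,
    fisher_on_rounded_tpm: bool = False,
) -> ShiftResult:
    """Fisher's exact test for proximal<->distal PAC usage change.

    Pools raw tag counts (or rounded TPM behind the flag) of the PACs in the
    transcript 5' half versus the 3' half, per condition, into a 2x2 table.
    Genes need >= 2 high-confidence PACs and pooled TPM > 0 in both halves
    in both conditions; otherwise the gene is skipped with a reason.
    """
    if len(pacs) < 2:
        return ShiftResult(gene_id, (0, 0), (0, 0), math.nan, math.nan, False, None, "single-PAC")
    strand = pacs[0].strand
    proximal, _ = _halves(pacs, strand)

    def _pool(values: pd.Series, samples: list[str]) -> float:
        return float(values[samples].sum())

    tpm_a = np.array([_pool(p.tpm, samples_a) for p in pacs])
    tpm_b = np.array([_pool(p.tpm, samples_b) for p in pacs])
    for tpm in (tpm_a, tpm_b):
        if tpm[proximal].sum() <= 0 or tpm[~proximal].sum() <= 0:
            return ShiftResult(gene_id, (0, 0), (0, 0), math.nan, math.nan, False, None, "zero-half")

    source_a = tpm_a if fisher_on_rounded_tpm else np.array([_pool(p.counts, samples_a) for p in pacs])
    source_b = tpm_b if fisher_on_rounded_tpm else np.array([_pool(p.counts, samples_b) for p in pacs])
    a_prox = int(round(source_a[proximal].sum()))
    a_dist = int(round(source_a[~proximal].sum()))
    b_prox = int(round(source_b[proximal].sum()))
    b_dist = int(round(source_b[~proximal].sum()))
    odds, p = fisher_exact_2x2([[a_prox, a_dist], [b_prox, b_dist]])

    dist_share_a = a_dist / max(a_prox + a_dist, 1)
    dist_share_b = b_dist / max(b_prox + b_dist, 1)
    direction = "distal" if dist_share_b > dist_share_a else "proximal"
    return ShiftResult(
        gene_id,
        (a_prox, a_dist),
        (b_prox, b_dist),
        odds,
        p,
        bool(p < alpha),
        direction,
    )


def shift_table(results: list[ShiftResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "a_proximal": [r.counts_a[0] for r in results],
            "a_distal": [r.counts_a[1] for r in results],
            "b_proximal": [r.counts_b[0] for r in results],
            "b_distal": [r.counts_b[1] for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "shifted": [r.shifted for r in results],
            "direction": [r.direction for r in results],
            "skipped": [r.skipped for r in results],
        }
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# weighted 3'UTR length

def weighted_utr_length(distances, weights) -> float:
    """TPM-weighted mean distance from PAC to stop codon (nt).

    ``L = sum(d_i * w_i) / sum(w_i)``; NaN if the weights sum to zero.
    """
    d = np.asarray(distances, dtype=float)
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        return math.nan
    return float((d * w).sum() / total)


def gene_weighted_utr_length(gene: GeneModel, pacs: list[PAC], samples: list[str]) -> float:
    """Weighted 3'UTR length for one gene in one condition's samples."""
    distances = [gene.utr3_distance(p.representative_position) for p in pacs]
    weights = [float(p.tpm[samples].sum()) for p in pacs]
    return weighted_utr_length(distances, weights)


def compare_utr_lengths(
    lengths_a: pd.Series,
    lengths_b: pd.Series,
    groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Paired-by-gene two-sided t test of 3'UTR length between conditions,
    per gene group; groups with < 2 usable genes are skipped."""
    rows = []
    for label, genes in groups.items():
        idx = pd.Index(genes)
        common = idx.intersection(lengths_a.dropna().index).intersection(lengths_b.dropna().index)
        if len(common) < 2:
            rows.append({"group": label, "n": len(common), "mean_diff": math.nan,
                         "t": math.nan, "p_value": math.nan, "skipped": True})
            continue
        diff = lengths_b[common] - lengths_a[common]
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(lengths_b[common], lengths_a[common])
        rows.append({"group": label, "n": len(common), "mean_diff": float(diff.mean()),
                     "t": float(t), "p_value": float(p), "skipped": False})
    return pd.DataFrame(rows).set_index("group")
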