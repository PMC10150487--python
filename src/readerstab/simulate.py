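"""Synthetic-data generators with machine-readable truth.

Each generator is a pure function of ``(config, seed)`` and emulates one
post-alignment product of the study design: per-gene count matrices from an
actinomycin-D decay time course with ERCC-style spike-ins, clustered
poly(A)-site 3'-end tag tables with programmed proximal/distal usage swaps,
gene-anchored CLIP/m6A peak sets with configurable pairwise overlap, and a
paired ribo/RNA FPKM table with known translation efficiency.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .annotation import GeneModel, GeneModelSet
from .config import ConfigurationError, SimulationConfig

_LN2 = math.log(2.0)

# stable sub-stream ids so adding a generator never reshuffles another's draws
_STREAM = {"annotation": 0, "decay": 1, "polya": 2, "peaks": 3, "expression": 4, "scale": 5}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], config.seed])


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


@dataclass
class TruthRecord:
    """Ground truth for one simulated dataset, keyed by emitted gene IDs."""

    halflife_wt: dict[str, float] = field(default_factory=dict)
    halflife_mut: dict[str, float] = field(default_factory=dict)
    destabilized: dict[str, bool] = field(default_factory=dict)
    n_pacs: dict[str, int] = field(default_factory=dict)
    shifted: dict[str, bool] = field(default_factory=dict)
    target_label: dict[str, str] = field(default_factory=dict)
    ect2_sites: dict[str, int] = field(default_factory=dict)
    has_m6a: dict[str, bool] = field(default_factory=dict)
    pab2: dict[str, bool] = field(default_factory=dict)
    pab4: dict[str, bool] = field(default_factory=dict)
    te: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))

    def update(self, other: "TruthRecord") -> "TruthRecord":
        for f in dataclasses.fields(self):
            getattr(self, f.name).update(getattr(other, f.name))
        return self


# ---------------------------------------------------------------------------
# annotation

def make_annotation(config: SimulationConfig) -> GeneModelSet:
    """Lay out non-overlapping stranded genes on one synthetic chromosome.

    Each gene is single-exon with a 5'UTR, a CDS (length a multiple of 3)
    and a 3'UTR drawn from ``config.utr3_length``; neighbouring genes are
    separated by >= 1500 nt so downstream poly(A)-cluster assignment with
    the default 500-nt extension is unambiguous.
    """
    if config.n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    rng = _rng(config, "annotation")
    genes = []
    cursor = 1000
    for i in range(config.n_genes):
        utr5 = int(rng.integers(50, 201))
        cds = int(rng.integers(100, 601)) * 3
        utr3 = int(rng.integers(config.utr3_length[0], config.utr3_length[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        length = utr5 + cds + utr3
        start = cursor
        end = start + length
        if strand == "+":
            cds_start, cds_end = start + utr5, start + utr5 + cds
            u3s, u3e = cds_end, end
        else:
            u3s, u3e = start, start + utr3
            cds_start, cds_end = u3e, u3e + cds
        genes.append(
            GeneModel(
                gene_id=f"SYNG{i + 1:05d}",
                chrom="chrS",
                start=start,
                end=end,
                strand=strand,
                cds_start=cds_start,
                cds_end=cds_end,
                utr3_start=u3s,
                utr3_end=u3e,
            )
        )
        cursor = end + int(rng.integers(1500, 2501))
    return GeneModelSet(genes, chrom_sizes={"chrS": cursor + 1000})


# ---------------------------------------------------------------------------
# decay time course

class DecaySimulation(NamedTuple):
    counts: pd.DataFrame      # genes x samples, integer counts
    spikeins: pd.DataFrame    # spikein_id, known_amount, one column per sample
    design: pd.DataFrame      # sample, genotype, time, replicate
    scale_factors: pd.Series  # true per-sample library distortions
    truth: TruthRecord


def simulate_decay_counts(
    config: SimulationConfig,
    annotation: GeneModelSet,
    destabilized_genes: set[str] | None = None,
) -> DecaySimulation:
    """Simulate the transcription shut-off count matrix plus spike-ins.

    Per gene g and sample s the expected count is
    ``depth * w_g * exp(-ln2 * t_s / t_half_g(genotype)) * scale_s`` with
    ``w_g`` a length-scaled log-normal abundance weight normalised at t=0,
    and negative-binomial noise on top.  Spike-in expectations are
    ``known_amount * c * scale_s`` so total RNA decay does not distort the
    calibration.  Destabilized genes get mutant half-lives shortened by
    ``config.destabilize_factor``; pass ``destabilized_genes`` to pin the
    destabilized set (e.g. to a simulated target class).
    """
    if config.depth_per_sample <= 0:
        raise ConfigurationError("depth_per_sample must be positive")
    rng = _rng(config, "decay")
    gene_ids = annotation.gene_ids
    n = len(gene_ids)

    lo, hi = config.halflife_range
    t_half_wt = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    if destabilized_genes is None:
        destab = rng.random(n) < config.frac_destabilized
    else:
        destab = np.array([g in destabilized_genes for g in gene_ids])
    t_half_mut = np.where(destab, t_half_wt * config.destabilize_factor, t_half_wt)

    lengths_kb = annotation.gene_lengths().loc[gene_ids].to_numpy() / 1e3
    weight = np.exp(rng.normal(0.0, 1.0, size=n)) * lengths_kb
    weight /= weight.sum()

    samples = config.sample_names
    design = pd.DataFrame(
        [
            {"sample": s, "genotype": s.split("_")[0],
             "time": float(s.split("_")[1][1:]), "replicate": int(s.split("_")[2][1:])}
            for s in samples
        ]
    ).set_index("sample")

    if config.sample_scale_factors is not None:
        scale = pd.Series({s: float(config.sample_scale_factors[s]) for s in samples})
    else:
        scale_rng = _rng(config, "scale")
        scale = pd.Series(np.exp(scale_rng.normal(0.0, 0.25, size=len(samples))), index=samples)

    t_half = {"WT": t_half_wt, "mut": t_half_mut}
    counts = {}
    for s in samples:
        geno, t = design.loc[s, "genotype"], design.loc[s, "time"]
        mu = config.depth_per_sample * weight * np.exp(-_LN2 * t / t_half[geno]) * scale[s]
        counts[s] = _nb_sample(rng, mu, config.dispersion)
    counts_df = pd.DataFrame(counts, index=gene_ids)

    amounts = np.array(sorted(set(config.spikein_amounts)), dtype=float)
    spike_ids = [f"SPIKE{i + 1:03d}" for i in range(len(amounts))]
    spike_per_amount = 0.03 * config.depth_per_sample / amounts.sum()
    spikes = {"known_amount": amounts}
    for s in samples:
        spikes[s] = _nb_sample(rng, amounts * spike_per_amount * scale[s], config.spikein_dispersion)
    spike_df = pd.DataFrame(spikes, index=pd.Index(spike_ids, name="spikein_id"))

    truth = TruthRecord(
        halflife_wt=dict(zip(gene_ids, t_half_wt.tolist())),
        halflife_mut=dict(zip(gene_ids, t_half_mut.tolist())),
        destabilized=dict(zip(gene_ids, (destab & (config.destabilize_factor < 1)).tolist())),
    )
    return DecaySimulation(counts_df, spike_df, design, scale, truth)


# ---------------------------------------------------------------------------
# poly(A)-site tags

class PolyASimulation(NamedTuple):
    sites: pd.DataFrame   # chrom, position, strand + per-sample tag counts
    truth: TruthRecord


def simulate_polya_tags(config: SimulationConfig, annotation: GeneModelSet) -> PolyASimulation:
    """Simulate per-site 3'-end tag counts for two conditions (WT, mut).

    Multi-cluster genes carry two true poly(A) clusters >= 40 nt apart in
    the 3'UTR (so the 25-nt merge rule cannot fuse them), each cluster's
    member sites scattered within +-10 nt of its centre.  Shifted genes swap
    proximal/distal usage between conditions per ``config.usage_shift``; a
    ``polya_background_frac`` share of each gene's tags falls at an internal
    CDS position to mimic off-3'UTR background.

    Noise model: the per-sample gene total is negative-binomial
    (library-level biological overdispersion); given the total, tags are
    allocated to sites multinomially with the usage fractions as
    probabilities.  Overdispersing the within-gene split instead would not
    represent poly(A)-site choice, which is conditional on the transcript
    being sequenced at all.
    """
    rng = _rng(config, "polya")
    n_rep = config.n_replicates
    samples = [f"{c}_r{r}" for c in ("WT", "mut") for r in range(1, n_rep + 1)]
    truth = TruthRecord()

    gene_ids = annotation.gene_ids
    share = np.exp(rng.normal(0.0, 1.0, size=len(gene_ids)))
    share /= share.sum()
    rows: list[dict] = []

    for gid, gshare in zip(gene_ids, share):
        gene = annotation[gid]
        utr_len = gene.utr3_end - gene.utr3_start
        multi = rng.random() < config.frac_multi_pac
        shifted = bool(multi and rng.random() < config.frac_shifted_genes)
        truth.n_pacs[gid] = 2 if multi else 1
        truth.shifted[gid] = shifted

        # cluster centres as distances from the stop codon, >= 40 nt apart
        if multi:
            d_prox = int(0.25 * utr_len)
            d_dist = int(0.85 * utr_len)
            if shifted:
                prox_frac = {"WT": config.usage_shift[0], "mut": config.usage_shift[1]}
            else:
                f = float(rng.uniform(0.35, 0.65))
                prox_frac = {"WT": f, "mut": f}
            clusters = [(d_prox, prox_frac), (d_dist, {c: 1 - v for c, v in prox_frac.items()})]
        else:
            clusters = [(int(0.6 * utr_len), {"WT": 1.0, "mut": 1.0})]

        gene_mu = config.polya_depth_per_sample * gshare / n_rep
        sign = 1 if gene.strand == "+" else -1

        # site layout and per-condition allocation probabilities
        positions: list[int] = []
        probs: dict[str, list[float]] = {"WT": [], "mut": []}
        for d_center, usage in clusters:
            k_sites = int(rng.integers(3, 8))
            offsets = rng.choice(np.arange(-10, 11), size=k_sites, replace=False)
            w = rng.dirichlet(np.ones(k_sites))
            for off, sw in zip(offsets, w):
                positions.append(gene.stop_codon + sign * (d_center + int(off)))
                for cond in ("WT", "mut"):
                    probs[cond].append((1 - config.polya_background_frac) * usage[cond] * sw)
        if config.polya_background_frac > 0:
            positions.append((gene.cds_start + gene.cds_end) // 2)
            for cond in ("WT", "mut"):
                probs[cond].append(config.polya_background_frac)

        gene_rows = [
            {"chrom": gene.chrom, "position": pos, "strand": gene.strand}
            for pos in positions
        ]
        for cond in ("WT", "mut"):
            p = np.asarray(probs[cond])
            p = p / p.sum()
            for r in range(1, n_rep + 1):
                total = int(_nb_sample(rng, np.array([gene_mu]), config.dispersion)[0])
                alloc = rng.multinomial(total, p)
                for row, c in zip(gene_rows, alloc):
                    row[f"{cond}_r{r}"] = int(c)
        rows.extend(gene_rows)

    sites = pd.DataFrame(rows, columns=["chrom", "position", "strand"] + samples)
    sites = sites.sort_values(["chrom", "strand", "position"], kind="stable").reset_index(drop=True)
    if (sites["position"] < 0).any():
        raise ConfigurationError("negative poly(A)-site position generated")
    return PolyASimulation(sites, truth)


# ---------------------------------------------------------------------------
# peaks

class PeakSimulation(NamedTuple):
    peaks: dict[str, pd.DataFrame]  # name -> BED6-style frame with gene_id
    truth: TruthRecord


_SITE_COUNT_P = (0.4, 0.3, 0.2, 0.1)  # P(1..4 binding sites | target)


def simulate_peaks(config: SimulationConfig, annotation: GeneModelSet) -> PeakSimulation:
    """Simulate ECT2 / m6A / PAB2 / PAB4 peak sets in gene 3'UTRs.

    Per-gene membership follows the configured conditional probabilities
    (m6A, PAB2 and PAB4 drawn given ECT2-target status); co-occurring peaks
    are co-located so that an m6A peak always overlaps its gene's first
    ECT2 peak by construction.  Non-ECT2 genes may carry an m6A-only peak
    with probability ``frac_m6a_background``.
    """
    rng = _rng(config, "peaks")
    width = config.peak_width
    half = width // 2
    peaks: dict[str, list[dict]] = {"ECT2": [], "m6A": [], "PAB2": [], "PAB4": []}
    truth = TruthRecord()

    def _emit(name: str, gene: GeneModel, center: int) -> None:
        lo = max(gene.start, center - half)
        hi = min(gene.end, center + half)
        peaks[name].append(
            {
                "chrom": gene.chrom,
                "start": lo,
                "end": hi,
                "name": f"{name}_{gene.gene_id}_{len(peaks[name]) + 1}",
                "score": int(rng.integers(10, 1000)),
                "strand": gene.strand,
                "gene_id": gene.gene_id,
            }
        )

    for gid in annotation.gene_ids:
        gene = annotation[gid]
        u3s, u3e = gene.utr3_start, gene.utr3_end
        span = u3e - u3s
        is_ect2 = rng.random() < config.frac_ect2_targets
        has_m6a = False
        has_pab2 = False
        has_pab4 = False
        n_sites = 0
        if is_ect2:
            n_sites = int(rng.choice([1, 2, 3, 4], p=_SITE_COUNT_P))
            # spread site centres across the 3'UTR
            centers = sorted(
                u3s + half + int(x * max(span - width, 1))
                for x in rng.uniform(0, 1, size=n_sites)
            )
            for c in centers:
                _emit("ECT2", gene, c)
            has_m6a = rng.random() < config.frac_m6a_given_ect2
            if has_m6a:
                _emit("m6A", gene, centers[0] + int(rng.integers(-10, 11)))
            has_pab2 = rng.random() < config.frac_pab2_given_ect2
            if has_pab2:
                _emit("PAB2", gene, int(centers[rng.integers(len(centers))]) + int(rng.integers(-15, 16)))
            has_pab4 = rng.random() < config.frac_pab4_given_ect2
            if has_pab4:
                _emit("PAB4", gene, int(centers[rng.integers(len(centers))]) + int(rng.integers(-15, 16)))
        else:
            has_m6a = rng.random() < config.frac_m6a_background
            if has_m6a:
                _emit("m6A", gene, u3s + half + int(rng.uniform() * max(span - width, 1)))

        if is_ect2 and has_m6a:
            label = "ECT2 & m6A target"
        elif is_ect2:
            label = "ECT2 target"
        elif has_m6a:
            label = "excluded"
        else:
            label = "Non-target"
        truth.target_label[gid] = label
        truth.ect2_sites[gid] = n_sites
        truth.has_m6a[gid] = bool(has_m6a)
        truth.pab2[gid] = bool(has_pab2)
        truth.pab4[gid] = bool(has_pab4)

    cols = ["chrom", "start", "end", "name", "score", "strand", "gene_id"]
    frames = {
        name: pd.DataFrame(rows, columns=cols).sort_values(["chrom", "start"]).reset_index(drop=True)
        for name, rows in peaks.items()
    }
    return PeakSimulation(frames, truth)


# ---------------------------------------------------------------------------
# ribo / RNA expression pair

class ExpressionSimulation(NamedTuple):
    ribo: pd.DataFrame  # gene_id index, FPKM column
    rna: pd.DataFrame
    truth: TruthRecord


def simulate_expression_pair(config: SimulationConfig, annotation: GeneModelSet) -> ExpressionSimulation:
    """Paired ribo-seq / mRNA-seq FPKM tables with known TE.

    ``ribo = TE_true * rna * lognormal(0, te_noise_sigma)`` with
    ``TE_true ~ lognormal(0, te_sigma)`` independent of target status.
    """
    rng = _rng(config, "expression")
    gene_ids = annotation.gene_ids
    n = len(gene_ids)
    rna = np.exp(rng.normal(2.0, 1.2, size=n))
    te_true = np.exp(rng.normal(0.0, config.te_sigma, size=n))
    noise = np.exp(rng.normal(0.0, config.te_noise_sigma, size=n)) if config.te_noise_sigma > 0 else 1.0
    ribo = te_true * rna * noise
    idx = pd.Index(gene_ids, name="gene_id")
    truth = TruthRecord(te=dict(zip(gene_ids, te_true.tolist())))
    return ExpressionSimulation(
        pd.DataFrame({"FPKM": ribo}, index=idx),
        pd.DataFrame({"FPKM": rna}, index=idx),
        truth,
    )
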