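"""Configuration objects for simulation and pipeline runs.

All analysis thresholds live in :class:`PipelineConfig` so that the printed
defaults (TPM >= 3, RPKM > 1, alpha = 0.05, 25-nt cluster gap, ...) are
configuration, never literals buried in code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass
class SimulationConfig:
    """Study design for the synthetic-data generator.

    The defaults emulate the sequencing experiments the package analyses:
    an actinomycin-D transcription shut-off time course sampled at 0, 4 and
    6 h in two genotypes with two replicates and ERCC-style spike-ins; 3'-end
    tag libraries of ~1e7 tags per sample with clustered poly(A) sites and a
    programmed proximal<->distal usage swap in a subset of multi-cluster
    genes; CLIP/m6A-style peak sets with configurable conditional overlap;
    and a paired ribo/RNA FPKM table with a known translation efficiency.

    Parameters
    ----------
    n_genes : number of genes on the synthetic chromosome.
    seed : master seed; every generator is a pure function of (config, seed).
    timepoints : hours after transcription shut-off; must start at 0 and
        strictly increase.
    n_replicates : biological replicates per genotype x timepoint.
    halflife_range : (low, high) hours; true half-lives are log-uniform.
    depth_per_sample : expected total mRNA-seq read count per sample.
    dispersion : negative-binomial overdispersion (var = mu + disp * mu^2);
        0 means Poisson.
    spikein_amounts : known spike-in quantities (attomoles), spanning at
        least two orders of magnitude; the default is an ERCC-like
        24-point geometric series over four orders.
    spikein_dispersion : negative-binomial overdispersion for spike-in
        counts.  Spike-ins are synthetic RNAs added to the extract, so they
        carry technical noise only — far below the biological gene-level
        dispersion.
    sample_scale_factors : per-sample multiplicative library distortions;
        None draws log-normal factors from the seed.
    frac_destabilized : fraction of genes whose mutant half-life is
        shortened by ``destabilize_factor``.
    destabilize_factor : mutant/WT half-life ratio for destabilized genes.
    polya_depth_per_sample : expected 3'-end tags per sample.
    frac_multi_pac : fraction of genes carrying two true poly(A) clusters.
    frac_shifted_genes : fraction of multi-cluster genes with a programmed
        proximal<->distal usage swap between conditions.
    usage_shift : (proximal fraction in WT, proximal fraction in mutant)
        for shifted genes.
    polya_background_frac : fraction of a gene's tags placed outside the
        3'UTR (internal/CDS background).
    frac_ect2_targets, frac_m6a_given_ect2, frac_pab2_given_ect2,
    frac_pab4_given_ect2 : peak-overlap design probabilities.
    frac_m6a_background : probability that a non-ECT2 gene carries an m6A
        peak (these genes belong to no target class).
    peak_width : CLIP/m6A peak width in nt.
    utr3_length : (low, high) nt for annotated 3'UTR lengths.
    te_sigma : s.d. of log true translation efficiency.
    te_noise_sigma : s.d. of multiplicative log-normal noise linking ribo
        FPKM to TE x RNA FPKM.
    """

    n_genes: int = 500
    seed: int = 0
    timepoints: tuple[float, ...] = (0.0, 4.0, 6.0)
    n_replicates: int = 2
    halflife_range: tuple[float, float] = (1.0, 10.0)
    depth_per_sample: float = 5e6
    dispersion: float = 0.05
    spikein_amounts: tuple[float, ...] = tuple(
        round(0.1 * 10 ** (4 * k / 23), 4) for k in range(24)
    )
    spikein_dispersion: float = 0.005
    sample_scale_factors: dict[str, float] | None = None
    frac_destabilized: float = 0.3
    destabilize_factor: float = 0.5
    polya_depth_per_sample: float = 1e7
    frac_multi_pac: float = 0.6
    frac_shifted_genes: float = 0.3
    usage_shift: tuple[float, float] = (0.7, 0.3)
    polya_background_frac: float = 0.1
    frac_ect2_targets: float = 0.3
    frac_m6a_given_ect2: float = 0.7
    frac_pab2_given_ect2: float = 0.6
    frac_pab4_given_ect2: float = 0.55
    frac_m6a_background: float = 0.05
    peak_width: int = 40
    utr3_length: tuple[int, int] = (150, 400)
    te_sigma: float = 0.5
    te_noise_sigma: float = 0.15

    def __post_init__(self) -> None:
        _check(self.n_genes >= 1, "n_genes must be a positive integer")
        _check(self.n_replicates >= 2, "n_replicates must be >= 2")
        tp = tuple(float(t) for t in self.timepoints)
        _check(len(tp) >= 2 and tp[0] == 0.0, "timepoints must start at 0")
        _check(all(b > a for a, b in zip(tp, tp[1:])), "timepoints must strictly increase")
        self.timepoints = tp
        lo, hi = self.halflife_range
        _check(lo > 0 and hi >= lo, "halflife_range low must be > 0 and <= high")
        _check(self.depth_per_sample > 0, "depth_per_sample must be positive")
        _check(self.polya_depth_per_sample > 0, "polya_depth_per_sample must be positive")
        _check(self.dispersion >= 0, "dispersion must be >= 0")
        _check(self.spikein_dispersion >= 0, "spikein_dispersion must be >= 0")
        amounts = sorted(set(float(a) for a in self.spikein_amounts))
        _check(len(amounts) >= 3, "need >= 3 distinct spike-in amounts")
        _check(amounts[-1] / amounts[0] >= 100, "spike-in amounts must span >= 2 orders of magnitude")
        for name in (
            "frac_destabilized",
            "frac_multi_pac",
            "frac_shifted_genes",
            "polya_background_frac",
            "frac_ect2_targets",
            "frac_m6a_given_ect2",
            "frac_pab2_given_ect2",
            "frac_pab4_given_ect2",
            "frac_m6a_background",
        ):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must lie in [0, 1]")
        _check(
            all(0.0 <= u <= 1.0 for u in self.usage_shift),
            "usage_shift fractions must lie in [0, 1]",
        )
        _check(0 < self.destabilize_factor <= 1.0, "destabilize_factor must lie in (0, 1]")
        _check(self.utr3_length[0] >= 120, "3'UTRs shorter than 120 nt cannot hold two clusters 40 nt apart")

    @property
    def sample_names(self) -> list[str]:
        """Decay-course sample names in genotype, time, replicate order."""
        return [
            f"{geno}_t{t:g}_r{r}"
            for geno in ("WT", "mut")
            for t in self.timepoints
            for r in range(1, self.n_replicates + 1)
        ]


#: Timepoint preset matching the RT-qPCR stability assay design.
QPCR_TIMEPOINTS: tuple[float, ...] = (0.0, 2.0, 4.0)


@dataclass
class PipelineConfig:
    """Thresholds, interpretation flags and the seed for a pipeline run."""

    seed: int = 0
    min_tpm: float = 3.0
    expressed_rpkm: float = 1.0
    shift_alpha: float = 0.05
    de_fc: float = 2.0
    de_alpha: float = 0.05
    cluster_gap: int = 25
    pab_enrichment: float = 1.0
    utr_extension: int = 500
    percent_decimals: int = 1
    # gap-ledger alternative behaviours
    fisher_on_rounded_tpm: bool = False
    tpm_filter_all_samples: bool = False
    replicate_mean_decay: bool = False
    loglog_spikein_fit: bool = False
    pac_location_midpoint: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        for name in ("min_tpm", "expressed_rpkm", "de_fc", "pab_enrichment"):
            _check(getattr(self, name) > 0, f"{name} must be positive")
        _check(self.cluster_gap > 0, "cluster_gap must be positive")
        for name in ("shift_alpha", "de_alpha"):
            _check(0 < getattr(self, name) < 1, f"{name} must lie in (0, 1)")

    def config_hash(self) -> str:
        """SHA-256 over the canonical JSON of all semantic fields."""
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def to_yaml(self, path: str) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
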