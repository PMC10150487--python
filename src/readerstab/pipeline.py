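"""End-to-end pipeline: simulate -> calibrate -> half-life / APA shift /
target classification -> group comparison, with provenance-stamped outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__, apa, compare, normalization, targets
from .annotation import GeneModelSet
from .config import PipelineConfig
from .decay import ExponentialDecayModel, halflife_table
from .simulate import (
    TruthRecord,
    make_annotation,
    simulate_decay_counts,
    simulate_expression_pair,
    simulate_peaks,
    simulate_polya_tags,
)

log = logging.getLogger("readerstab")


def provenance_header(config: PipelineConfig) -> str:
    return (
        f"# readerstab {__version__} | config {config.config_hash()}"
        f" | seed {config.seed}\n"
    )


def write_tsv(frame: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config))
        frame.to_csv(fh, sep="\t")


def compute_shift_results(
    pacs: list[apa.PAC],
    samples_a: list[str],
    samples_b: list[str],
    config: PipelineConfig,
) -> list[apa.ShiftResult]:
    """Run the PAC-shift test for every gene with assigned 3'-end PACs.

    Only PACs in the 3'UTR or terminal exon enter the proximal/distal
    analysis: an internal (CDS) PAC is not an alternative 3' end and would
    drag the midpoint out of the 3'UTR.
    """
    keep = (apa.FEATURE_UTR3, apa.FEATURE_TERMINAL_EXON)
    by_gene: dict[str, list[apa.PAC]] = {}
    for p in pacs:
        if p.gene_id is not None and p.feature in keep:
            by_gene.setdefault(p.gene_id, []).append(p)
    return [
        apa.pac_shift_test(
            gid,
            gene_pacs,
            samples_a,
            samples_b,
            alpha=config.shift_alpha,
            fisher_on_rounded_tpm=config.fisher_on_rounded_tpm,
        )
        for gid, gene_pacs in sorted(by_gene.items())
    ]


def build_pacs(
    sites: pd.DataFrame,
    annotation: GeneModelSet,
    config: PipelineConfig,
) -> list[apa.PAC]:
    """Cluster sites, quantify TPM, keep high-confidence PACs, assign genes."""
    pacs = apa.cluster_sites(sites, gap=config.cluster_gap)
    apa.attach_tpm(pacs)
    n_all = len(pacs)
    pacs = apa.filter_pacs(pacs, min_tpm=config.min_tpm, all_samples=config.tpm_filter_all_samples)
    log.info("PACs: %d clustered, %d high-confidence (TPM >= %g)", n_all, len(pacs), config.min_tpm)
    return apa.assign_features(pacs, annotation, extension=config.utr_extension)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full synthetic-study pipeline and write all artifacts.

    Returns a bundle with the truth record, the fitted half-life table, the
    shift table, the target assignments and the group-comparison tables.
    Identical config (including seed) gives byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    annotation = make_annotation(sim)
    annotation.write_gff3(str(outdir / "genes.gff3"))

    peaks, truth_peaks = simulate_peaks(sim, annotation)
    truth = TruthRecord().update(truth_peaks)
    destabilized = {g for g, lbl in truth_peaks.target_label.items() if lbl == "ECT2 & m6A target"}

    decay_sim = simulate_decay_counts(sim, annotation, destabilized_genes=destabilized)
    truth.update(decay_sim.truth)
    polya = simulate_polya_tags(sim, annotation)
    truth.update(polya.truth)
    expr = simulate_expression_pair(sim, annotation)
    truth.update(expr.truth)
    truth.to_json(str(outdir / "truth.json"))

    # --- half-life -------------------------------------------------------
    factors = normalization.fit_spikein_calibration(
        decay_sim.spikeins,
        method="loglog" if config.loglog_spikein_fit else "linear",
    )
    lengths = annotation.gene_lengths()
    norm = normalization.normalize_expression(decay_sim.counts, lengths, factors)
    t0 = {
        geno: [
            s for s in norm.columns
            if decay_sim.design.loc[s, "genotype"] == geno and decay_sim.design.loc[s, "time"] == 0
        ]
        for geno in ("WT", "mut")
    }
    expressed = normalization.expressed_filter(norm, config.expressed_rpkm, samples=t0["WT"])
    log.info("expressed filter: %d of %d genes retained", len(expressed), len(norm))
    results = {
        geno: ExponentialDecayModel.from_dataframe(
            norm.loc[expressed], decay_sim.design, genotype=geno
        ).fit(replicate_mean=config.replicate_mean_decay)
        for geno in ("WT", "mut")
    }
    hl = halflife_table(results["WT"], results["mut"], expressed=expressed)
    write_tsv(hl, outdir / "halflife.tsv", config)

    # --- APA -------------------------------------------------------------
    pacs = build_pacs(polya.sites, annotation, config)
    samples_a = [c for c in polya.sites.columns if c.startswith("WT_")]
    samples_b = [c for c in polya.sites.columns if c.startswith("mut_")]
    shift_results = compute_shift_results(pacs, samples_a, samples_b, config)
    shifts = apa.shift_table(shift_results)
    tested = shifts[shifts["skipped"].isna()]
    log.info(
        "PAC shift: %d genes tested, %d shifted (p < %g)",
        len(tested), int(tested["shifted"].sum()), config.shift_alpha,
    )
    write_tsv(shifts, outdir / "pac_shifts.tsv", config)

    utr = {}
    for cond, samples in (("WT", samples_a), ("mut", samples_b)):
        by_gene: dict[str, list[apa.PAC]] = {}
        for p in pacs:
            if p.gene_id is not None and p.feature == apa.FEATURE_UTR3:
                by_gene.setdefault(p.gene_id, []).append(p)
        utr[cond] = pd.Series(
            {
                gid: apa.gene_weighted_utr_length(annotation[gid], gp, samples)
                for gid, gp in by_gene.items()
            }
        )
    utr_frame = pd.DataFrame({"utr_WT": utr["WT"], "utr_mut": utr["mut"]})
    write_tsv(utr_frame, outdir / "utr_lengths.tsv", config)

    # --- targets ---------------------------------------------------------
    assignments = targets.classify_targets(
        annotation.gene_ids, peaks["ECT2"], peaks["m6A"], peaks["PAB2"], peaks["PAB4"]
    )
    assignments = targets.bin_by_site_count(assignments)
    write_tsv(assignments, outdir / "targets.tsv", config)

    # --- group comparisons ----------------------------------------------
    tested_groups = [targets.LABEL_ECT2, targets.LABEL_ECT2_M6A]
    hl_ok = hl.loc[hl["status"] == "ok", "log2fc_halflife"]
    group_hl = compare.mann_whitney_group_test(
        hl_ok, assignments["label"], reference=targets.LABEL_NON, groups=tested_groups
    )
    te = compare.translation_efficiency(expr.ribo, expr.rna, min_fpkm=config.expressed_rpkm)
    group_te = compare.mann_whitney_group_test(
        te["te"], assignments["label"], reference=targets.LABEL_NON, groups=tested_groups
    )
    write_tsv(group_hl, outdir / "groups_halflife.tsv", config)
    write_tsv(group_te, outdir / "groups_te.tsv", config)

    return {
        "annotation": annotation,
        "truth": truth,
        "norm": norm,
        "decay_results": results,
        "halflife": hl,
        "pacs": pacs,
        "shifts": shifts,
        "utr_lengths": utr_frame,
        "assignments": assignments,
        "te": te,
        "groups_halflife": group_hl,
        "groups_te": group_te,
    }
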