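"""Gene models and GFF3 input/output.

Internal coordinates are 0-based half-open (BED convention) on every type;
GFF3 is written and parsed 1-based closed, converted at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd
from gffutils.feature import Feature
from gffutils.iterators import DataIterator


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """A stranded, single-transcript gene model.

    ``start``/``end`` span the whole gene; ``cds_start``/``cds_end`` the
    coding sequence and ``utr3_start``/``utr3_end`` the annotated 3'UTR,
    all 0-based half-open genomic intervals.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_start: int
    cds_end: int
    utr3_start: int
    utr3_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise AnnotationError(f"{self.gene_id}: invalid gene span")

    @property
    def stop_codon(self) -> int:
        """0-based position of the 3'-most coding nucleotide (strand-aware).

        Distances from poly(A) sites to the stop codon are measured from
        this coordinate.
        """
        return self.cds_end - 1 if self.strand == "+" else self.cds_start

    def utr3_distance(self, position: int) -> int:
        """Strand-aware distance (nt) from ``position`` to the stop codon."""
        if self.strand == "+":
            return position - self.stop_codon
        return self.stop_codon - position

    def contains(self, position: int, extension: int = 0) -> bool:
        """Whether ``position`` lies in the gene span extended ``extension``
        nt past the 3' end (strand-aware)."""
        if self.strand == "+":
            return self.start <= position < self.end + extension
        return self.start - extension <= position < self.end

    def in_utr3(self, position: int) -> bool:
        return self.utr3_start <= position < self.utr3_end


class GeneModelSet:
    """Ordered collection of :class:`GeneModel`, indexed by gene_id."""

    def __init__(self, genes: Iterable[GeneModel], chrom_sizes: dict[str, int] | None = None):
        self.genes: dict[str, GeneModel] = {g.gene_id: g for g in genes}
        self.chrom_sizes = chrom_sizes or {}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "cds_start": g.cds_start,
                "cds_end": g.cds_end,
                "utr3_start": g.utr3_start,
                "utr3_end": g.utr3_end,
            }
            for g in self
        ]
        return pd.DataFrame(rows).set_index("gene_id")

    def gene_lengths(self) -> pd.Series:
        return pd.Series({g.gene_id: g.end - g.start for g in self}, name="length")

    # --- GFF3 boundary (1-based closed on disk) -----------------------------

    def write_gff3(self, path: str) -> None:
        lines = ["##gff-version 3"]
        for chrom, size in sorted(self.chrom_sizes.items()):
            lines.append(f"##sequence-region {chrom} 1 {size}")
        for g in self:
            for ftype, s0, e0 in (
                ("gene", g.start, g.end),
                ("CDS", g.cds_start, g.cds_end),
                ("three_prime_UTR", g.utr3_start, g.utr3_end),
            ):
                attrs = (
                    f"ID={g.gene_id}"
                    if ftype == "gene"
                    else f"ID={g.gene_id}.{ftype};Parent={g.gene_id}"
                )
                feat = Feature(
                    seqid=g.chrom,
                    source="readerstab",
                    featuretype=ftype,
                    start=s0 + 1,
                    end=e0,
                    score=".",
                    strand=g.strand,
                    frame=".",
                    attributes=attrs,
                )
                lines.append(str(feat))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def read_gff3(cls, path: str) -> "GeneModelSet":
        spans: dict[str, dict] = {}
        chrom_sizes: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, chrom, _, size = line.split()
                    chrom_sizes[chrom] = int(size)
        for n, feat in enumerate(DataIterator(path), start=1):
            try:
                if feat.featuretype == "gene":
                    gid = feat.attributes["ID"][0]
                    rec = spans.setdefault(gid, {})
                    rec.update(
                        chrom=feat.seqid,
                        strand=feat.strand,
                        start=feat.start - 1,
                        end=feat.end,
                    )
                elif feat.featuretype in ("CDS", "three_prime_UTR"):
                    gid = feat.attributes["Parent"][0]
                    key = "cds" if feat.featuretype == "CDS" else "utr3"
                    rec = spans.setdefault(gid, {})
                    rec[f"{key}_start"] = feat.start - 1
                    rec[f"{key}_end"] = feat.end
            except (KeyError, IndexError) as exc:
                raise AnnotationError(f"{path}: malformed record #{n}: {exc}") from exc
        genes = []
        for gid, rec in spans.items():
            missing = {"chrom", "start", "cds_start", "utr3_start"} - set(rec)
            if missing:
                raise AnnotationError(f"{path}: gene {gid} missing features: {sorted(missing)}")
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom=rec["chrom"],
                    start=rec["start"],
                    end=rec["end"],
                    strand=rec["strand"],
                    cds_start=rec["cds_start"],
                    cds_end=rec["cds_end"],
                    utr3_start=rec["utr3_start"],
                    utr3_end=rec["utr3_end"],
                )
            )
        return cls(genes, chrom_sizes=chrom_sizes)

    @classmethod
    def read_bed12(cls, path: str) -> "GeneModelSet":
        """Read gene models from BED12 (thickStart/thickEnd delimit the CDS;
        the 3'UTR is the strand-aware thin segment past the CDS)."""
        cols = [
            "chrom", "start", "end", "name", "score", "strand",
            "thickStart", "thickEnd",
        ]
        df = pd.read_csv(path, sep="\t", header=None, comment="#").iloc[:, :8]
        df.columns = cols
        genes = []
        for n, row in enumerate(df.itertuples(index=False), start=1):
            try:
                if row.strand == "+":
                    u3s, u3e = int(row.thickEnd), int(row.end)
                else:
                    u3s, u3e = int(row.start), int(row.thickStart)
                genes.append(
                    GeneModel(
                        gene_id=str(row.name),
                        chrom=str(row.chrom),
                        start=int(row.start),
                        end=int(row.end),
                        strand=str(row.strand),
                        cds_start=int(row.thickStart),
                        cds_end=int(row.thickEnd),
                        utr3_start=u3s,
                        utr3_end=u3e,
                    )
                )
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}: malformed record #{n}: {exc}") from exc
        return cls(genes)


def read_annotation(path: str) -> GeneModelSet:
    """Load a :class:`GeneModelSet` from GFF3 (``.gff``/``.gff3``) or BED12."""
    lower = str(path).lower()
    if lower.endswith((".gff", ".gff3")):
        return GeneModelSet.read_gff3(path)
    if lower.endswith(".bed"):
        return GeneModelSet.read_bed12(path)
    raise AnnotationError(f"unrecognised annotation format: {path}")
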