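"""Gene annotations and genomic-interval I/O.

All coordinates inside the package are 0-based half-open, the BED
convention.  GTF/GFF3 input (1-based, fully closed) is converted at the
boundary and converted back on write, so a single convention holds
everywhere downstream of this module.  Strand is stored but never used in
window assignment: the DEG-density scan is strand-blind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

GENE_CLASSES = ("histone", "nonhistone", "other")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """A single gene: identifier, location and (optional) class labels.

    ``start``/``end`` are 0-based half-open.  ``gene_class`` is one of
    ``histone``, ``nonhistone`` or ``other``; ``cluster_tag`` marks
    membership of a named gene cluster (e.g. ``"HIST1"``).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    gene_class: str = "other"
    cluster_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise AnnotationError("gene_id must be non-empty")
        if not self.chrom:
            raise AnnotationError(f"{self.gene_id}: chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise AnnotationError(
                f"{self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.gene_class not in GENE_CLASSES:
            raise AnnotationError(
                f"{self.gene_id}: gene_class must be one of {GENE_CLASSES}, "
                f"got {self.gene_class!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def anchor(self) -> int:
        """Point used for window assignment (the gene start, strand-blind)."""
        return self.start


class Annotation:
    """An ordered collection of genes plus chromosome lengths.

    Genes iterate sorted by (chrom, start).  Every gene must lie within its
    chromosome's declared length; lengths missing from ``chrom_lengths``
    are inferred as the maximum gene end on that chromosome.
    """

    def __init__(
        self,
        genes: Iterable[GeneModel],
        chrom_lengths: Optional[Mapping[str, int]] = None,
    ) -> None:
        genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
        seen: set[str] = set()
        for g in genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
        lengths = dict(chrom_lengths) if chrom_lengths else {}
        for g in genes:
            inferred = lengths.get(g.chrom)
            if inferred is None:
                lengths[g.chrom] = g.end
            elif g.end > inferred and chrom_lengths and g.chrom in chrom_lengths:
                raise AnnotationError(
                    f"gene {g.gene_id} ends at {g.end}, beyond declared length "
                    f"{inferred} of {g.chrom}"
                )
            else:
                lengths[g.chrom] = max(inferred, g.end)
        self.genes: list[GeneModel] = genes
        self.chrom_lengths: dict[str, int] = lengths
        self._by_id = {g.gene_id: g for g in genes}

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def chroms(self) -> list[str]:
        return sorted(self.chrom_lengths)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom]

    def with_classes(self, classes: Mapping[str, str]) -> "Annotation":
        """Return a copy with gene classes replaced from a gene_id -> class map."""
        genes = [
            GeneModel(
                g.gene_id, g.chrom, g.start, g.end, g.strand,
                classes.get(g.gene_id, g.gene_class), g.cluster_tag,
            )
            for g in self.genes
        ]
        return Annotation(genes, self.chrom_lengths)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "gene_class": [g.gene_class for g in self.genes],
                "cluster_tag": [g.cluster_tag for g in self.genes],
            }
        )


def _first(attrs, key: str) -> Optional[str]:
    vals = attrs.get(key)
    if not vals:
        return None
    return vals[0] if isinstance(vals, (list, tuple)) else str(vals)


def read_annotation(
    path: str | Path,
    format: Optional[str] = None,
    *,
    feature_type: str = "gene",
    id_attr: str = "gene_id",
    class_attr: str = "gene_class",
    cluster_attr: str = "cluster_tag",
    class_map: Optional[Mapping[str, str]] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> Annotation:
    """Read a gene annotation from GTF, GFF3 or BED6.

    GTF/GFF3 1-based inclusive coordinates are converted to internal
    0-based half-open.  Gene class is read from ``class_attr`` (GTF/GFF3)
    or from a separate ``class_map`` (gene_id -> class); genes without a
    recognized class get ``other``.  Malformed records raise
    :class:`AnnotationError` naming the offending line number.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".gtf": "gtf", ".gff": "gff3", ".gff3": "gff3", ".bed": "bed"}.get(suffix)
        if format is None:
            raise AnnotationError(f"cannot infer annotation format from {path.name!r}")
    if format not in ("gtf", "gff3", "bed"):
        raise AnnotationError(f"unknown annotation format {format!r}")

    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            try:
                if format == "bed":
                    genes.append(_gene_from_bed(line))
                else:
                    gene = _gene_from_gxf(
                        line, feature_type, id_attr, class_attr, cluster_attr
                    )
                    if gene is not None:
                        genes.append(gene)
            except AnnotationError:
                raise
            except Exception as exc:
                raise AnnotationError(
                    f"{path.name} line {lineno}: cannot parse record ({exc})"
                ) from exc
    if class_map:
        genes = [
            GeneModel(
                g.gene_id, g.chrom, g.start, g.end, g.strand,
                class_map.get(g.gene_id, g.gene_class), g.cluster_tag,
            )
            for g in genes
        ]
    return Annotation(genes, chrom_lengths)


def _gene_from_bed(line: str) -> GeneModel:
    fields = line.split("\t")
    if len(fields) < 6:
        raise ValueError(f"BED6 requires 6 columns, got {len(fields)}")
    chrom, start, end, name, _score, strand = fields[:6]
    return GeneModel(name, chrom, int(start), int(end), strand)


def _gene_from_gxf(
    line: str, feature_type: str, id_attr: str, class_attr: str, cluster_attr: str
) -> Optional[GeneModel]:
    if len(line.split("\t")) != 9:
        raise ValueError(f"expected 9 tab-separated columns, got {len(line.split(chr(9)))}")
    feat = feature_from_line(line)
    if feat.featuretype != feature_type:
        return None
    gene_id = _first(feat.attributes, id_attr) or _first(feat.attributes, "ID")
    if gene_id is None:
        raise ValueError(f"no {id_attr!r} or ID attribute")
    gene_class = _first(feat.attributes, class_attr) or "other"
    if gene_class not in GENE_CLASSES:
        gene_class = "other"
    cluster_tag = _first(feat.attributes, cluster_attr)
    # GTF/GFF3 are 1-based inclusive; internal is 0-based half-open.
    return GeneModel(
        gene_id, feat.seqid, feat.start - 1, feat.end,
        feat.strand if feat.strand in ("+", "-") else ".",
        gene_class, cluster_tag,
    )


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={0: str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def read_gene_classes(path: str | Path) -> dict[str, str]:
    """Two-column TSV: gene_id, class (histone/nonhistone/other)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "gene_class"])
    return dict(zip(df["gene_id"], df["gene_class"]))


def write_annotation_bed(annotation: Annotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in annotation:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_annotation_gtf(annotation: Annotation, path: str | Path, source: str = "degscan") -> None:
    with open(path, "w") as fh:
        for g in annotation:
            attrs = f'gene_id "{g.gene_id}"; gene_class "{g.gene_class}";'
            if g.cluster_tag:
                attrs += f' cluster_tag "{g.cluster_tag}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_chrom_lengths(annotation: Annotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(annotation.chrom_lengths):
            fh.write(f"{chrom}\t{annotation.chrom_lengths[chrom]}\n")


def write_regions_bed(regions: Sequence, path: str | Path) -> None:
    """Write refractory regions (or flagged windows) as BED6.

    Score column is the DEG count capped at 1000 (BED format limit); the name
    column carries the supporting contrast label(s).  Input must be sorted
    by (chrom, start).
    """
    keys = [(r.chrom, r.start) for r in regions]
    if keys != sorted(keys):
        raise AnnotationError("regions must be sorted by (chrom, start)")
    with open(path, "w") as fh:
        for r in regions:
            contrasts = getattr(r, "supporting_contrasts", None)
            if contrasts is None:
                name = getattr(r, "contrast", None) or "region"
            else:
                name = ",".join(sorted(contrasts))
            score = min(int(getattr(r, "deg_count", getattr(r, "total_distinct_degs", 0))), 1000)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\t.\n")
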