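"""Genomic annotations: gene models, TE insertions, and TSS-proximity logic.

All coordinates are held internally as 0-based half-open intervals (the BED
convention).  GFF3 input (1-based closed) is converted on ingest.  The
transcription start site (TSS) of a gene is the strand-aware 5' end of the
gene-level feature: ``interval.start`` on the plus strand and
``interval.end - 1`` on the minus strand.

Signed TSS distances follow closestBed-style gap counting: a TE overlapping
the TSS base has distance 0; otherwise the distance is the number of bases
from the TSS to the nearest TE edge, so a TE ending on the base immediately
before the TSS has distance 1.  Upstream (5' of the gene, strand-aware) is
positive, downstream negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

SUPERFAMILIES = ("TIR", "RLG", "RLC", "RLX", "LINE")

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "TEInsertion",
    "GeneTEAssociation",
    "AnnotationParseError",
    "parse_gene_annotation",
    "parse_te_annotation",
    "write_gene_gff3",
    "write_te_bed",
    "write_te_gff3",
    "tss_window",
    "signed_distance",
    "assign_te_to_genes",
    "associations_to_frame",
]


class AnnotationParseError(ValueError):
    """Raised for malformed annotation input; carries the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    gene_set: str = "WGS-only"  # {"FGS", "WGS-only"}

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (a single base position)."""
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def exon_length_total(self) -> int:
        """Total bp of merged exon space; the gene length if no exons annotated."""
        if not self.exons:
            return len(self.interval)
        merged = merge_intervals(self.exons)
        return sum(e.end - e.start for e in merged)


@dataclass
class TEInsertion:
    te_id: str
    family: str
    superfamily: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("family must be non-empty")
        if self.superfamily not in SUPERFAMILIES:
            raise ValueError(f"unknown superfamily {self.superfamily!r}")

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class GeneTEAssociation:
    """One gene-insertion pair: the unit of enrichment counting.

    ``signed_distance`` is positive when the TE lies 5' (upstream) of the
    gene's TSS and negative when 3', zero when the TE overlaps the TSS.
    """

    gene_id: str
    te_id: str
    family: str
    signed_distance: int
    same_strand: bool


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals (same chromosome assumed)."""
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged = [ordered[0]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


# ---------------------------------------------------------------------------
# GFF3 / BED ingest
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, _, value = chunk.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def _iter_gff3_records(path: str | Path):
    """Yield (lineno, chrom, source, ftype, start0, end, strand, attrs)."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, source, ftype, start, end, score, strand, phase, attr_text = fields
            try:
                start1, end1 = int(start), int(end)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: non-integer coordinates {start!r}..{end!r}"
                ) from exc
            if start1 < 1 or end1 < start1:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: invalid 1-based closed range {start1}..{end1}"
                )
            # GFF3 1-based closed -> 0-based half-open
            yield lineno, chrom, source, ftype, start1 - 1, end1, strand, _parse_gff3_attributes(attr_text)


def parse_gene_annotation(
    path: str | Path,
    gene_set_ids: Iterable[str] | None = None,
) -> list[GeneModel]:
    """Read gene models from GFF3, setting TSSs strand-aware.

    gene/mRNA/exon features are recognised; exons attach to genes directly or
    through their mRNA parent.  Genes whose id appears in ``gene_set_ids``
    are labelled FGS (filtered gene set); all others WGS-only.  A gene
    without annotated exons keeps its full span as exon space (warning).
    """
    fgs = set(gene_set_ids) if gene_set_ids is not None else set()
    genes: dict[str, GeneModel] = {}
    mrna_parent: dict[str, str] = {}
    pending_exons: list[tuple[str, GenomicInterval]] = []

    for lineno, chrom, _src, ftype, start, end, strand, attrs in _iter_gff3_records(path):
        if ftype == "gene":
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if gene_id is None:
                raise AnnotationParseError(f"{path}: line {lineno}: gene feature lacks ID")
            genes[gene_id] = GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval(chrom, start, end, strand),
                gene_set="FGS" if gene_id in fgs else "WGS-only",
            )
        elif ftype == "mRNA":
            mrna_id = attrs.get("ID")
            parent = attrs.get("Parent")
            if mrna_id and parent:
                mrna_parent[mrna_id] = parent
        elif ftype == "exon":
            parent = attrs.get("Parent")
            if parent is None:
                raise AnnotationParseError(f"{path}: line {lineno}: exon feature lacks Parent")
            pending_exons.append((parent, GenomicInterval(chrom, start, end, strand)))

    for parent, exon in pending_exons:
        gene_id = mrna_parent.get(parent, parent)
        gene = genes.get(gene_id)
        if gene is None:
            logger.warning("exon with unknown parent %s skipped", parent)
            continue
        gene.exons.append(exon)

    n_exonless = sum(1 for g in genes.values() if not g.exons)
    if n_exonless:
        logger.warning(
            "%d gene(s) without annotated exons; using gene length as exon space", n_exonless
        )
    return list(genes.values())


def _family_from_name(name: str) -> str:
    """BED name fields like ``naiba_001`` carry the family before a numeric suffix."""
    stem, _, suffix = name.rpartition("_")
    if stem and suffix.isdigit():
        return stem
    return name


def parse_te_annotation(
    path: str | Path,
    family_map: Mapping[str, str] | None = None,
) -> list[TEInsertion]:
    """Read TE insertions from BED or GFF3 (dialect sniffed from content).

    ``family_map`` assigns superfamilies (TIR/RLG/RLC/RLX/LINE) per family;
    unmapped families default to RLX (the unknown-retrotransposon class)
    with a warning.  Records lacking a family are skipped and counted.
    """
    family_map = dict(family_map or {})
    path = Path(path)
    is_gff = _sniff_gff3(path)
    tes: list[TEInsertion] = []
    n_skipped = 0
    unmapped: set[str] = set()

    def build(te_id: str, family: str, chrom: str, start: int, end: int, strand: str,
              superfamily: str | None = None) -> None:
        sf = superfamily or family_map.get(family)
        if sf is None:
            unmapped.add(family)
            sf = "RLX"
        tes.append(TEInsertion(te_id, family, sf, GenomicInterval(chrom, start, end, strand)))

    if is_gff:
        for lineno, chrom, _src, _ftype, start, end, strand, attrs in _iter_gff3_records(path):
            family = attrs.get("family") or attrs.get("Name")
            if not family:
                n_skipped += 1
                continue
            te_id = attrs.get("ID") or f"{family}_{lineno}"
            build(te_id, family, chrom, start, end,
                  strand if strand in "+-" else ".", attrs.get("superfamily"))
    else:
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    n_skipped += 1
                    continue
                chrom, start, end = fields[0], fields[1], fields[2]
                name = fields[3]
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
                try:
                    start0, end0 = int(start), int(end)
                except ValueError as exc:
                    raise AnnotationParseError(
                        f"{path}: line {lineno}: non-integer BED coordinates"
                    ) from exc
                build(name, _family_from_name(name), chrom, start0, end0, strand)

    if n_skipped:
        logger.warning("%d TE record(s) without a family field skipped", n_skipped)
    if unmapped:
        logger.warning(
            "no superfamily mapping for %d family(ies) (%s...); defaulting to RLX",
            len(unmapped), sorted(unmapped)[0],
        )
    return tes


def _sniff_gff3(path: Path) -> bool:
    if path.suffix.lower() in (".gff", ".gff3"):
        return True
    if path.suffix.lower() == ".bed":
        return False
    with open(path) as handle:
        for line in handle:
            if line.startswith("##gff-version"):
                return True
            if line.startswith("#") or not line.strip():
                continue
            return len(line.rstrip("\n").split("\t")) == 9
    return False


def write_gene_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for gene in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = gene.interval
            out.write(
                f"{iv.chrom}\tte_stress\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            for i, exon in enumerate(sorted(gene.exons, key=lambda e: e.start), start=1):
                out.write(
                    f"{exon.chrom}\tte_stress\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{iv.strand}\t.\tID={gene.gene_id}.exon{i};Parent={gene.gene_id}\n"
                )


def write_te_bed(tes: Sequence[TEInsertion], path: str | Path) -> None:
    with open(path, "w") as out:
        for te in sorted(tes, key=lambda t: (t.interval.chrom, t.interval.start)):
            iv = te.interval
            strand = iv.strand if iv.strand in "+-" else "."
            out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{te.te_id}\t.\t{strand}\n")


def write_te_gff3(tes: Sequence[TEInsertion], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for te in sorted(tes, key=lambda t: (t.interval.chrom, t.interval.start)):
            iv = te.interval
            strand = iv.strand if iv.strand in "+-" else "."
            out.write(
                f"{iv.chrom}\tte_stress\ttransposable_element\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{strand}\t.\tID={te.te_id};family={te.family};superfamily={te.superfamily}\n"
            )


# ---------------------------------------------------------------------------
# TSS proximity
# ---------------------------------------------------------------------------

def tss_window(gene: GeneModel, size: int = 100) -> GenomicInterval:
    """The ``size``-bp window extending upstream from the TSS (strand-aware).

    The window abuts the TSS on its 5' side; it is truncated at the
    chromosome start when it would extend below position 0.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    tss = gene.tss
    chrom = gene.interval.chrom
    if gene.interval.strand == "-":
        return GenomicInterval(chrom, tss + 1, tss + 1 + size, "-")
    start = max(0, tss - size)
    if start == tss:  # gene starts at chromosome position 0
        raise ValueError(f"TSS window for {gene.gene_id} is empty at chromosome start")
    return GenomicInterval(chrom, start, tss, gene.interval.strand if gene.interval.strand in "+-" else "+")


def signed_distance(te: TEInsertion, gene: GeneModel) -> int:
    """Signed bp distance from the gene's TSS to the nearest edge of ``te``.

    0 when the TE interval contains the TSS base; otherwise gap counting in
    which the closest possible non-overlapping TE is at distance 1.
    Positive = TE on the gene's 5' side, negative = 3' side.
    """
    iv = te.interval
    giv = gene.interval
    if iv.chrom != giv.chrom:
        raise ValueError(
            f"signed_distance undefined across chromosomes ({iv.chrom} vs {giv.chrom})"
        )
    tss = gene.tss
    if iv.contains(tss):
        return 0
    if iv.end <= tss:  # TE on the lower-coordinate side
        gap = tss - (iv.end - 1)
        return -gap if giv.strand == "-" else gap
    gap = iv.start - tss  # TE on the higher-coordinate side
    return gap if giv.strand == "-" else -gap


def assign_te_to_genes(
    genes: Sequence[GeneModel],
    tes: Sequence[TEInsertion],
    window: int = 1000,
    mode: str = "upstream_only",
) -> list[GeneTEAssociation]:
    """Associate every TE within ``window`` bp of each gene's TSS.

    ``mode='upstream_only'`` keeps TEs at signed distance 0..window (5' of
    the TSS or overlapping it); ``mode='symmetric'`` keeps |d| <= window.
    A gene may associate with many insertions and families.
    """
    if mode not in ("upstream_only", "symmetric"):
        raise ValueError(f"unknown mode {mode!r}")
    by_chrom: dict[str, IntervalTree] = {}
    for idx, te in enumerate(tes):
        tree = by_chrom.setdefault(te.interval.chrom, IntervalTree())
        tree.addi(te.interval.start, te.interval.end, idx)

    out: list[GeneTEAssociation] = []
    for gene in genes:
        tree = by_chrom.get(gene.interval.chrom)
        if tree is None:
            continue
        tss = gene.tss
        # any TE within `window` of the TSS intersects this padded interval
        for hit in tree.overlap(max(0, tss - window), tss + window + 1):
            te = tes[hit.data]
            d = signed_distance(te, gene)
            if mode == "upstream_only" and not (0 <= d <= window):
                continue
            if mode == "symmetric" and abs(d) > window:
                continue
            out.append(
                GeneTEAssociation(
                    gene_id=gene.gene_id,
                    te_id=te.te_id,
                    family=te.family,
                    signed_distance=d,
                    same_strand=te.interval.strand == gene.interval.strand,
                )
            )
    out.sort(key=lambda a: (a.gene_id, a.te_id))
    return out


def associations_to_frame(associations: Sequence[GeneTEAssociation]) -> pd.DataFrame:
    """Tabulate associations (one row per gene-insertion pair)."""
    return pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in associations],
            "te_id": [a.te_id for a in associations],
            "family": [a.family for a in associations],
            "signed_distance": [a.signed_distance for a in associations],
            "same_strand": [a.same_strand for a in associations],
        }
    )
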