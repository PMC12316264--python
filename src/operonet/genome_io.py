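"""Genome annotations, per-base coverage tracks, and strand-aware gene pairing.

All coordinates are 0-based half-open internally.  GFF3/GTF files (1-based
inclusive) are converted on read and write, bedGraph (already 0-based
half-open) is taken as-is, and per-base depth TSVs (``samtools depth``
dialect) are 1-based.

Gene pairs are formed per (contig, strand): genes are sorted by start and
each adjacent same-strand pair becomes one candidate.  Genes on the opposite
strand lying between the two do not break adjacency, which is what lets the
classifier see noncontiguous-operon candidates (a co-transcribed pair
separated by an antisense gene).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np

logger = logging.getLogger(__name__)

_ID_ATTRIBUTES = ("ID", "locus_tag", "gene_id", "Name")


class AnnotationFormatError(ValueError):
    """Raised when an annotation file cannot be parsed as GFF3/GTF."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: contig, 0-based half-open interval, strand."""

    gene_id: str
    seqid: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: need 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Dense per-contig read-depth arrays for one RNA-seq sample."""

    sample_id: str
    depths: dict[str, np.ndarray] = field(default_factory=dict)

    def contig_length(self, seqid: str) -> int:
        return len(self.depths[seqid])

    def slice(self, seqid: str, start: int, end: int) -> np.ndarray:
        if seqid not in self.depths:
            raise KeyError(
                f"contig {seqid!r} missing from coverage track "
                f"{self.sample_id!r}"
            )
        return self.depths[seqid][start:end]


@dataclass(frozen=True)
class GenePair:
    """Two consecutive same-strand genes plus their intergenic interval.

    ``gene1`` is the genomic-leftmost gene.  The intergenic region (IGR) is
    the half-open gap between gene1.end and gene2.start, clamped to length 0
    when the genes abut or overlap.
    """

    pair_id: str
    gene1: GeneModel
    gene2: GeneModel
    strand: str
    seqid: str
    igr_start: int
    igr_end: int

    def __post_init__(self) -> None:
        if self.gene1.strand != self.strand or self.gene2.strand != self.strand:
            raise ValueError(f"pair {self.pair_id!r}: strand mismatch")
        if self.gene1.seqid != self.gene2.seqid:
            raise ValueError(f"pair {self.pair_id!r}: contig mismatch")
        if self.igr_start > self.igr_end:
            raise ValueError(f"pair {self.pair_id!r}: inverted IGR interval")

    @property
    def igr_length(self) -> int:
        return self.igr_end - self.igr_start


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _feature_id(feature: "gffutils.Feature", id_attribute: str | None) -> str | None:
    if id_attribute is not None:
        values = feature.attributes.get(id_attribute, [])
        return values[0] if values else None
    for key in _ID_ATTRIBUTES:
        values = feature.attributes.get(key, [])
        if values:
            return values[0]
    if feature.id:
        return feature.id
    return None


def load_annotation(
    path: str | Path,
    feature_type: str = "gene",
    id_attribute: str | None = None,
) -> tuple[list[GeneModel], dict]:
    """Read gene records from a GFF3 or GTF file via gffutils.

    Coordinates are converted from the file's 1-based inclusive convention
    to 0-based half-open.  Records with strand ``.``/``?`` or without any
    recognisable identifier are skipped with a warning; the count of skipped
    records is returned in the metadata dict.

    Returns
    -------
    (genes, meta)
        Genes sorted by (seqid, start, end, gene_id); ``meta`` holds
        ``n_skipped`` and ``n_records``.
    """
    try:
        db = gffutils.create_db(
            str(path), ":memory:",
            merge_strategy="create_unique", keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return [], {"n_skipped": 0, "n_records": 0}
    except Exception as exc:
        raise AnnotationFormatError(f"cannot parse {path}: {exc}") from exc
    genes: list[GeneModel] = []
    n_skipped = 0
    n_records = 0
    seen_ids: set[str] = set()
    for feature in db.features_of_type(feature_type):
        n_records += 1
        gene_id = _feature_id(feature, id_attribute)
        if feature.strand not in ("+", "-") or gene_id is None:
            n_skipped += 1
            logger.warning(
                "%s: skipping %s record at %s:%d-%d (strand=%r, id=%r)",
                path, feature_type, feature.seqid, feature.start,
                feature.end, feature.strand, gene_id,
            )
            continue
        if gene_id in seen_ids:
            raise AnnotationFormatError(f"{path}: duplicate gene id {gene_id!r}")
        seen_ids.add(gene_id)
        # GFF/GTF are 1-based inclusive; internal is 0-based half-open.
        genes.append(
            GeneModel(gene_id=gene_id, seqid=feature.seqid,
                      start=feature.start - 1, end=feature.end,
                      strand=feature.strand)
        )
    genes.sort(key=lambda g: (g.seqid, g.start, g.end, g.gene_id))
    return genes, {"n_skipped": n_skipped, "n_records": n_records}


def write_annotation(genes: Iterable[GeneModel], path: str | Path,
                     feature_type: str = "gene", source: str = "operonet") -> None:
    """Write genes as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "wt") as handle:
        handle.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.seqid, g.start, g.end)):
            handle.write(
                f"{g.seqid}\t{source}\t{feature_type}\t{g.start + 1}\t{g.end}"
                f"\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def load_coverage(
    path: str | Path,
    sample_id: str,
    contig_lengths: dict[str, int],
    dialect: str = "perbase",
) -> CoverageTrack:
    """Read one coverage track into dense per-contig arrays.

    Parameters
    ----------
    dialect
        ``"perbase"`` — rows ``contig<TAB>position<TAB>depth`` with 1-based
        positions (``samtools depth`` output); or ``"bedgraph"`` — rows
        ``contig<TAB>start<TAB>end<TAB>depth`` with 0-based half-open
        intervals.  Positions absent from the input are depth 0.
    """
    if dialect not in ("perbase", "bedgraph"):
        raise ValueError(f"unknown coverage dialect {dialect!r}")
    depths = {
        seqid: np.zeros(length, dtype=np.int64)
        for seqid, length in contig_lengths.items()
    }
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            seqid = cols[0]
            if seqid not in depths:
                raise ValueError(
                    f"{path}:{lineno}: contig {seqid!r} not in contig_lengths"
                )
            arr = depths[seqid]
            if dialect == "bedgraph":
                start, end, depth = int(cols[1]), int(cols[2]), int(float(cols[3]))
                if depth < 0:
                    raise ValueError(f"{path}:{lineno}: negative depth {depth}")
                if end > len(arr):
                    raise ValueError(
                        f"{path}:{lineno}: interval end {end} beyond length "
                        f"of contig {seqid!r} ({len(arr)})"
                    )
                arr[start:end] += depth
            else:
                pos1, depth = int(cols[1]), int(float(cols[2]))
                if depth < 0:
                    raise ValueError(f"{path}:{lineno}: negative depth {depth}")
                if not (1 <= pos1 <= len(arr)):
                    raise ValueError(
                        f"{path}:{lineno}: position {pos1} beyond length of "
                        f"contig {seqid!r} ({len(arr)})"
                    )
                arr[pos1 - 1] = depth
    return CoverageTrack(sample_id=sample_id, depths=depths)


def enumerate_pairs(genes: Sequence[GeneModel]) -> list[GenePair]:
    """Enumerate consecutive same-strand gene pairs per contig.

    Adjacency is defined within each (contig, strand) group after sorting by
    start, so antisense genes between two same-strand genes never terminate
    a pair — the antisense gene simply sits inside the pair's IGR.  The IGR
    is clamped to length 0 when the genes abut, overlap, or are nested.
    """
    groups: dict[tuple[str, str], list[GeneModel]] = {}
    for gene in genes:
        groups.setdefault((gene.seqid, gene.strand), []).append(gene)
    pairs: list[GenePair] = []
    for (seqid, strand), members in groups.items():
        members = sorted(members, key=lambda g: (g.start, g.end, g.gene_id))
        for left, right in zip(members, members[1:]):
            igr_start = left.end
            igr_end = max(left.end, right.start)
            pairs.append(
                GenePair(
                    pair_id=f"{left.gene_id}|{right.gene_id}",
                    gene1=left,
                    gene2=right,
                    strand=strand,
                    seqid=seqid,
                    igr_start=igr_start,
                    igr_end=igr_end,
                )
            )
    pairs.sort(key=lambda p: (p.seqid, p.gene1.start, p.gene2.start))
    return pairs
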