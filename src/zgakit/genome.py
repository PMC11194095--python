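"""Genome annotation, interval arithmetic, and intergenic-region derivation.

All coordinates are 0-based, half-open (`[start, end)`), BED-style. GTF input
(1-based, closed) is converted on read. Intergenic space is defined as every
base lying strictly more than a fixed distance (default 10 kb) from any
annotated gene body, with non-coding genes and pseudogenes counting as genes
and repeat elements *not* subtracted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GenomeAnnotation",
    "IntervalSet",
    "ParseError",
    "merge_intervals",
    "derive_intergenic_regions",
    "read_annotation",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
]


class ParseError(ValueError):
    """Malformed annotation input; the message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome.

    ``name`` carries a feature/read id and ``feature_class`` a biotype
    (e.g. ``protein_coding``, ``lncRNA``, ``pseudogene``) or repeat family.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    feature_class: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus gene and repeat intervals.

    Genes of every class (protein-coding, non-coding, pseudogene) participate
    in intergenic-region derivation; repeats are carried along for repeat
    expression analysis but never subtracted from intergenic space.
    """

    chrom_sizes: dict[str, int]
    genes: list[GenomicInterval] = field(default_factory=list)
    repeats: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {size}")
        seen: set[str] = set()
        for gene in self.genes:
            if gene.name:
                if gene.name in seen:
                    raise ValueError(f"duplicate gene id {gene.name!r}")
                seen.add(gene.name)
        for iv in list(self.genes) + list(self.repeats):
            size = self.chrom_sizes.get(iv.chrom)
            if size is None:
                raise ValueError(f"feature {iv.name!r} on unknown chromosome {iv.chrom}")
            if iv.end > size:
                raise ValueError(
                    f"feature {iv.name!r} [{iv.start}, {iv.end}) exceeds "
                    f"{iv.chrom} length {size}"
                )


class IntervalSet:
    """Per-chromosome sorted, disjoint, merged intervals.

    Stored as ``(n, 2)`` integer arrays keyed by chromosome; supports O(log n)
    full-containment queries, complements, and BED round-trips. A provenance
    ``tag`` (e.g. ``"intergenic, d=10000"``) travels with the set.
    """

    def __init__(self, per_chrom: Mapping[str, np.ndarray] | None = None, tag: str = ""):
        self.tag = tag
        self._data: dict[str, np.ndarray] = {}
        if per_chrom:
            for chrom, arr in per_chrom.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                if arr.size:
                    order = np.argsort(arr[:, 0], kind="stable")
                    arr = arr[order]
                    if np.any(arr[:, 0] >= arr[:, 1]):
                        raise ValueError(f"empty or inverted interval on {chrom}")
                    if np.any(arr[1:, 0] < arr[:-1, 1]):
                        raise ValueError(f"overlapping intervals on {chrom}")
                    self._data[chrom] = arr

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval], tag: str = "") -> "IntervalSet":
        """Build the minimal disjoint cover of the union (touching intervals merge)."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        out: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            merged: list[list[int]] = []
            for s, e in pairs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = np.asarray(merged, dtype=np.int64)
        return cls(out, tag=tag)

    # -- queries -----------------------------------------------------------

    def contains(self, query: GenomicInterval) -> bool:
        """True iff one member interval fully contains ``[query.start, query.end)``."""
        arr = self._data.get(query.chrom)
        if arr is None:
            return False
        idx = int(np.searchsorted(arr[:, 0], query.start, side="right")) - 1
        if idx < 0:
            return False
        return bool(arr[idx, 0] <= query.start and query.end <= arr[idx, 1])

    def contains_many(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`contains` for arrays of queries on one chromosome."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        arr = self._data.get(chrom)
        if arr is None or arr.size == 0:
            return np.zeros(starts.shape, dtype=bool)
        idx = np.searchsorted(arr[:, 0], starts, side="right") - 1
        ok = idx >= 0
        idx = np.clip(idx, 0, len(arr) - 1)
        return ok & (arr[idx, 0] <= starts) & (ends <= arr[idx, 1])

    def chromosomes(self) -> list[str]:
        return sorted(self._data)

    def arrays(self, chrom: str) -> np.ndarray:
        return self._data.get(chrom, np.empty((0, 2), dtype=np.int64))

    def intervals(self) -> Iterator[GenomicInterval]:
        for chrom in self.chromosomes():
            for s, e in self._data[chrom]:
                yield GenomicInterval(chrom, int(s), int(e))

    @property
    def n_intervals(self) -> int:
        return sum(len(a) for a in self._data.values())

    def total_bp(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._data.values()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(np.array_equal(self._data[c], other._data[c]) for c in self._data)

    def __repr__(self) -> str:
        return f"IntervalSet({self.n_intervals} intervals, tag={self.tag!r})"

    # -- IO ----------------------------------------------------------------

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals():
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")

    @classmethod
    def from_bed(cls, path: str | Path, tag: str = "") -> "IntervalSet":
        return cls.from_intervals(read_bed(path), tag=tag)


def merge_intervals(intervals: Iterable[GenomicInterval], tag: str = "") -> IntervalSet:
    """Merge possibly overlapping/touching intervals into a disjoint cover."""
    return IntervalSet.from_intervals(intervals, tag=tag)


def derive_intergenic_regions(
    annotation: GenomeAnnotation, distance_bp: int = 10_000
) -> IntervalSet:
    """Complement of all gene bodies expanded by ``distance_bp`` on both sides.

    A base exactly ``distance_bp`` away from a gene is *excluded*: intergenic
    space keeps only bases strictly farther than the cutoff, matching a strict
    ``> distance_bp`` rule. Gene classes are not distinguished and repeats are
    not subtracted.
    """
    if distance_bp < 0:
        raise ValueError("distance_bp must be >= 0")
    if not annotation.chrom_sizes:
        raise ValueError("annotation has no chromosomes")
    if not annotation.genes:
        logger.warning("annotation has no genes; whole chromosomes are intergenic")
    expanded = [
        GenomicInterval(
            g.chrom,
            max(0, g.start - distance_bp),
            min(annotation.chrom_sizes[g.chrom], g.end + distance_bp),
        )
        for g in annotation.genes
    ]
    excluded = IntervalSet.from_intervals(expanded)
    out: dict[str, np.ndarray] = {}
    for chrom, size in annotation.chrom_sizes.items():
        arr = excluded.arrays(chrom)
        comp: list[tuple[int, int]] = []
        cursor = 0
        for s, e in arr:
            if s > cursor:
                comp.append((cursor, int(s)))
            cursor = max(cursor, int(e))
        if cursor < size:
            comp.append((cursor, size))
        if comp:
            out[chrom] = np.asarray(comp, dtype=np.int64)
    return IntervalSet(out, tag=f"intergenic, d={distance_bp}")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'name<TAB>length'")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4(+) intervals; coordinates pass through unchanged."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "."
            try:
                out.append(GenomicInterval(parts[0], start, end, name=name, strand=strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gtf_genes(path: str | Path, feature_types: tuple[str, ...] = ("gene",)) -> list[GenomicInterval]:
    """Read gene records from a GTF file.

    GTF 1-based closed coordinates are converted to 0-based half-open. The
    attribute field is parsed for ``gene_id`` and a biotype
    (``gene_biotype``/``gene_type``/``biotype``).
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns, got {len(parts)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = parts
            if feature not in feature_types:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise ParseError(f"{path}:{lineno}: end {end1} < start {start1}")
            attr = dict(_GTF_ATTR.findall(attrs))
            biotype = (
                attr.get("gene_biotype") or attr.get("gene_type") or attr.get("biotype") or ""
            )
            try:
                out.append(
                    GenomicInterval(
                        chrom,
                        start1 - 1,
                        end1,
                        name=attr.get("gene_id", ""),
                        feature_class=biotype,
                        strand=strand,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_gtf_genes(genes: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.name}"; gene_biotype "{g.feature_class or "protein_coding"}";'
            fh.write(
                f"{g.chrom}\tzgakit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_annotation(
    path: str | Path,
    format: str,
    chrom_sizes: Mapping[str, int] | str | Path,
    repeats_path: str | Path | None = None,
) -> GenomeAnnotation:
    """Read a gene annotation (GTF or BED) into a :class:`GenomeAnnotation`.

    ``chrom_sizes`` may be a mapping or a path to a two-column TSV. Repeats,
    if given, are read from a BED file whose name column holds the repeat
    subfamily.
    """
    if not isinstance(chrom_sizes, Mapping):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    if format == "gtf":
        genes = read_gtf_genes(path)
    elif format == "bed":
        genes = read_bed(path)
    else:
        raise ValueError(f"unknown annotation format {format!r} (expected 'gtf' or 'bed')")
    repeats: list[GenomicInterval] = []
    if repeats_path is not None:
        repeats = [
            GenomicInterval(iv.chrom, iv.start, iv.end, name=iv.name, feature_class=iv.name)
            for iv in read_bed(repeats_path)
        ]
    return GenomeAnnotation(chrom_sizes=dict(chrom_sizes), genes=genes, repeats=repeats)
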