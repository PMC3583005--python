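"""File formats and the canonical in-memory coordinate conventions.

All internal coordinates are 0-based half-open ``[start, end)`` on the
forward strand, regardless of source format.  GTF (1-based inclusive) is
converted at the boundary; BED and bedGraph are passed through unchanged.
Chromosome names are taken verbatim — no ``chr`` normalisation is ever
applied, and cross-file chromosome mismatches raise rather than silently
dropping intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger("nmiscape")

BIOTYPES = frozenset({
    "protein_coding", "lncRNA", "miRNA", "rRNA", "snRNA", "snoRNA",
    "pseudogene", "processed_transcript", "novel",
})

STRANDS = frozenset({"+", "-", "."})


class ParseError(ValueError):
    """Raised on malformed input records; carries file/line context."""


# ---------------------------------------------------------------------------
# core domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open genomic interval.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive, so
    ``length == end - start >= 1``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def sort_key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval` on one genome.

    Supports the interval algebra every pipeline stage needs: sorting,
    merging to a disjoint footprint, per-base coverage queries and
    any-overlap lookups (binary search over per-chromosome sorted arrays).
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (),
                 genome_id: str = "genome"):
        self.intervals: List[GenomicInterval] = list(intervals)
        self.genome_id = genome_id
        self._index: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None
        self._index_src: List[GenomicInterval] = []

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def sorted(self) -> "IntervalSet":
        return IntervalSet(sorted(self.intervals, key=GenomicInterval.sort_key),
                           self.genome_id)

    def chroms(self) -> List[str]:
        seen: Dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def merge(self, gap: int = 0) -> "IntervalSet":
        """Union intervals closer than ``gap`` bp into a disjoint footprint.

        With ``gap == 0`` (default) touching intervals are joined; the
        per-base footprint of the result equals the input's.
        """
        merged: List[GenomicInterval] = []
        for iv in sorted(self.intervals, key=GenomicInterval.sort_key):
            if merged and iv.chrom == merged[-1].chrom \
                    and iv.start <= merged[-1].end + gap:
                last = merged[-1]
                if iv.end > last.end:
                    merged[-1] = replace(last, end=iv.end)
            else:
                merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
        return IntervalSet(merged, self.genome_id)

    def total_bp(self) -> int:
        """Base pairs in the merged footprint."""
        return sum(iv.length for iv in self.merge())

    # -- overlap queries ----------------------------------------------------

    def _build_index(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        if self._index is None or len(self._index_src) != len(self.intervals):
            idx: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
            merged = self.merge()
            for chrom in merged.chroms():
                ivs = [iv for iv in merged if iv.chrom == chrom]
                idx[chrom] = (np.array([iv.start for iv in ivs]),
                              np.array([iv.end for iv in ivs]))
            self._index = idx
            self._index_src = list(self.intervals)
        return self._index

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        """True if ``[start, end)`` on ``chrom`` intersects >= 1 bp of the set."""
        idx = self._build_index()
        if chrom not in idx:
            return False
        starts, ends = idx[chrom]
        # first merged interval whose end is past our start
        i = int(np.searchsorted(ends, start, side="right"))
        return i < len(starts) and starts[i] < end

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Base pairs of ``[start, end)`` covered by the merged footprint."""
        idx = self._build_index()
        if chrom not in idx:
            return 0
        starts, ends = idx[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return int(np.sum(e - s))


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand, derived TSS/TTS and a biotype label."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: require 0 <= start < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"gene {self.gene_id}: unknown biotype {self.biotype}")

    @property
    def tss(self) -> int:
        """TSS base: ``start`` on +, ``end - 1`` on - (last base of the span)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               self.strand, self.gene_id)


class CoverageTrack:
    """Per-chromosome read-density vectors at a fixed bin width.

    Values are non-negative densities per base (bin value applies to every
    base of the bin); ``total_reads`` carries the read count when known.
    """

    def __init__(self, chrom_sizes: Dict[str, int], bin_width: int = 1,
                 total_reads: float = 0.0):
        if bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        self.bin_width = bin_width
        self.chrom_sizes = dict(chrom_sizes)
        self.total_reads = total_reads
        self.data: Dict[str, np.ndarray] = {
            c: np.zeros(math.ceil(n / bin_width), dtype=float)
            for c, n in chrom_sizes.items()
        }

    def chroms(self) -> List[str]:
        return list(self.data)

    def add_interval(self, chrom: str, start: int, end: int, value: float) -> None:
        """Add ``value`` per-base over ``[start, end)`` (bin-proportional)."""
        vec = self.data[chrom]
        w = self.bin_width
        if w == 1:
            vec[start:end] += value
            return
        b0, b1 = start // w, (end - 1) // w
        if b0 == b1:
            vec[b0] += value * (end - start) / w
            return
        vec[b0] += value * ((b0 + 1) * w - start) / w
        vec[b1] += value * (end - b1 * w) / w
        if b1 - b0 > 1:
            vec[b0 + 1:b1] += value

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base density values over ``[start, end)`` (expanded to 1 bp)."""
        vec = self.data[chrom]
        if self.bin_width == 1:
            return vec[start:end]
        idx = np.arange(start, end) // self.bin_width
        return vec[idx]

    def area(self, chrom: str, start: int, end: int) -> float:
        """Summed per-base density (signal area) over ``[start, end)``."""
        return float(self.values(chrom, start, end).sum())

    def mean(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            return 0.0
        return self.area(chrom, start, end) / (end - start)

    def total_area(self) -> float:
        return float(sum(v.sum() for v in self.data.values())) * self.bin_width


@dataclass
class CountMatrix:
    """Gene x sample read counts with a tissue label per sample."""

    counts: pd.DataFrame                  # rows gene_id, columns sample_id
    tissues: Dict[str, str]               # sample_id -> tissue label

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        missing = set(self.counts.columns) - set(self.tissues)
        if missing:
            raise ValueError(f"samples without tissue label: {sorted(missing)}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    def samples_for(self, tissue: str) -> List[str]:
        return [s for s in self.counts.columns if self.tissues[s] == tissue]

    def tissue_labels(self) -> List[str]:
        seen: Dict[str, None] = {}
        for s in self.counts.columns:
            seen.setdefault(self.tissues[s], None)
        return list(seen)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path: str) -> Iterator[Tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track") \
                    or line.startswith("browser"):
                continue
            yield lineno, line


def read_bed(path: str, genome_id: str = "genome") -> IntervalSet:
    """Read BED3/BED6 into an :class:`IntervalSet` (coordinates unchanged)."""
    intervals: List[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        name = fields[3] if len(fields) > 3 else "."
        score: Optional[float] = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            score = float(fields[4])
        strand = fields[5] if len(fields) > 5 else "."
        try:
            intervals.append(GenomicInterval(fields[0], start, end, strand,
                                             name, score))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals, genome_id)


def write_bed(iset: IntervalSet, path: str, sort: bool = True) -> None:
    """Write BED6; score written as its shortest exact representation."""
    ivs = iset.sorted().intervals if sort else iset.intervals
    with open(path, "w") as fh:
        for iv in ivs:
            score = "0" if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                     f"{score}\t{iv.strand}\n")


def read_chrom_sizes(path: str) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: need chrom<TAB>size")
        sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, n in sizes.items():
            fh.write(f"{chrom}\t{n}\n")


def _coerce_biotype(raw: str, gene_id: str) -> str:
    aliases = {"lincRNA": "lncRNA", "lnc_RNA": "lncRNA"}
    bt = aliases.get(raw, raw)
    if bt not in BIOTYPES:
        logger.warning("gene %s: unknown biotype %r mapped to processed_transcript",
                       gene_id, raw)
        return "processed_transcript"
    return bt


def _parse_gtf_attributes(attr: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, value = part.partition(" ")
            out[key] = value.strip().strip('"')
    return out


def read_gene_models(path: str, dialect: str = "gtf") -> List[GeneModel]:
    """Read gene models from GTF (gene features), BED12 or a plain TSV.

    GTF 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention.  Records without strand are rejected; unknown
    biotypes are mapped to ``processed_transcript`` with a warning.
    """
    genes: List[GeneModel] = []
    if dialect == "gtf":
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: GTF needs 9 columns")
            if fields[2] != "gene":
                continue
            strand = fields[6]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: gene record without strand")
            attrs = _parse_gtf_attributes(fields[8])
            gene_id = attrs.get("gene_id", f"gene_line{lineno}")
            biotype = _coerce_biotype(
                attrs.get("gene_biotype", attrs.get("gene_type", "protein_coding")),
                gene_id)
            genes.append(GeneModel(gene_id, fields[0],
                                   int(fields[3]) - 1, int(fields[4]),
                                   strand, biotype))
    elif dialect == "bed12":
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED12 needs >= 6 columns")
            strand = fields[5]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: gene record without strand")
            biotype = _coerce_biotype(fields[12] if len(fields) > 12
                                      else "protein_coding", fields[3])
            genes.append(GeneModel(fields[3], fields[0], int(fields[1]),
                                   int(fields[2]), strand, biotype))
    elif dialect == "tsv":
        # columns: gene_id chrom start end strand biotype (0-based half-open)
        df = pd.read_csv(path, sep="\t")
        for _, row in df.iterrows():
            strand = str(row["strand"])
            if strand not in ("+", "-"):
                raise ParseError(f"{path}: gene {row['gene_id']} without strand")
            genes.append(GeneModel(str(row["gene_id"]), str(row["chrom"]),
                                   int(row["start"]), int(row["end"]), strand,
                                   _coerce_biotype(str(row.get("biotype",
                                                               "protein_coding")),
                                                   str(row["gene_id"]))))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return genes


def write_gene_models_gtf(genes: Sequence[GeneModel], path: str) -> None:
    """Write gene features as GTF-lite (internal half-open -> 1-based)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(f"{g.chrom}\tnmiscape\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")


def read_bedgraph(path: str, chrom_sizes: Dict[str, int],
                  bin_width: int = 1) -> CoverageTrack:
    """Read bedGraph into a :class:`CoverageTrack` (uncovered positions = 0).

    Overlapping records are last-writer-wins with a warning; intervals
    beyond the chromosome end raise.
    """
    track = CoverageTrack(chrom_sizes, bin_width=bin_width)
    seen_end: Dict[str, int] = {}
    warned = False
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), \
            float(fields[3])
        if chrom not in chrom_sizes:
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if end > chrom_sizes[chrom]:
            raise ParseError(
                f"{path}:{lineno}: interval beyond end of {chrom}")
        if start < seen_end.get(chrom, 0) and not warned:
            logger.warning("%s:%d: overlapping bedGraph records; "
                           "last writer wins", path, lineno)
            warned = True
        seen_end[chrom] = max(seen_end.get(chrom, 0), end)
        if bin_width == 1:
            track.data[chrom][start:end] = value
        else:  # last-writer-wins approximated at bin resolution
            b0, b1 = start // bin_width, math.ceil(end / bin_width)
            track.data[chrom][b0:b1] = value
    return track


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """Write a run-length-compressed, zero-suppressed, sorted bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            vec = track.data[chrom]
            if not len(vec):
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            w = track.bin_width
            size = track.chrom_sizes[chrom]
            for s, e in zip(starts, ends):
                v = vec[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s * w}\t{min(e * w, size)}\t{v:g}\n")


def read_counts(path: str, tissues: Optional[Dict[str, str]] = None
                ) -> CountMatrix:
    """Read a gene x sample counts TSV.

    Column names encode the tissue as ``<tissue>_<replicate>`` unless an
    explicit ``tissues`` mapping is given.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if tissues is None:
        tissues = {c: c.rsplit("_", 1)[0] for c in df.columns}
    return CountMatrix(df, tissues)


def write_counts(cm: CountMatrix, path: str) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_orthologues(path: str) -> pd.DataFrame:
    """Read a 1:1 (two-column) or 1:1:1 (three-column) orthologue TSV.

    Enforces the 1:1 constraint: each gene id appears at most once per
    column.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] not in (2, 3):
        raise ParseError(f"{path}: orthologue table needs 2 or 3 columns")
    for col in df.columns:
        if df[col].duplicated().any():
            raise ParseError(f"{path}: column {col} violates the 1:1 constraint")
    return df


def read_go_mapping(path: str) -> pd.DataFrame:
    """Read a gene -> GO-term TSV: gene_id, term_id, term_name, ontology."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "term_id"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: GO mapping needs columns {sorted(required)}")
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    if "ontology" not in df.columns:
        df["ontology"] = "BP"
    bad = set(df["ontology"]) - {"MF", "BP", "CC"}
    if bad:
        raise ParseError(f"{path}: unknown ontology codes {sorted(bad)}")
    return df


def write_fasta(sequences: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def check_chromosome_consistency(reference: Dict[str, int],
                                 *sets: IntervalSet) -> None:
    """Error loudly when interval sets mention chromosomes absent from
    ``reference`` (verbatim naming — no ``chr`` normalisation)."""
    for iset in sets:
        unknown = set(iset.chroms()) - set(reference)
        if unknown:
            raise ValueError(
                f"chromosomes {sorted(unknown)} not present in reference "
                f"(have {sorted(reference)}); check naming conventions")
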