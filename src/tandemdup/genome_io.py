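"""Reading and writing the formats the duplication pipeline touches.

Annotations come in as Ensembl/GENCODE-dialect GTF and are normalized to
one :class:`GeneModel` per gene with a deduplicated set of exons; coverage
and conservation come in as bedGraph; splice junctions as a plain TSV; the
query-target pair table goes out as BED12 (one line per pair) with a TSV
sidecar carrying alignment statistics.

Internally every coordinate is 0-based half-open (BED convention). GTF is
1-based inclusive and is converted on read.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, merge_intervals

if TYPE_CHECKING:  # pragma: no cover
    from .homology import QueryTargetPair

REGION_CLASSES = ("CDS", "UTR", "mixed", "noncoding")


@dataclass(frozen=True)
class ExonRecord:
    """One unique exon of one gene.

    ``exon_key`` is derived from the coordinates and is unique within the
    gene; the same coordinates appearing under two genes are two records,
    because the homology search runs per parent gene.
    """

    gene_id: str
    interval: GenomicInterval
    region_class: str = "noncoding"

    def __post_init__(self) -> None:
        if self.interval.strand not in "+-":
            raise ValueError("exon must be stranded")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region_class {self.region_class!r}")

    @property
    def exon_key(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"


@dataclass
class GeneModel:
    """A gene: its genomic span, unique exons, and merged CDS intervals."""

    gene_id: str
    interval: GenomicInterval
    exons: list[ExonRecord] = field(default_factory=list)
    cds_intervals: list[GenomicInterval] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def is_coding(self) -> bool:
        return bool(self.cds_intervals)


@dataclass(frozen=True)
class JunctionRecord:
    """A splice junction observed in one tissue.

    ``donor_pos`` and ``acceptor_pos`` are the 0-based first and
    one-past-last intronic positions; ``unique_read_count`` is the number
    of uniquely mapped split reads supporting the junction.
    """

    chrom: str
    donor_pos: int
    acceptor_pos: int
    strand: str
    tissue: str
    unique_read_count: int

    def __post_init__(self) -> None:
        if self.donor_pos == self.acceptor_pos:
            raise ValueError("degenerate junction: donor == acceptor")
        if self.unique_read_count < 0:
            raise ValueError("negative junction read count")


class CoverageTrack:
    """A run-length encoded per-base numeric track (coverage or conservation).

    Positions not covered by any run have value 0. Runs must be
    non-overlapping within a chromosome.
    """

    def __init__(self, label: str = "coverage") -> None:
        self.label = label
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_runs(
        cls,
        runs: Iterable[tuple[str, int, int, float]],
        label: str = "coverage",
    ) -> "CoverageTrack":
        track = cls(label)
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in runs:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping runs on {chrom}")
            if np.any(ends <= starts):
                raise ValueError(f"empty run on {chrom}")
            track._runs[chrom] = (starts, ends, values)
        return track

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._runs.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, float)),
        )

    def value_at(self, chrom: str, pos: int) -> float:
        starts, ends, values = self.runs(chrom)
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def region_sum(self, region: GenomicInterval) -> float:
        """Sum of per-base values over ``region`` (uncovered bases are 0)."""
        starts, ends, values = self.runs(region.chrom)
        if starts.size == 0:
            return 0.0
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], region.start)
        e = np.minimum(ends[lo:hi], region.end)
        return float(np.sum((e - s) * values[lo:hi]))

    def region_mean(self, region: GenomicInterval) -> float:
        """Mean per-base value over ``region``."""
        if len(region) == 0:  # pragma: no cover - constructor forbids
            raise ValueError("zero-length region")
        return self.region_sum(region) / len(region)

    def total(self) -> float:
        return sum(
            float(np.sum((e - s) * v)) for s, e, v in self._runs.values()
        )

    def write_bedgraph(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            for chrom in self.chroms:
                starts, ends, values = self._runs[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# GTF annotation


def read_annotation(
    path: str | Path,
    keep_biotypes: set[str] | None = frozenset({"protein_coding"}),
) -> list[GeneModel]:
    """Parse a GTF file into :class:`GeneModel` objects.

    Only genes whose ``gene_type``/``gene_biotype`` is in ``keep_biotypes``
    are retained (``None`` keeps everything). Exons are deduplicated on
    (chrom, start, end, strand) within each gene and classified as CDS,
    UTR, mixed or noncoding relative to the union of the gene's CDS
    intervals.
    """
    exons_by_gene: dict[str, set[tuple[str, int, int, str]]] = {}
    cds_by_gene: dict[str, list[GenomicInterval]] = {}
    strand_by_gene: dict[str, str] = {}
    biotype_by_gene: dict[str, str] = {}
    order: list[str] = []

    from gffutils.feature import feature_from_line

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: "
                    f"expected 9 tab-separated columns"
                )
            try:
                feat = feature_from_line(line, strict=False)
            except Exception as exc:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: {exc}"
                ) from exc
            feature = feat.featuretype
            if feature not in ("gene", "exon", "CDS"):
                continue
            chrom, strand = feat.seqid, feat.strand
            start, end = feat.start - 1, feat.end  # GTF is 1-based inclusive
            attrs = {k: v[0] for k, v in feat.attributes.items() if v}
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}: GTF line {lineno} lacks gene_id")
            if gene_id not in strand_by_gene:
                strand_by_gene[gene_id] = strand
                order.append(gene_id)
            elif strand != strand_by_gene[gene_id]:
                raise ValueError(
                    f"{path}: line {lineno}: {feature} strand {strand!r} "
                    f"conflicts with gene {gene_id} strand "
                    f"{strand_by_gene[gene_id]!r}"
                )
            biotype = attrs.get("gene_type") or attrs.get("gene_biotype")
            if biotype is not None:
                biotype_by_gene.setdefault(gene_id, biotype)
            if feature == "exon":
                exons_by_gene.setdefault(gene_id, set()).add(
                    (chrom, start, end, strand)
                )
            elif feature == "CDS":
                cds_by_gene.setdefault(gene_id, []).append(
                    GenomicInterval(chrom, start, end, strand)
                )

    genes: list[GeneModel] = []
    for gene_id in order:
        if keep_biotypes is not None:
            biotype = biotype_by_gene.get(gene_id)
            if biotype is not None and biotype not in keep_biotypes:
                continue
        exon_tuples = sorted(exons_by_gene.get(gene_id, set()))
        if not exon_tuples:
            continue
        cds = merge_intervals(cds_by_gene.get(gene_id, []), stranded=True)
        chrom = exon_tuples[0][0]
        strand = strand_by_gene[gene_id]
        span = GenomicInterval(
            chrom,
            min(t[1] for t in exon_tuples),
            max(t[2] for t in exon_tuples),
            strand,
        )
        exons = [
            ExonRecord(
                gene_id,
                GenomicInterval(c, s, e, st),
                classify_region(GenomicInterval(c, s, e, st), cds),
            )
            for (c, s, e, st) in exon_tuples
        ]
        genes.append(GeneModel(gene_id, span, exons, cds))
    return genes


def classify_region(
    exon: GenomicInterval, cds_union: Sequence[GenomicInterval]
) -> str:
    """Classify an exon as CDS/UTR/mixed/noncoding vs the gene's CDS union."""
    if not cds_union:
        return "noncoding"
    covered = sum(exon.overlap_length(c) for c in cds_union)
    if covered == 0:
        return "UTR"
    if covered == len(exon):
        return "CDS"
    return "mixed"


# ---------------------------------------------------------------------------
# bedGraph / BED


def read_coverage(path: str | Path, label: str | None = None) -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack`.

    Overlapping records are an error; positions without a record read as 0.
    """
    runs: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(
                    f"{path}: bedGraph line {lineno}: expected 4 columns"
                )
            runs.append(
                (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
            )
    if label is None:
        label = Path(path).stem
    return CoverageTrack.from_runs(runs, label=label)


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED4/BED6 features (e.g. a repeat track) as intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out


def write_bed6(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Iterable[str] | None = None,
    header: str | None = None,
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        names_it = iter(names) if names is not None else None
        for i, iv in enumerate(intervals):
            name = next(names_it) if names_it is not None else f"region_{i}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# BED12 pair table


def write_pairs_bed12(
    pairs: Sequence["QueryTargetPair"],
    path: str | Path,
    header: str | None = None,
) -> None:
    """Write one BED12 line per query-target pair.

    The line spans the target; blocks are the target-side aligned segments
    (split at alignment gaps); the name encodes gene, exon key and percent
    identity; the score is ``round(10 * identity)`` clamped to [0, 1000].
    """
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for pair in pairs:
            hit = pair.hit
            tgt = hit.target_interval
            blocks = sorted(hit.blocks, key=lambda b: b[0])
            if not blocks:
                raise ValueError("pair has no aligned blocks")
            for bs, be in blocks:
                if bs < tgt.start or be > tgt.end:
                    raise ValueError(
                        f"block [{bs},{be}) outside target "
                        f"[{tgt.start},{tgt.end})"
                    )
            if blocks[0][0] != tgt.start or blocks[-1][1] != tgt.end:
                raise ValueError("blocks must span the target interval")
            sizes = ",".join(str(be - bs) for bs, be in blocks)
            offsets = ",".join(str(bs - tgt.start) for bs, _ in blocks)
            name = f"{pair.query.gene_id}|{pair.query.exon_key}|{hit.identity:.1f}"
            score = max(0, min(1000, round(10 * hit.identity)))
            fh.write(
                "\t".join(
                    [
                        tgt.chrom,
                        str(tgt.start),
                        str(tgt.end),
                        name,
                        str(score),
                        pair.query.interval.strand,
                        str(tgt.start),
                        str(tgt.end),
                        "0",
                        str(len(blocks)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


@dataclass(frozen=True)
class Bed12Record:
    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str
    blocks: tuple[tuple[int, int], ...]


def read_pairs_bed12(path: str | Path) -> list[Bed12Record]:
    """Read a pair table back as plain BED12 records (round-trip check)."""
    out: list[Bed12Record] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            nblocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != nblocks or len(offsets) != nblocks:
                raise ValueError(f"inconsistent block columns in {path}")
            blocks = tuple(
                (start + o, start + o + s) for o, s in zip(offsets, sizes)
            )
            out.append(
                Bed12Record(chrom, start, end, f[3], int(f[4]), f[5], blocks)
            )
    return out


# ---------------------------------------------------------------------------
# Pair TSV sidecar (lossless round-trip of QueryTargetPair)

_PAIR_COLUMNS = [
    "gene_id",
    "exon_key",
    "region_class",
    "chrom",
    "exon_start",
    "exon_end",
    "strand",
    "target_start",
    "target_end",
    "query_start",
    "query_end",
    "identity",
    "matches",
    "aligned_columns",
    "score",
    "is_self",
    "blocks",
]


def write_pairs_table(
    pairs: Sequence["QueryTargetPair"], path: str | Path, header: str | None = None
) -> None:
    """Write the TSV sidecar of the BED12 pair table.

    Round-trips every pair attribute except the column-level alignment
    path (coordinates, blocks, identity components and the self flag all
    survive).
    """
    rows = []
    for p in pairs:
        h = p.hit
        rows.append(
            {
                "gene_id": p.query.gene_id,
                "exon_key": p.query.exon_key,
                "region_class": p.query.region_class,
                "chrom": p.query.interval.chrom,
                "exon_start": p.query.interval.start,
                "exon_end": p.query.interval.end,
                "strand": p.query.interval.strand,
                "target_start": h.target_interval.start,
                "target_end": h.target_interval.end,
                "query_start": h.query_span[0],
                "query_end": h.query_span[1],
                "identity": f"{h.identity:.6f}",
                "matches": h.matches,
                "aligned_columns": h.aligned_columns,
                "score": f"{h.score:g}",
                "is_self": int(p.is_self),
                "blocks": ";".join(f"{bs}-{be}" for bs, be in h.blocks),
            }
        )
    df = pd.DataFrame(rows, columns=_PAIR_COLUMNS)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_pairs_table(path: str | Path) -> list["QueryTargetPair"]:
    """Read the TSV sidecar back into :class:`QueryTargetPair` objects."""
    from .homology import AlignmentHit, QueryTargetPair

    df = pd.read_csv(path, sep="\t", comment="#")
    pairs: list[QueryTargetPair] = []
    for row in df.itertuples(index=False):
        exon = ExonRecord(
            row.gene_id,
            GenomicInterval(
                row.chrom, int(row.exon_start), int(row.exon_end), row.strand
            ),
            row.region_class,
        )
        blocks = tuple(
            tuple(int(x) for x in b.split("-"))
            for b in str(row.blocks).split(";")
            if b
        )
        hit = AlignmentHit(
            query_span=(int(row.query_start), int(row.query_end)),
            target_interval=GenomicInterval(
                row.chrom, int(row.target_start), int(row.target_end), row.strand
            ),
            matches=int(row.matches),
            aligned_columns=int(row.aligned_columns),
            blocks=blocks,  # type: ignore[arg-type]
            score=float(row.score),
        )
        pairs.append(QueryTargetPair(exon, hit, bool(row.is_self)))
    return pairs


# ---------------------------------------------------------------------------
# Junction TSV


def read_junctions(path: str | Path) -> list[JunctionRecord]:
    """Read the 6-column junction table; duplicate (junction, tissue) rows
    have their counts summed."""
    counts: dict[tuple[str, int, int, str, str], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) != 6:
                raise ValueError(
                    f"{path}: junction line {lineno}: expected 6 columns"
                )
            chrom, donor, acceptor, strand, tissue, count = f
            n = int(count)
            if n < 0:
                raise ValueError(
                    f"{path}: junction line {lineno}: negative read count"
                )
            key = (chrom, int(donor), int(acceptor), strand, tissue)
            counts[key] = counts.get(key, 0) + n
    return [
        JunctionRecord(chrom, d, a, s, t, n)
        for (chrom, d, a, s, t), n in sorted(counts.items())
    ]


def write_junctions(
    junctions: Iterable[JunctionRecord], path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for j in junctions:
            fh.write(
                f"{j.chrom}\t{j.donor_pos}\t{j.acceptor_pos}\t{j.strand}"
                f"\t{j.tissue}\t{j.unique_read_count}\n"
            )


# ---------------------------------------------------------------------------
# Genome sequence access


def fetch_sequence(
    genome: Mapping[str, object], chrom: str, start: int, end: int
) -> str:
    """Fetch an uppercase subsequence from a pyfaidx Fasta or a plain dict."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from genome")
    record = genome[chrom]
    if isinstance(record, str):
        return record[start:end].upper()
    # pyfaidx FastaRecord supports slicing to a Sequence with .seq
    piece = record[start:end]
    return str(getattr(piece, "seq", piece)).upper()


def chromosome_length(genome: Mapping[str, object], chrom: str) -> int:
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from genome")
    return len(genome[chrom])
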