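"""Exon-vs-parent-gene homology search.

Each annotated exon (the *query*) is aligned against the sequence of its
parent gene extended in both directions by a fraction of the gene length
(default 15%), in a strand-specific way. Local alignment uses exhaustive
affine-gap dynamic programming (Smith-Waterman semantics, executed by
Biopython's :class:`Bio.Align.PairwiseAligner`); multiple homologous
regions (*targets*) per exon are found by iteratively hard-masking the
footprint of the best hit and re-aligning. Every exon recovers its own
location as a trivial *self-hit* at 100% identity; self-hits are flagged
but retained, because the nucleotide increase ratio is defined with them.

Percent identity is ``100 * matches / aligned_columns`` where
``aligned_columns`` counts match, mismatch and gap columns of the local
alignment. The ambiguity code N scores as a mismatch against everything,
including itself.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import islice
from typing import Iterable, Mapping

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from numba import njit

from .genome_io import (
    ExonRecord,
    GeneModel,
    chromosome_length,
    fetch_sequence,
)
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

_ALPHABET = "ACGTNX"  # X is the hard-mask sentinel
_COMPLEMENT = str.maketrans("ACGTNX", "TGCANX")
_MAX_TIEBREAK_PATHS = 32


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize(seq: str) -> str:
    """Uppercase and collapse non-ACGT symbols to N."""
    seq = seq.upper()
    if all(c in "ACGT" for c in seq):
        return seq
    return "".join(c if c in "ACGTN" else "N" for c in seq)


@dataclass(frozen=True)
class ScoringParams:
    """Affine-gap scoring. A gap of length L costs open + (L-1)*extend."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 12.0
    gap_extend: float = 4.0


@dataclass(frozen=True)
class SearchConfig:
    extension_fraction: float = 0.15
    scoring: ScoringParams = field(default_factory=ScoringParams)
    min_identity: float = 50.0
    min_hit_len: int = 30
    max_hits: int = 20
    max_n_fraction: float = 0.3


@dataclass(frozen=True)
class SearchWindow:
    """The extended parent-gene sequence an exon is searched against.

    ``sequence`` is oriented along the gene strand (reverse-complemented
    for minus-strand genes); ``interval`` is its genomic footprint.
    """

    gene_id: str
    interval: GenomicInterval
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.interval):
            raise ValueError("window sequence length != interval length")

    def window_offsets(self, iv: GenomicInterval) -> tuple[int, int]:
        """Map a genomic sub-interval to offsets in the oriented sequence."""
        if self.interval.strand == "-":
            return self.interval.end - iv.end, self.interval.end - iv.start
        return iv.start - self.interval.start, iv.end - self.interval.start

    def genomic_span(self, start_off: int, end_off: int) -> tuple[int, int]:
        """Map oriented-sequence offsets back to a genomic [start, end)."""
        if self.interval.strand == "-":
            return self.interval.end - end_off, self.interval.end - start_off
        return self.interval.start + start_off, self.interval.start + end_off


@dataclass(frozen=True)
class LocalAlignment:
    """A local alignment in window (oriented-sequence) coordinates.

    ``path`` is the alignment's coordinate trace: breakpoints of
    (target_offset, query_offset); between consecutive breakpoints either
    both offsets advance (aligned columns) or one does (gap columns).
    """

    query_span: tuple[int, int]
    target_span: tuple[int, int]
    matches: int
    aligned_columns: int
    blocks: tuple[tuple[int, int], ...]  # target-side aligned segments
    score: float
    path: tuple[tuple[int, int], ...] = ()

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.aligned_columns


@dataclass(frozen=True)
class AlignmentHit:
    """A homologous region for one query exon, in genomic coordinates.

    ``path`` traces the alignment as (offset within the strand-oriented
    target sequence, offset within the query) breakpoints, so the
    reported statistics can be re-derived column-by-column.
    """

    query_span: tuple[int, int]
    target_interval: GenomicInterval
    matches: int
    aligned_columns: int
    blocks: tuple[tuple[int, int], ...]
    score: float
    path: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.matches > self.aligned_columns:
            raise ValueError("matches exceed aligned columns")

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.aligned_columns


@dataclass(frozen=True)
class QueryTargetPair:
    """One exon (query) paired with one homologous region (target)."""

    query: ExonRecord
    hit: AlignmentHit
    is_self: bool = False


# ---------------------------------------------------------------------------
# Aligner construction


_CODE = np.full(256, 4, dtype=np.int8)  # default: N
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_CODE[ord("X")] = 5


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _score_matrix(params: ScoringParams) -> np.ndarray:
    m = np.full((6, 6), params.mismatch, dtype=np.float64)
    for i in range(4):
        m[i, i] = params.match
    m[5, :] = m[:, 5] = -1e6  # hard-mask sentinel
    return m


@njit(cache=False)
def _sw_best_end(
    w: np.ndarray,
    q: np.ndarray,
    mat: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[float, int]:
    """Affine-gap Smith-Waterman scan: best local score and the smallest
    window offset at which an optimal alignment ends. A gap of length L
    costs gap_open + (L-1)*gap_extend."""
    n = w.shape[0]
    m = q.shape[0]
    neg = -1e18
    h_prev = np.zeros(m + 1)
    d_prev = np.full(m + 1, neg)
    h_cur = np.zeros(m + 1)
    d_cur = np.full(m + 1, neg)
    best = 0.0
    best_end = 0
    for i in range(1, n + 1):
        h_cur[0] = 0.0
        ins = neg
        wc = w[i - 1]
        for j in range(1, m + 1):
            d = max(h_prev[j] - gap_open, d_prev[j] - gap_extend)
            ins = max(h_cur[j - 1] - gap_open, ins - gap_extend)
            h = h_prev[j - 1] + mat[wc, q[j - 1]]
            if d > h:
                h = d
            if ins > h:
                h = ins
            if h < 0.0:
                h = 0.0
            h_cur[j] = h
            d_cur[j] = d
            if h > best:
                best = h
                best_end = i
        h_prev, h_cur = h_cur, h_prev
        d_prev, d_cur = d_cur, d_prev
    return best, best_end


def make_aligner(params: ScoringParams) -> Align.PairwiseAligner:
    n = len(_ALPHABET)
    m = np.full((n, n), params.mismatch, dtype=float)
    for i, b in enumerate("ACGT"):
        m[i, i] = params.match
    # the mask sentinel must never appear inside an aligned column
    m[5, :] = m[:, 5] = -1e6
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.Array(
        alphabet=_ALPHABET, dims=2, data=m
    )
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _walk_alignment(
    coords: np.ndarray, window_seq: str, query_seq: str
) -> tuple[int, int, tuple[tuple[int, int], ...]]:
    """Count matches and columns and extract target-side aligned blocks
    from a Biopython coordinate path (target row first)."""
    tc, qc = coords[0], coords[1]
    matches = 0
    columns = 0
    blocks: list[list[int]] = []
    for i in range(len(tc) - 1):
        dt = int(tc[i + 1] - tc[i])
        dq = int(qc[i + 1] - qc[i])
        if dt > 0 and dq > 0:  # aligned segment (dt == dq)
            t_seg = window_seq[tc[i] : tc[i + 1]]
            q_seg = query_seq[qc[i] : qc[i + 1]]
            matches += sum(
                1 for a, b in zip(t_seg, q_seg) if a == b and a in "ACGT"
            )
            columns += dt
            if blocks and blocks[-1][1] == tc[i]:
                blocks[-1][1] = int(tc[i + 1])
            else:
                blocks.append([int(tc[i]), int(tc[i + 1])])
        else:  # gap columns
            columns += max(dt, dq)
    return matches, columns, tuple((a, b) for a, b in blocks)


_ALIGNER_CACHE: dict[ScoringParams, Align.PairwiseAligner] = {}
_MATRIX_CACHE: dict[ScoringParams, np.ndarray] = {}


def _cached_aligner(params: ScoringParams) -> Align.PairwiseAligner:
    if params not in _ALIGNER_CACHE:
        _ALIGNER_CACHE[params] = make_aligner(params)
        _MATRIX_CACHE[params] = _score_matrix(params)
    return _ALIGNER_CACHE[params]


def local_align(
    query_seq: str,
    window_seq: str,
    params: ScoringParams | None = None,
) -> LocalAlignment | None:
    """Best local alignment of ``query_seq`` within ``window_seq``.

    Exhaustive affine-gap dynamic programming over the full window; a
    fast score/endpoint scan locates the optimum and the traceback is
    recovered exactly on a window crop guaranteed to contain it (an
    optimal local alignment of an m-nt query spans at most 2.25 m of the
    target under this scoring). Returns ``None`` when no positive-scoring
    alignment exists. Ties on score break deterministically: earliest
    optimal end offset, then smallest target start, then fewest columns
    (up to 32 co-optimal traceback paths examined).
    """
    if not query_seq or not window_seq:
        raise ValueError("empty sequence")
    params = params or ScoringParams()
    aligner = _cached_aligner(params)
    query_seq = sanitize(query_seq)
    window_clean = sanitize(window_seq) if "X" not in window_seq else window_seq

    best_score, best_end = _sw_best_end(
        _encode(window_clean),
        _encode(query_seq),
        _MATRIX_CACHE[params],
        params.gap_open,
        params.gap_extend,
    )
    if best_score <= 0:
        return None
    lo = max(0, best_end - (3 * len(query_seq) + 64))
    crop = window_clean[lo:best_end]
    result = aligner.align(crop, query_seq)
    if len(result) == 0 or result.score <= 0:  # pragma: no cover - guarded
        return None

    best: LocalAlignment | None = None
    best_key = None
    for aln in islice(result, _MAX_TIEBREAK_PATHS):
        coords = aln.coordinates
        matches, columns, blocks = _walk_alignment(coords, crop, query_seq)
        if columns == 0:
            continue
        cand = LocalAlignment(
            query_span=(int(coords[1][0]), int(coords[1][-1])),
            target_span=(int(coords[0][0]) + lo, int(coords[0][-1]) + lo),
            matches=matches,
            aligned_columns=columns,
            blocks=tuple((a + lo, b + lo) for a, b in blocks),
            score=float(aln.score),
            path=tuple(
                (int(t) + lo, int(q))
                for t, q in zip(coords[0], coords[1])
            ),
        )
        key = (cand.target_span[0], columns)
        if best is None or key < best_key:
            best, best_key = cand, key
    return best


# ---------------------------------------------------------------------------
# Search operations


def build_search_window(
    gene: GeneModel,
    genome: Mapping[str, object],
    extension_fraction: float = 0.15,
) -> SearchWindow:
    """Extend the gene span by ``extension_fraction`` x gene length on each
    side (rounded down, clipped to the chromosome) and fetch its sequence,
    reverse-complemented for minus-strand genes."""
    if extension_fraction < 0:
        raise ValueError("extension_fraction must be >= 0")
    iv = gene.interval
    chrom_len = chromosome_length(genome, iv.chrom)
    pad = int(extension_fraction * len(iv))
    start = max(0, iv.start - pad)
    end = min(chrom_len, iv.end + pad)
    seq = sanitize(fetch_sequence(genome, iv.chrom, start, end))
    if iv.strand == "-":
        seq = reverse_complement(seq)
    return SearchWindow(
        gene.gene_id, GenomicInterval(iv.chrom, start, end, iv.strand), seq
    )


def find_targets(
    exon: ExonRecord,
    window: SearchWindow,
    params: ScoringParams | None = None,
    min_identity: float = 50.0,
    min_hit_len: int = 30,
    max_hits: int = 20,
) -> list[AlignmentHit]:
    """All homologous regions for one exon within its search window.

    Iterative search: the best local alignment is reported, its target
    footprint hard-masked, and the search repeated until the best hit
    falls below ``min_identity``, spans fewer than ``min_hit_len``
    positions, or ``max_hits`` is reached.
    """
    params = params or ScoringParams()
    q_off, q_end = window.window_offsets(exon.interval)
    if q_off < 0 or q_end > len(window.sequence):
        raise ValueError(
            f"exon {exon.exon_key} outside window of gene {window.gene_id}"
        )
    query_seq = window.sequence[q_off:q_end]
    work = list(window.sequence)
    hits: list[AlignmentHit] = []
    while len(hits) < max_hits:
        aln = local_align(query_seq, "".join(work), params=params)
        if aln is None:
            break
        t0, t1 = aln.target_span
        if aln.identity < min_identity or (t1 - t0) < min_hit_len:
            break
        g_start, g_end = window.genomic_span(t0, t1)
        g_blocks = tuple(
            sorted(window.genomic_span(b0, b1) for b0, b1 in aln.blocks)
        )
        hits.append(
            AlignmentHit(
                query_span=aln.query_span,
                target_interval=GenomicInterval(
                    window.interval.chrom, g_start, g_end, window.interval.strand
                ),
                matches=aln.matches,
                aligned_columns=aln.aligned_columns,
                blocks=g_blocks,
                score=aln.score,
                path=tuple((t - t0, q) for t, q in aln.path),
            )
        )
        work[t0:t1] = "X" * (t1 - t0)
    return hits


def oriented_target_sequence(
    hit: AlignmentHit, genome: Mapping[str, object]
) -> str:
    """The target's sequence oriented along the gene strand, i.e. the
    frame of reference of ``hit.path`` target offsets."""
    iv = hit.target_interval
    seq = sanitize(fetch_sequence(genome, iv.chrom, iv.start, iv.end))
    return reverse_complement(seq) if iv.strand == "-" else seq


def is_self_hit(exon: ExonRecord, hit: AlignmentHit) -> bool:
    """A hit is the exon's own location if target and exon overlap by more
    than 50% of the shorter of the two lengths."""
    ov = exon.interval.overlap_length(hit.target_interval)
    shorter = min(len(exon.interval), len(hit.target_interval))
    return ov > 0.5 * shorter


def classify_self_hit(pair: QueryTargetPair) -> bool:
    return is_self_hit(pair.query, pair.hit)


def search_gene(
    gene: GeneModel,
    genome: Mapping[str, object],
    config: SearchConfig | None = None,
) -> list[QueryTargetPair]:
    """Run the homology search for every unique exon of one gene."""
    config = config or SearchConfig()
    window = build_search_window(gene, genome, config.extension_fraction)
    pairs: list[QueryTargetPair] = []
    for exon in sorted(gene.exons, key=lambda e: (e.interval.start, e.interval.end)):
        iv = exon.interval
        if iv.start < gene.interval.start or iv.end > gene.interval.end:
            logger.warning(
                "exon %s outside span of gene %s; skipped", exon.exon_key, gene.gene_id
            )
            continue
        q_off, q_end = window.window_offsets(iv)
        seq = window.sequence[q_off:q_end]
        if seq.count("N") > config.max_n_fraction * len(seq):
            logger.warning(
                "exon %s of gene %s is >%d%% N; skipped",
                exon.exon_key,
                gene.gene_id,
                int(100 * config.max_n_fraction),
            )
            continue
        hits = find_targets(
            exon,
            window,
            params=config.scoring,
            min_identity=config.min_identity,
            min_hit_len=config.min_hit_len,
            max_hits=config.max_hits,
        )
        for hit in hits:
            pairs.append(QueryTargetPair(exon, hit, is_self_hit(exon, hit)))
    return pairs


def run_search(
    genes: Iterable[GeneModel],
    genome: Mapping[str, object],
    config: SearchConfig | None = None,
    n_jobs: int = 1,
) -> list[QueryTargetPair]:
    """Search every (gene, unique exon) once; self-hits are flagged and
    retained. Output order (and content) is independent of ``n_jobs``:
    genes are processed in input order and results concatenated in that
    order."""
    config = config or SearchConfig()
    genes = list(genes)
    if n_jobs > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=n_jobs) as pool:
            per_gene = list(
                pool.map(lambda g: search_gene(g, genome, config), genes)
            )
    else:
        per_gene = [search_gene(g, genome, config) for g in genes]
    return [p for chunk in per_gene for p in chunk]
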