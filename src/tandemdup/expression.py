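"""Expression and conservation support for candidate duplicated exons.

Each merged unannotated target is paired with a random same-length
control region placed 30 nt upstream or downstream. Per tissue, target
and control are scored (mean per-base read coverage, or total split-read
support) and compared through

    logFC_i = log10(1 + target_i) - log10(1 + control_i),

the per-tissue vector of logFC values is tested for departure from zero
with the two-sided Wilcoxon signed-rank test, and p-values are corrected
across tissues with the Benjamini-Hochberg step-up procedure. The same
paired design compares per-base conservation scores (phastCons-style,
in [0, 1]) between targets and controls.

The signed-rank test drops exact zeros, uses the exact null distribution
(computed by a rank-sum counting recursion that accommodates average
ranks for ties) for n <= 25, and the normal approximation with tie and
continuity corrections above.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome_io import CoverageTrack, JunctionRecord
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

EXACT_N_MAX = 25


@dataclass(frozen=True)
class ControlPair:
    """A candidate target with its matched same-length control region."""

    target: GenomicInterval
    control: GenomicInterval
    side: str  # "upstream" | "downstream"
    offset_nt: int = 30

    def __post_init__(self) -> None:
        if len(self.target) != len(self.control):
            raise ValueError("control length must equal target length")
        gap = (
            self.control.start - self.target.end
            if self.side == "downstream"
            else self.target.start - self.control.end
        )
        if gap != self.offset_nt:
            raise ValueError("control must sit offset_nt away from the target")

    @property
    def region_id(self) -> str:
        t = self.target
        return f"{t.chrom}:{t.start}-{t.end}"


@dataclass(frozen=True)
class RegionTissueScore:
    region_id: str
    tissue: str
    target_value: float
    control_value: float

    @property
    def logfc(self) -> float:
        return logfc_score(self.target_value, self.control_value)


@dataclass(frozen=True)
class TissueTestResult:
    tissue: str
    n: int
    median_logfc: float
    p_value: float
    q_value: float


@dataclass(frozen=True)
class ConservationComparison:
    region_ids: tuple[str, ...]
    differences: tuple[float, ...]  # target mean - control mean, per region
    p_value: float

    @property
    def mean_difference(self) -> float:
        return float(np.mean(self.differences))

    @property
    def median_difference(self) -> float:
        return float(np.median(self.differences))


# ---------------------------------------------------------------------------
# Control matching


def match_control(
    target: GenomicInterval,
    chrom_length: int,
    rng: np.random.Generator,
    offset_nt: int = 30,
) -> ControlPair | None:
    """Pick an upstream/downstream control at random for one target.

    The control has the target's length and sits ``offset_nt`` nucleotides
    away on the drawn side; if that side leaves the chromosome the other
    side is used; if both sides are invalid the target is dropped
    (returns ``None``). Deterministic under a seeded generator.
    """
    length = len(target)
    shift = length + offset_nt
    upstream = (target.start - shift, target.end - shift)
    downstream = (target.start + shift, target.end + shift)

    def valid(span: tuple[int, int]) -> bool:
        return span[0] >= 0 and span[1] <= chrom_length

    first = "upstream" if rng.random() < 0.5 else "downstream"
    order = [first, "downstream" if first == "upstream" else "upstream"]
    for side in order:
        span = upstream if side == "upstream" else downstream
        if valid(span):
            return ControlPair(
                target,
                GenomicInterval(target.chrom, span[0], span[1], target.strand),
                side,
                offset_nt,
            )
    logger.info("target %s:%d-%d dropped: no valid control side",
                target.chrom, target.start, target.end)
    return None


def match_controls(
    targets: Sequence[GenomicInterval],
    chrom_lengths: Mapping[str, int],
    seed: int | np.random.Generator,
    offset_nt: int = 30,
) -> list[ControlPair]:
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = []
    for t in targets:
        pair = match_control(t, chrom_lengths[t.chrom], rng, offset_nt)
        if pair is not None:
            out.append(pair)
    return out


# ---------------------------------------------------------------------------
# Scoring


def region_mean(track: CoverageTrack, region: GenomicInterval) -> float:
    """Mean per-base track value over a region (uncovered bases are 0)."""
    return track.region_mean(region)


def logfc_score(target_value: float, control_value: float) -> float:
    """log10(1 + target) - log10(1 + control)."""
    if target_value < 0 or control_value < 0:
        raise ValueError("coverage/support values must be >= 0")
    return math.log10(1.0 + target_value) - math.log10(1.0 + control_value)


def split_read_support(
    junctions: Iterable[JunctionRecord],
    region: GenomicInterval,
    tissue: str,
) -> int:
    """Total unique split reads whose junction has at least one end
    (donor or acceptor position) inside the region, in one tissue."""
    total = 0
    for j in junctions:
        if j.tissue != tissue or j.chrom != region.chrom:
            continue
        if (
            region.start <= j.donor_pos < region.end
            or region.start <= j.acceptor_pos < region.end
        ):
            total += j.unique_read_count
    return total


def coverage_scores(
    pairs: Sequence[ControlPair],
    tracks: Mapping[str, CoverageTrack],
) -> list[RegionTissueScore]:
    """Mean-coverage scores for every (region, tissue)."""
    out = []
    for tissue in sorted(tracks):
        track = tracks[tissue]
        for cp in pairs:
            out.append(
                RegionTissueScore(
                    cp.region_id,
                    tissue,
                    track.region_mean(cp.target),
                    track.region_mean(cp.control),
                )
            )
    return out


def junction_scores(
    pairs: Sequence[ControlPair],
    junctions: Sequence[JunctionRecord],
    tissues: Sequence[str] | None = None,
) -> list[RegionTissueScore]:
    """Split-read support scores for every (region, tissue)."""
    if tissues is None:
        tissues = sorted({j.tissue for j in junctions})
    out = []
    for tissue in tissues:
        for cp in pairs:
            out.append(
                RegionTissueScore(
                    cp.region_id,
                    tissue,
                    float(split_read_support(junctions, cp.target, tissue)),
                    float(split_read_support(junctions, cp.control, tissue)),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Statistics


def _exact_signed_rank_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for the signed-rank statistic.

    ``ranks2`` are the doubled (hence integer) average ranks of |d|;
    ``w2`` the doubled positive-rank sum. Counts, over all 2^n sign
    assignments, those with min(W+, W-) <= min(w+, w-).
    """
    ranks2 = ranks2.astype(np.int64)
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    m2 = min(w2, total - w2)
    lo = int(math.floor(m2 + 1e-9))
    hi = int(math.ceil(total - m2 - 1e-9))
    p = (counts[: lo + 1].sum() + counts[hi:].sum()) / counts.sum()
    return min(1.0, float(p))


def wilcoxon_signed_rank(differences: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Exact zeros are dropped before ranking. If everything is zero the
    test is undefined and p = 1 is returned with a warning.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one difference")
    d = d[d != 0]
    n = d.size
    if n == 0:
        logger.warning("all differences are zero; signed-rank p set to 1")
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        ranks2 = np.round(2 * ranks)
        return _exact_signed_rank_p(ranks2, 2 * w_plus)
    # normal approximation with tie and continuity corrections
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts**3 - tie_counts) / 48.0).sum()
    )
    if var <= 0:
        return 1.0
    diff = w_plus - mu
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def tissue_panel_test(
    scores: Sequence[RegionTissueScore],
    min_n: int = 20,
) -> list[TissueTestResult]:
    """Per-tissue signed-rank tests of logFC against zero, BH-corrected.

    Tissues contributing fewer than ``min_n`` logFC values are excluded
    (and logged). Results are sorted by ascending p (descending
    significance).
    """
    by_tissue: dict[str, list[float]] = {}
    for s in scores:
        by_tissue.setdefault(s.tissue, []).append(s.logfc)
    tested: list[tuple[str, int, float, float]] = []
    for tissue in sorted(by_tissue):
        values = by_tissue[tissue]
        if len(values) < min_n:
            logger.info(
                "tissue %s excluded: %d logFC values < min_n=%d",
                tissue, len(values), min_n,
            )
            continue
        p = wilcoxon_signed_rank(values)
        tested.append((tissue, len(values), float(np.median(values)), p))
    if not tested:
        logger.warning("no tissue passed the min_n=%d threshold", min_n)
        return []
    q = bh_adjust([t[3] for t in tested])
    results = [
        TissueTestResult(tissue, n, med, p, float(qv))
        for (tissue, n, med, p), qv in zip(tested, q)
    ]
    results.sort(key=lambda r: (r.p_value, r.tissue))
    return results


def conservation_compare(
    track: CoverageTrack,
    pairs: Sequence[ControlPair],
) -> ConservationComparison:
    """Paired comparison of mean conservation over targets vs controls."""
    ids = tuple(cp.region_id for cp in pairs)
    diffs = tuple(
        track.region_mean(cp.target) - track.region_mean(cp.control)
        for cp in pairs
    )
    p = wilcoxon_signed_rank(diffs) if diffs else 1.0
    return ConservationComparison(ids, diffs, p)


# ---------------------------------------------------------------------------
# Reports


def write_scores(
    scores: Sequence[RegionTissueScore], path: str | Path, header: str | None = None
) -> None:
    df = pd.DataFrame(
        {
            "region_id": [s.region_id for s in scores],
            "tissue": [s.tissue for s in scores],
            "target_value": [s.target_value for s in scores],
            "control_value": [s.control_value for s in scores],
            "logfc": [s.logfc for s in scores],
        }
    )
    _write_tsv(df, path, header)


def write_tissue_tests(
    results: Sequence[TissueTestResult], path: str | Path, header: str | None = None
) -> None:
    df = pd.DataFrame(
        {
            "tissue": [r.tissue for r in results],
            "n": [r.n for r in results],
            "median_logfc": [r.median_logfc for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    )
    _write_tsv(df, path, header)


def write_conservation(
    comparison: ConservationComparison, path: str | Path, header: str | None = None
) -> None:
    df = pd.DataFrame(
        {
            "region_id": comparison.region_ids,
            "difference": comparison.differences,
        }
    )
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write(f"# paired signed-rank p = {comparison.p_value:.6g}\n")
        df.to_csv(fh, sep="\t", index=False)


def _write_tsv(df: pd.DataFrame, path: str | Path, header: str | None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)
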