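"""The Nucleotide Increase Ratio (NIR) and its summaries.

NIR measures how much sequence the homology search adds on top of the
annotated exons: it is the number of genomic nucleotides covered by the
union of target regions found at or above an identity threshold, divided
by the number covered by the union of the query exons. Because every
query recovers itself as a 100%-identity self-hit, NIR >= 1 by
construction, with equality exactly when no non-self target adds coverage.

The module provides the global/per-gene/per-class NIR, the NIR-vs-identity
curve, the exon-length-bin profile, and the per-gene frequency
distribution on logarithmic bins.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .homology import QueryTargetPair
from .intervals import union_length

interval_union_length = union_length


@dataclass(frozen=True)
class NIRPoint:
    identity_threshold: float
    query_nt: int
    target_nt: int

    @property
    def nir(self) -> float:
        return self.target_nt / self.query_nt


@dataclass(frozen=True)
class GeneNIR:
    gene_id: str
    point: NIRPoint

    @property
    def nir(self) -> float:
        return self.point.nir


@dataclass(frozen=True)
class LengthBinNIR:
    bin_index: int  # 1-based
    length_range: tuple[float, float]
    n_queries: int
    point: NIRPoint | None  # None marks an empty bin (NIR undefined)

    @property
    def nir(self) -> float:
        return self.point.nir if self.point is not None else math.nan


def _scope_pairs(
    pairs: Sequence[QueryTargetPair],
    gene_id: str | None = None,
    region_class: str | None = None,
) -> list[QueryTargetPair]:
    out = pairs
    if gene_id is not None:
        out = [p for p in out if p.query.gene_id == gene_id]
    if region_class is not None:
        # mixed-class exons belong to neither the CDS nor the UTR scope
        out = [p for p in out if p.query.region_class == region_class]
    return list(out)


def compute_nir(
    pairs: Sequence[QueryTargetPair],
    threshold: float,
    gene_id: str | None = None,
    region_class: str | None = None,
) -> NIRPoint:
    """NIR at one identity threshold over an optional gene/class scope.

    The denominator is the union of all in-scope query exon intervals (it
    does not depend on the threshold); the numerator is the union of
    target intervals of in-scope pairs with identity >= threshold.
    Self-hits qualify at every threshold <= 100.
    """
    scoped = _scope_pairs(pairs, gene_id, region_class)
    queries = {p.query.interval for p in scoped}
    if not queries:
        raise ValueError("empty scope: no query exons")
    query_nt = union_length(queries)
    targets = [
        p.hit.target_interval
        for p in scoped
        if p.is_self or p.hit.identity >= threshold
    ]
    target_nt = union_length(targets)
    return NIRPoint(threshold, query_nt, target_nt)


def nir_curve(
    pairs: Sequence[QueryTargetPair], thresholds: Sequence[float]
) -> list[NIRPoint]:
    """One NIRPoint per threshold; non-increasing in the threshold."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    return [compute_nir(pairs, t) for t in thresholds]


def nir_by_length_bins(
    pairs: Sequence[QueryTargetPair],
    n_bins: int = 10,
    threshold: float = 0.0,
) -> list[LengthBinNIR]:
    """NIR per equal-width exon-length bin spanning [min, max] length.

    Bins partition the length range of all query exons; each query falls
    in exactly one bin (the top edge closes the last bin). Each bin's
    NIR uses its queries' pairs at the given identity threshold (self-hits
    always qualify). Empty bins are reported with an undefined NIR.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lengths = sorted({len(p.query.interval) for p in pairs})
    if not lengths:
        raise ValueError("no query exons")
    lo, hi = float(lengths[0]), float(lengths[-1])
    if hi == lo:
        edges = [lo, hi]
        n_eff = 1
    else:
        edges = list(np.linspace(lo, hi, n_bins + 1))
        n_eff = n_bins

    def bin_of(length: int) -> int:
        if hi == lo:
            return 0
        i = int((length - lo) / (hi - lo) * n_eff)
        return min(i, n_eff - 1)

    out: list[LengthBinNIR] = []
    for b in range(n_eff):
        in_bin = [p for p in pairs if bin_of(len(p.query.interval)) == b]
        rng = (edges[b], edges[b + 1])
        if not in_bin:
            out.append(LengthBinNIR(b + 1, rng, 0, None))
            continue
        queries = {p.query.interval for p in in_bin}
        targets = [
            p.hit.target_interval
            for p in in_bin
            if p.is_self or p.hit.identity >= threshold
        ]
        point = NIRPoint(
            threshold, union_length(queries), union_length(targets)
        )
        out.append(LengthBinNIR(b + 1, rng, len(queries), point))
    return out


@dataclass
class GeneNIRDistribution:
    threshold: float
    genes: list[GeneNIR]
    bin_edges: np.ndarray
    frequencies: np.ndarray

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "query_nt": [g.point.query_nt for g in self.genes],
                "target_nt": [g.point.target_nt for g in self.genes],
                "nir": [g.nir for g in self.genes],
            }
        )

    def top_genes(self, k: int = 10) -> list[GeneNIR]:
        return sorted(self.genes, key=lambda g: (-g.nir, g.gene_id))[:k]


def gene_nir_distribution(
    pairs: Sequence[QueryTargetPair],
    threshold: float = 80.0,
    n_hist_bins: int = 20,
) -> GeneNIRDistribution:
    """Per-gene NIR at one threshold plus a log-binned frequency histogram.

    The default threshold of 80% identity is the midpoint of the 60-100%
    identity range in which targets are observed.
    """
    gene_ids = sorted({p.query.gene_id for p in pairs})
    genes = [
        GeneNIR(g, compute_nir(pairs, threshold, gene_id=g)) for g in gene_ids
    ]
    values = np.array([g.nir for g in genes])
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:  # degenerate histogram: one bin holding every gene
        edges = np.array([vmin, vmax if vmax > vmin else vmin + 1e-9])
        freqs = np.array([len(genes)])
    else:
        edges = np.logspace(
            math.log10(vmin), math.log10(vmax), n_hist_bins + 1
        )
        edges[0], edges[-1] = vmin, vmax  # guard float drift at the rims
        freqs, edges = np.histogram(values, bins=edges)
    return GeneNIRDistribution(threshold, genes, edges, freqs)


# ---------------------------------------------------------------------------
# Reports


def write_nir_curve(
    points: Iterable[NIRPoint], path: str | Path, header: str | None = None
) -> None:
    df = pd.DataFrame(
        {
            "threshold": [p.identity_threshold for p in points],
            "query_nt": [p.query_nt for p in points],
            "target_nt": [p.target_nt for p in points],
            "nir": [p.nir for p in points],
        }
    )
    _write_tsv(df, path, header)


def write_gene_nir(
    dist: GeneNIRDistribution, path: str | Path, header: str | None = None
) -> None:
    _write_tsv(dist.table(), path, header)


def write_length_bins(
    bins: Iterable[LengthBinNIR], path: str | Path, header: str | None = None
) -> None:
    df = pd.DataFrame(
        {
            "bin": [b.bin_index for b in bins],
            "length_lo": [b.length_range[0] for b in bins],
            "length_hi": [b.length_range[1] for b in bins],
            "n_queries": [b.n_queries for b in bins],
            "nir": [b.nir for b in bins],
        }
    )
    _write_tsv(df, path, header)


def _write_tsv(df: pd.DataFrame, path: str | Path, header: str | None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)


def plot_nir_curve(points: Sequence[NIRPoint], path: str | Path) -> None:
    """NIR as a function of the identity threshold (linear axes)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(
        [p.identity_threshold for p in points],
        [p.nir for p in points],
        marker="o",
    )
    ax.set_xlabel("sequence identity threshold (%)")
    ax.set_ylabel("nucleotide increase ratio")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_gene_nir_hist(dist: GeneNIRDistribution, path: str | Path) -> None:
    """Per-gene NIR frequency distribution on log-log axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = np.sqrt(dist.bin_edges[:-1] * dist.bin_edges[1:])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(centers, dist.frequencies, marker="o", linestyle="none")
    if (dist.frequencies > 0).sum() > 1 and centers[0] > 0:
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel("per-gene NIR")
    ax.set_ylabel("number of genes")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
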