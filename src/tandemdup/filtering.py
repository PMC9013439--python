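"""Nomination of unannotated candidate duplicated exons.

A query-target pair survives filtering when the target is (i) not the
query's own location, (ii) covered by annotated exons for at most 5% of
its length, and (iii) covered by interspersed-repeat/low-complexity
annotation for at most 10% of its length. Both overlap fractions are
measured against the *target's* length and both boundaries are strict
("more than" removes). Surviving targets are merged into disjoint
candidate regions (strand-blind; touching intervals coalesce, matching
``bedtools merge``).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .genome_io import ExonRecord
from .homology import QueryTargetPair
from .intervals import (
    GenomicInterval,
    merge_intervals,
    overlap_fraction,
)

REASONS = ("self", "exon", "repeat")


@dataclass(frozen=True)
class FilterConfig:
    max_exon_overlap_frac: float = 0.05
    max_repeat_overlap_frac: float = 0.10
    drop_self: bool = True
    # True: fractions vs the union of features (a target tiled by many
    # small overlaps is removed); False: vs each feature separately.
    union_overlap: bool = True

    def __post_init__(self) -> None:
        for f in (self.max_exon_overlap_frac, self.max_repeat_overlap_frac):
            if not 0 <= f <= 1:
                raise ValueError("overlap fractions must be in [0, 1]")


@dataclass(frozen=True)
class MergedTarget:
    """A disjoint candidate region with its contributing pairs."""

    interval: GenomicInterval
    contributors: tuple[int, ...]  # indices into the retained-pair list
    max_identity: float


def _features_by_chrom(
    features: Sequence[GenomicInterval],
) -> dict[str, list[GenomicInterval]]:
    by: dict[str, list[GenomicInterval]] = {}
    for iv in features:
        by.setdefault(iv.chrom, []).append(iv)
    return by


def _max_overlap_fraction(
    region: GenomicInterval,
    features: Sequence[GenomicInterval],
    union: bool,
) -> float:
    """Overlap with the union of features, or the max single-feature
    overlap, as a fraction of the region's length."""
    if union:
        return overlap_fraction(region, features)
    best = 0.0
    for iv in features:
        best = max(best, region.overlap_length(iv) / len(region))
    return best


def filter_pairs(
    pairs: Sequence[QueryTargetPair],
    annotated_exons: Sequence[ExonRecord] | Sequence[GenomicInterval],
    repeats: Sequence[GenomicInterval],
    config: FilterConfig | None = None,
) -> tuple[list[QueryTargetPair], list[str | None]]:
    """Apply the self/exon/repeat rules to every pair.

    ``annotated_exons`` should be all unique exons genome-wide, not just
    the parent gene's. Returns the retained pairs and, aligned with the
    *input* order, the first matching rejection reason per pair
    (``self``/``exon``/``repeat``) or ``None`` if retained.
    """
    config = config or FilterConfig()
    exon_ivs = [
        e.interval if isinstance(e, ExonRecord) else e for e in annotated_exons
    ]
    exon_by_chrom = {
        c: merge_intervals(ivs) for c, ivs in _features_by_chrom(exon_ivs).items()
    }
    rep_by_chrom = {
        c: merge_intervals(ivs) for c, ivs in _features_by_chrom(repeats).items()
    }
    retained: list[QueryTargetPair] = []
    reasons: list[str | None] = []
    for pair in pairs:
        tgt = pair.hit.target_interval
        reason: str | None = None
        if config.drop_self and pair.is_self:
            reason = "self"
        elif (
            _max_overlap_fraction(
                tgt, exon_by_chrom.get(tgt.chrom, []), config.union_overlap
            )
            > config.max_exon_overlap_frac
        ):
            reason = "exon"
        elif (
            _max_overlap_fraction(
                tgt, rep_by_chrom.get(tgt.chrom, []), config.union_overlap
            )
            > config.max_repeat_overlap_frac
        ):
            reason = "repeat"
        reasons.append(reason)
        if reason is None:
            retained.append(pair)
    return retained, reasons


def merge_targets(retained: Sequence[QueryTargetPair]) -> list[MergedTarget]:
    """Coalesce retained targets into disjoint merged candidate regions.

    Strand-blind; touching intervals merge. Every retained target's bases
    are covered by exactly one merged region.
    """
    if not retained:
        return []
    merged_ivs = merge_intervals([p.hit.target_interval for p in retained])
    out: list[MergedTarget] = []
    for iv in merged_ivs:
        contrib = tuple(
            i
            for i, p in enumerate(retained)
            if p.hit.target_interval.overlaps(iv)
        )
        max_id = max(retained[i].hit.identity for i in contrib)
        out.append(MergedTarget(iv, contrib, max_id))
    return out


def write_rejection_report(
    pairs: Sequence[QueryTargetPair],
    reasons: Sequence[str | None],
    path: str | Path,
    header: str | None = None,
) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [p.query.gene_id for p in pairs],
            "exon_key": [p.query.exon_key for p in pairs],
            "target_start": [p.hit.target_interval.start for p in pairs],
            "target_end": [p.hit.target_interval.end for p in pairs],
            "identity": [round(p.hit.identity, 3) for p in pairs],
            "status": [
                "retained" if r is None else f"removed:{r}" for r in reasons
            ],
        }
    )
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)
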