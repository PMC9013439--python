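"""Synthetic fixtures with planted tandem exon duplications.

The generator emits a self-contained study system: one chromosome of
multi-exon protein-coding genes on both strands, with mutated copies of
annotated exons planted inside introns (CDS-derived copies) or in the
gene flanks inside the 15% search window (UTR-derived copies), a repeat
annotation (some records deliberately overlapping planted copies so the
repeat filter has true positives), per-tissue read-coverage tracks with
elevated signal over the planted copies in the tissues that "express"
them, splice junctions landing at exon and planted-copy boundaries, and
a conservation track elevated over exons and expressed copies.

A truth manifest records every planted copy (source exon, insertion
site, realized edits, expressing tissues) so recovery, filtering and
expression calls can be checked against ground truth. Everything is a
deterministic function of (config, seed).

Planted copies replace intron/flank sequence in place, so annotation
coordinates never shift; repeat records are annotation-only (the
underlying sequence stays random). Divergence is substitution-only by
default, which keeps the expected percent identity at 100*(1 - p);
short 1-3 nt indels can be switched on per copy.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome_io import (
    CoverageTrack,
    JunctionRecord,
    write_junctions,
)
from .intervals import GenomicInterval

_BASES = np.array(list("ACGT"))


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study system (lengths in nucleotides)."""

    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (60, 240)
    intron_len: tuple[int, int] = (300, 1200)
    intergenic_len: tuple[int, int] = (600, 2000)
    gc_content: float = 0.45
    n_duplications: int = 15
    divergence_levels: tuple[float, ...] = (0.10,)
    indel_prob: float = 0.0
    utr_fraction: float = 0.3
    fraction_outside_window: float = 0.0
    n_repeats: int = 10
    repeat_len: tuple[int, int] = (80, 200)
    frac_copies_repeat_overlap: float = 0.0
    n_tissues: int = 10
    expressed_fraction: float = 0.5
    expressed_tissues: tuple[str, ...] | None = None
    background_rate: float = 1.0
    exon_rate: float = 10.0
    duplicate_rate: float = 5.0
    cons_background: float = 0.1
    cons_conserved: float = 0.8
    junction_rate: float = 20.0
    dup_junction_rate: float = 10.0
    coverage_bin: int = 25
    copy_margin: int = 20  # min distance of a planted copy from intron ends
    extension_fraction: float = 0.15
    chrom_name: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.gc_content,
            self.indel_prob,
            self.utr_fraction,
            self.expressed_fraction,
            self.frac_copies_repeat_overlap,
            self.fraction_outside_window,
            *self.divergence_levels,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for lo, hi in (
            self.exons_per_gene,
            self.exon_len,
            self.intron_len,
            self.intergenic_len,
            self.repeat_len,
        ):
            if not (0 < lo <= hi):
                raise ValueError("ranges must be positive and ordered")

    def tissues(self) -> list[str]:
        return [f"tissue{i:02d}" for i in range(self.n_tissues)]


@dataclass(frozen=True)
class PlantedDuplication:
    dup_id: str
    gene_id: str
    source: GenomicInterval
    insertion: GenomicInterval
    substitution_prob: float
    realized_substitutions: int
    realized_indels: int
    expressed_in: tuple[str, ...]
    source_class: str  # "CDS" | "UTR"
    outside_window: bool = False

    @property
    def expected_identity(self) -> float:
        return 100.0 * (1.0 - self.substitution_prob)


@dataclass
class TruthManifest:
    seed: int
    chrom: str
    chrom_length: int
    duplications: list[PlantedDuplication]
    repeat_overlap_dups: list[str] = field(default_factory=list)
    files: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def enc(o):
            if isinstance(o, GenomicInterval):
                return dataclasses.asdict(o)
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "chrom": self.chrom,
                    "chrom_length": self.chrom_length,
                    "duplications": [enc(d) for d in self.duplications],
                    "repeat_overlap_dups": self.repeat_overlap_dups,
                    "files": self.files,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            raw = json.load(fh)
        dups = []
        for d in raw["duplications"]:
            d = dict(d)
            d["source"] = GenomicInterval(**d["source"])
            d["insertion"] = GenomicInterval(**d["insertion"])
            d["expressed_in"] = tuple(d["expressed_in"])
            dups.append(PlantedDuplication(**d))
        return cls(
            raw["seed"],
            raw["chrom"],
            raw["chrom_length"],
            dups,
            list(raw.get("repeat_overlap_dups", [])),
            dict(raw.get("files", {})),
        )


@dataclass
class _GenePlan:
    gene_id: str
    strand: str
    span: tuple[int, int]
    exons: list[tuple[int, int]]
    introns: list[tuple[int, int]]
    cds: list[tuple[int, int]]


@dataclass
class SimulatedFixture:
    """In-memory synthetic dataset plus its ground truth."""

    config: SimConfig
    genome: dict[str, str]
    gtf_text: str
    repeats: list[GenomicInterval]
    manifest: TruthManifest
    gene_plans: list[_GenePlan]

    @property
    def chrom(self) -> str:
        return self.manifest.chrom


# ---------------------------------------------------------------------------
# Sequence-level operations


def random_sequence(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def mutate_sequence(
    seq: str,
    substitution_prob: float,
    indel_prob: float,
    rng: np.random.Generator,
) -> tuple[str, list[tuple]]:
    """Substitute each base independently (always to a different base) and,
    with probability ``indel_prob`` per copy, apply one short (1-3 nt)
    insertion or deletion. Returns the mutated sequence and the edit
    record (one tuple per edit)."""
    arr = np.array(list(seq))
    edits: list[tuple] = []
    if substitution_prob > 0:
        hit = rng.random(arr.size) < substitution_prob
        for i in np.nonzero(hit)[0]:
            old = arr[i]
            choices = [b for b in "ACGT" if b != old]
            new = choices[rng.integers(0, 3)]
            edits.append(("sub", int(i), str(old), new))
            arr[i] = new
    out = "".join(arr)
    if indel_prob > 0 and rng.random() < indel_prob and len(out) > 10:
        size = int(rng.integers(1, 4))
        pos = int(rng.integers(5, len(out) - 5 - size))
        if rng.random() < 0.5:
            edits.append(("del", pos, out[pos : pos + size]))
            out = out[:pos] + out[pos + size :]
        else:
            ins = random_sequence(size, 0.5, rng)
            edits.append(("ins", pos, ins))
            out = out[:pos] + ins + out[pos:]
    return out, edits


# ---------------------------------------------------------------------------
# Genome simulation


def _plan_genes(config: SimConfig, rng: np.random.Generator) -> tuple[list[_GenePlan], int]:
    cursor = 0
    plans: list[_GenePlan] = []
    for g in range(config.n_genes):
        cursor += int(rng.integers(*_incl(config.intergenic_len)))
        gene_start = cursor
        n_ex = int(rng.integers(*_incl(config.exons_per_gene)))
        exons: list[tuple[int, int]] = []
        introns: list[tuple[int, int]] = []
        for i in range(n_ex):
            el = int(rng.integers(*_incl(config.exon_len)))
            exons.append((cursor, cursor + el))
            cursor += el
            if i < n_ex - 1:
                il = int(rng.integers(*_incl(config.intron_len)))
                introns.append((cursor, cursor + il))
                cursor += il
        strand = "+" if rng.random() < 0.5 else "-"
        # middle exons coding, terminal exons UTR-like
        cds = exons[1:-1] if n_ex >= 3 else []
        plans.append(
            _GenePlan(f"geneS{g:04d}", strand, (gene_start, cursor), exons, introns, cds)
        )
    cursor += int(rng.integers(*_incl(config.intergenic_len)))
    return plans, cursor


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


def _gtf_line(
    chrom: str, feature: str, start: int, end: int, strand: str, attrs: str
) -> str:
    # GTF is 1-based inclusive
    return (
        f"{chrom}\tsim\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
    )


def simulate_genome(config: SimConfig) -> SimulatedFixture:
    """Build the genome, annotation, repeat track and truth manifest."""
    rng = np.random.default_rng([config.seed, 101])
    plans, chrom_len = _plan_genes(config, rng)
    chrom = config.chrom_name
    seq = np.array(list(random_sequence(chrom_len, config.gc_content, rng)))

    # ---- plant duplications -------------------------------------------------
    tissues = config.tissues()
    n_utr = round(config.utr_fraction * config.n_duplications)
    kinds = ["UTR"] * n_utr + ["CDS"] * (config.n_duplications - n_utr)
    n_outside = round(config.fraction_outside_window * config.n_duplications)
    free_introns: list[tuple[int, tuple[int, int]]] = []  # (gene idx, span)
    for gi, plan in enumerate(plans):
        for span in plan.introns:
            free_introns.append((gi, span))
    rng.shuffle(free_introns)

    dups: list[PlantedDuplication] = []
    occupied: list[tuple[int, int]] = []
    div_cycle = list(config.divergence_levels)

    def _expressed(k: int) -> tuple[str, ...]:
        if rng.random() >= config.expressed_fraction:
            return ()
        if config.expressed_tissues is not None:
            return tuple(config.expressed_tissues)
        n_pick = max(1, config.n_tissues // 2)
        picked = rng.choice(config.n_tissues, size=n_pick, replace=False)
        return tuple(tissues[i] for i in sorted(picked))

    for k, kind in enumerate(kinds):
        p_sub = div_cycle[k % len(div_cycle)]
        outside = k < n_outside
        placed = False
        if kind == "CDS":
            while free_introns and not placed:
                gi, (i_start, i_end) = free_introns.pop()
                plan = plans[gi]
                if not plan.cds:
                    continue
                src = plan.cds[int(rng.integers(0, len(plan.cds)))]
                src_seq = "".join(seq[src[0] : src[1]])
                mut, edits = mutate_sequence(
                    src_seq, p_sub, config.indel_prob, rng
                )
                margin = config.copy_margin
                room = (i_end - margin) - (i_start + margin) - len(mut)
                if room < 0:
                    continue
                pos = i_start + margin + int(rng.integers(0, room + 1))
                ins = (pos, pos + len(mut))
                seq[ins[0] : ins[1]] = list(mut)
                occupied.append(ins)
                dups.append(
                    _make_dup(
                        f"dup{k:03d}", plan, chrom, src, ins, p_sub, edits,
                        _expressed(k), "CDS", outside=False,
                    )
                )
                placed = True
        else:  # UTR-derived copy planted into a gene flank inside the window
            order = list(rng.permutation(len(plans)))
            for gi in order:
                plan = plans[gi]
                g0, g1 = plan.span
                pad = int(config.extension_fraction * (g1 - g0))
                term = plan.exons[-1] if plan.strand == "+" else plan.exons[0]
                src_seq = "".join(seq[term[0] : term[1]])
                mut, edits = mutate_sequence(
                    src_seq, p_sub, config.indel_prob, rng
                )
                if outside:
                    lo, hi = g1 + pad + 10, g1 + pad + 10 + len(mut)
                else:
                    lo = g1 + 5
                    hi = g1 + pad - len(mut)
                    if hi <= lo:
                        continue
                    start = lo + int(rng.integers(0, hi - lo + 1))
                    lo, hi = start, start + len(mut)
                if hi > chrom_len:
                    continue
                span_iv = (lo, hi)
                if any(a < span_iv[1] and span_iv[0] < b for a, b in occupied):
                    continue
                # keep out of neighbour genes
                if any(
                    q.span[0] < span_iv[1] and span_iv[0] < q.span[1]
                    for q in plans
                ):
                    continue
                seq[span_iv[0] : span_iv[1]] = list(mut)
                occupied.append(span_iv)
                dups.append(
                    _make_dup(
                        f"dup{k:03d}", plan, chrom, term, span_iv, p_sub,
                        edits, _expressed(k), "UTR", outside=outside,
                    )
                )
                placed = True
                break
        if not placed:
            raise SimulationError(
                f"could not place duplication {k} ({kind}); "
                "geometry too small for the requested insertions"
            )

    # ---- repeats ------------------------------------------------------------
    repeats: list[GenomicInterval] = []
    repeat_overlap_dups: list[str] = []
    n_overlap = round(config.frac_copies_repeat_overlap * len(dups))
    for d in dups[:n_overlap]:
        # cover ~half of the planted copy: well above the 10% threshold
        half = max(1, len(d.insertion) // 2)
        repeats.append(
            GenomicInterval(chrom, d.insertion.start, d.insertion.start + half, ".")
        )
        repeat_overlap_dups.append(d.dup_id)
    tries = 0
    while len(repeats) < n_overlap + config.n_repeats and tries < 10_000:
        tries += 1
        rl = int(rng.integers(*_incl(config.repeat_len)))
        start = int(rng.integers(0, max(1, chrom_len - rl)))
        span = (start, start + rl)
        if any(a < span[1] and span[0] < b for a, b in occupied):
            continue
        # repeats may fall in introns/intergenic; only exon overlap matters
        if any(
            e[0] < span[1] and span[0] < e[1]
            for p in plans
            for e in p.exons
        ):
            continue
        repeats.append(GenomicInterval(chrom, span[0], span[1], "."))

    # ---- GTF ----------------------------------------------------------------
    lines: list[str] = []
    for plan in plans:
        gid = plan.gene_id
        attrs = (
            f'gene_id "{gid}"; gene_type "protein_coding"; '
            f'gene_name "{gid}";'
        )
        lines.append(
            _gtf_line(chrom, "gene", plan.span[0], plan.span[1], plan.strand, attrs)
        )
        tid = f"{gid}.t1"
        tattrs = attrs + f' transcript_id "{tid}";'
        lines.append(
            _gtf_line(chrom, "transcript", plan.span[0], plan.span[1], plan.strand, tattrs)
        )
        for e0, e1 in plan.exons:
            lines.append(_gtf_line(chrom, "exon", e0, e1, plan.strand, tattrs))
        for c0, c1 in plan.cds:
            lines.append(_gtf_line(chrom, "CDS", c0, c1, plan.strand, tattrs))

    manifest = TruthManifest(
        config.seed, chrom, chrom_len, dups, repeat_overlap_dups
    )
    return SimulatedFixture(
        config,
        {chrom: "".join(seq)},
        "".join(lines),
        repeats,
        manifest,
        plans,
    )


def _make_dup(
    dup_id: str,
    plan: _GenePlan,
    chrom: str,
    src: tuple[int, int],
    ins: tuple[int, int],
    p_sub: float,
    edits: list[tuple],
    expressed_in: tuple[str, ...],
    source_class: str,
    outside: bool,
) -> PlantedDuplication:
    return PlantedDuplication(
        dup_id=dup_id,
        gene_id=plan.gene_id,
        source=GenomicInterval(chrom, src[0], src[1], plan.strand),
        insertion=GenomicInterval(chrom, ins[0], ins[1], plan.strand),
        substitution_prob=p_sub,
        realized_substitutions=sum(1 for e in edits if e[0] == "sub"),
        realized_indels=sum(1 for e in edits if e[0] in ("ins", "del")),
        expressed_in=expressed_in,
        source_class=source_class,
        outside_window=outside,
    )


# ---------------------------------------------------------------------------
# Coverage / conservation / junction simulation


def _rate_profile(
    fixture: SimulatedFixture, tissue: str | None
) -> np.ndarray:
    """Per-base expected coverage rate; ``tissue=None`` gives the
    conservation mean profile instead."""
    cfg = fixture.config
    L = fixture.manifest.chrom_length
    if tissue is None:
        prof = np.full(L, cfg.cons_background)
        hi = cfg.cons_conserved
    else:
        prof = np.full(L, cfg.background_rate)
        hi = cfg.exon_rate
    for plan in fixture.gene_plans:
        for e0, e1 in plan.exons:
            prof[e0:e1] = hi
    for d in fixture.manifest.duplications:
        if not d.expressed_in:
            continue
        if tissue is None:
            prof[d.insertion.start : d.insertion.end] = cfg.cons_conserved
        elif tissue in d.expressed_in:
            prof[d.insertion.start : d.insertion.end] = cfg.duplicate_rate
    return prof


def simulate_coverage(
    fixture: SimulatedFixture,
) -> tuple[dict[str, CoverageTrack], CoverageTrack]:
    """Per-tissue read-coverage tracks plus a conservation track.

    Coverage is Poisson noise around a per-base rate profile, drawn per
    fixed-size bin (the bin is just a run; the per-base semantics of the
    track are unchanged). Conservation values are Beta draws around the
    bin's mean profile, clipped to [0, 1].
    """
    cfg = fixture.config
    chrom = fixture.chrom
    L = fixture.manifest.chrom_length
    bin_edges = np.arange(0, L + cfg.coverage_bin, cfg.coverage_bin)
    bin_edges[-1] = min(bin_edges[-1], L)
    if bin_edges[-1] == bin_edges[-2]:
        bin_edges = bin_edges[:-1]
    widths = np.diff(bin_edges)

    tracks: dict[str, CoverageTrack] = {}
    for ti, tissue in enumerate(cfg.tissues()):
        rng = np.random.default_rng([cfg.seed, 202, ti])
        prof = _rate_profile(fixture, tissue)
        bin_rate = np.add.reduceat(prof, bin_edges[:-1])
        values = rng.poisson(bin_rate) / widths
        runs = [
            (chrom, int(bin_edges[i]), int(bin_edges[i + 1]), float(values[i]))
            for i in range(len(widths))
        ]
        tracks[tissue] = CoverageTrack.from_runs(runs, label=tissue)

    rng = np.random.default_rng([cfg.seed, 203])
    prof = _rate_profile(fixture, None)
    bin_mean = np.add.reduceat(prof, bin_edges[:-1]) / widths
    conc = 10.0
    a = np.clip(bin_mean * conc, 1e-3, None)
    b = np.clip((1 - bin_mean) * conc, 1e-3, None)
    values = np.clip(rng.beta(a, b), 0.0, 1.0)
    runs = [
        (chrom, int(bin_edges[i]), int(bin_edges[i + 1]), float(values[i]))
        for i in range(len(widths))
    ]
    conservation = CoverageTrack.from_runs(runs, label="conservation")
    return tracks, conservation


def simulate_junctions(fixture: SimulatedFixture) -> list[JunctionRecord]:
    """Junctions at annotated intron boundaries in every tissue, plus
    junctions into planted copies in their expressing tissues only."""
    cfg = fixture.config
    chrom = fixture.chrom
    rng = np.random.default_rng([cfg.seed, 204])
    out: list[JunctionRecord] = []
    for plan in fixture.gene_plans:
        for i0, i1 in plan.introns:
            for tissue in cfg.tissues():
                n = 1 + int(rng.poisson(cfg.junction_rate))
                out.append(JunctionRecord(chrom, i0, i1, plan.strand, tissue, n))
    for d in fixture.manifest.duplications:
        plan = next(
            p for p in fixture.gene_plans if p.gene_id == d.gene_id
        )
        ins = d.insertion
        # splice from the nearest upstream exon end into the copy, and
        # from the copy end to the nearest downstream exon start
        up_ends = [e1 for _, e1 in plan.exons if e1 <= ins.start]
        down_starts = [e0 for e0, _ in plan.exons if e0 >= ins.end]
        donor = max(up_ends) if up_ends else max(0, ins.start - 200)
        acceptor = min(down_starts) if down_starts else ins.end + 200
        for tissue in d.expressed_in:
            n = 1 + int(rng.poisson(cfg.dup_junction_rate))
            out.append(
                JunctionRecord(chrom, donor, ins.start, plan.strand, tissue, n)
            )
            out.append(
                JunctionRecord(chrom, ins.end, acceptor, plan.strand, tissue, n)
            )
    return out


# ---------------------------------------------------------------------------
# File emission


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            s = genome[chrom]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_fixture(fixture: SimulatedFixture, outdir: str | Path) -> TruthManifest:
    """Write every fixture artifact (FASTA/GTF/BED/bedGraph/TSV/JSON).

    The manifest records file names relative to ``outdir`` so the emitted
    fixture is byte-identical wherever it is written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    write_fasta(fixture.genome, outdir / "genome.fa")
    files["genome"] = "genome.fa"

    (outdir / "annotation.gtf").write_text(fixture.gtf_text)
    files["annotation"] = "annotation.gtf"

    with open(outdir / "repeats.bed", "w") as fh:
        for i, iv in enumerate(fixture.repeats):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\trepeat_{i}\t0\t+\n")
    files["repeats"] = "repeats.bed"

    tracks, conservation = simulate_coverage(fixture)
    covdir = outdir / "coverage"
    covdir.mkdir(exist_ok=True)
    for tissue, track in tracks.items():
        track.write_bedgraph(covdir / f"{tissue}.bedgraph")
        files[f"coverage:{tissue}"] = f"coverage/{tissue}.bedgraph"
    conservation.write_bedgraph(outdir / "conservation.bedgraph")
    files["conservation"] = "conservation.bedgraph"

    write_junctions(simulate_junctions(fixture), outdir / "junctions.tsv")
    files["junctions"] = "junctions.tsv"

    files["manifest"] = "truth.json"
    fixture.manifest.files = files
    fixture.manifest.to_json(outdir / "truth.json")
    return fixture.manifest
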