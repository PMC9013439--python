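"""Stage orchestration: simulate -> search -> nir / filter -> expression.

Each stage is a pure function of (inputs, config, seed); outputs land in
the configured output directory, every report carries a header naming
the tool version and config hash, and a run manifest records input and
output checksums so that reruns can be verified byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .expression import (
    conservation_compare,
    coverage_scores,
    junction_scores,
    match_controls,
    tissue_panel_test,
    write_conservation,
    write_scores,
    write_tissue_tests,
)
from .filtering import (
    FilterConfig,
    filter_pairs,
    merge_targets,
    write_rejection_report,
)
from .genome_io import (
    read_annotation,
    read_bed_intervals,
    read_coverage,
    read_junctions,
    read_pairs_table,
    write_bed6,
    write_pairs_bed12,
    write_pairs_table,
)
from .homology import ScoringParams, SearchConfig, run_search
from .nir import (
    compute_nir,
    gene_nir_distribution,
    nir_by_length_bins,
    nir_curve,
    write_gene_nir,
    write_length_bins,
    write_nir_curve,
)
from .simulate import SimConfig, simulate_genome, write_fixture

logger = logging.getLogger(__name__)

STAGES = ("simulate", "search", "nir", "filter", "expression")


@dataclass
class PipelineConfig:
    """Paths and parameters for a pipeline run.

    Defaults follow the published analysis where it states them: 15%
    window extension, 50% identity cutoff, 5%/10% exon/repeat overlap
    filters, 30-nt control offset, threshold-80 gene-level NIR.
    """

    output_dir: str = "tandemdup_out"
    genome: str | None = None
    annotation: str | None = None
    repeats: str | None = None
    coverage_dir: str | None = None
    junctions: str | None = None
    conservation: str | None = None
    extension_fraction: float = 0.15
    min_identity: float = 50.0
    min_hit_len: int = 30
    max_hits: int = 20
    nir_thresholds: tuple[float, ...] = (50, 60, 70, 80, 90, 100)
    gene_nir_threshold: float = 80.0
    exon_overlap_frac: float = 0.05
    repeat_overlap_frac: float = 0.10
    # expression support is scored on targets with at least this percent
    # identity to their query
    expression_min_identity: float = 80.0
    control_offset: int = 30
    min_n: int = 20
    threads: int = 1
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    # hashing covers the scientific parameters only, so the hash (and the
    # report headers carrying it) is invariant to where files happen to live
    _UNHASHED = frozenset(
        {"output_dir", "genome", "annotation", "repeats", "coverage_dir",
         "junctions", "conservation", "threads"}
    )

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in dataclasses.asdict(self).items()
             if k not in self._UNHASHED},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header(self) -> str:
        return f"tandemdup {__version__} config={self.config_hash()}"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw:
            for key in ("exons_per_gene", "exon_len", "intron_len",
                        "intergenic_len", "repeat_len", "divergence_levels",
                        "expressed_tissues"):
                if key in sim_raw and sim_raw[key] is not None:
                    sim_raw[key] = tuple(sim_raw[key])
            cfg.sim = SimConfig(**sim_raw)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class MissingStageError(RuntimeError):
    pass


def _require(path: str | Path | None, what: str, stage: str) -> Path:
    if path is None or not Path(path).exists():
        raise MissingStageError(
            f"missing {what} ({path}); run the '{stage}' stage first "
            "or point the config at existing inputs"
        )
    return Path(path)


def _record(manifest: dict, stage: str, outputs: list[Path]) -> None:
    manifest.setdefault("stages", {})[stage] = {
        str(p): _sha256(p) for p in outputs if p.is_file()
    }


def run_pipeline(config: PipelineConfig, stages: list[str]) -> dict:
    """Run the requested stages in dependency order; returns the run
    manifest (also written to ``run_manifest.json``)."""
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    stages = [s for s in STAGES if s in stages]
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = config.header()
    manifest: dict = {"version": __version__, "config_hash": config.config_hash()}

    if "simulate" in stages:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        fixture = simulate_genome(sim_cfg)
        write_fixture(fixture, out / "fixture")
        fx = out / "fixture"
        config.genome = str(fx / "genome.fa")
        config.annotation = str(fx / "annotation.gtf")
        config.repeats = str(fx / "repeats.bed")
        config.coverage_dir = str(fx / "coverage")
        config.junctions = str(fx / "junctions.tsv")
        config.conservation = str(fx / "conservation.bedgraph")
        _record(manifest, "simulate", sorted(fx.rglob("*")))
        logger.info("simulate: %d genes, %d planted copies",
                    sim_cfg.n_genes, len(fixture.manifest.duplications))
    elif any(s in stages for s in ("search", "nir", "filter", "expression")):
        # resume: pick up a previously simulated fixture if paths unset
        fx = out / "fixture"
        if config.genome is None and (fx / "genome.fa").exists():
            config.genome = str(fx / "genome.fa")
            config.annotation = str(fx / "annotation.gtf")
            config.repeats = str(fx / "repeats.bed")
            config.coverage_dir = str(fx / "coverage")
            config.junctions = str(fx / "junctions.tsv")
            config.conservation = str(fx / "conservation.bedgraph")

    pairs_tsv = out / "pairs.tsv"
    if "search" in stages:
        import pyfaidx

        genome_path = _require(config.genome, "genome FASTA", "simulate")
        annot_path = _require(config.annotation, "annotation GTF", "simulate")
        genome = pyfaidx.Fasta(str(genome_path))
        genes = read_annotation(annot_path)
        search_cfg = SearchConfig(
            extension_fraction=config.extension_fraction,
            scoring=ScoringParams(),
            min_identity=config.min_identity,
            min_hit_len=config.min_hit_len,
            max_hits=config.max_hits,
        )
        pairs = run_search(genes, genome, search_cfg, n_jobs=config.threads)
        write_pairs_table(pairs, pairs_tsv, header=hdr)
        write_pairs_bed12(pairs, out / "pairs.bed12", header=hdr)
        _record(manifest, "search", [pairs_tsv, out / "pairs.bed12"])
        logger.info("search: %d query-target pairs (%d self)",
                    len(pairs), sum(p.is_self for p in pairs))

    if "nir" in stages:
        _require(pairs_tsv, "pair table", "search")
        pairs = read_pairs_table(pairs_tsv)
        curve = nir_curve(pairs, sorted(config.nir_thresholds))
        write_nir_curve(curve, out / "nir_curve.tsv", header=hdr)
        dist = gene_nir_distribution(pairs, config.gene_nir_threshold)
        write_gene_nir(dist, out / "gene_nir.tsv", header=hdr)
        bins = nir_by_length_bins(pairs, threshold=config.gene_nir_threshold)
        write_length_bins(bins, out / "nir_length_bins.tsv", header=hdr)
        _record(manifest, "nir", [out / "nir_curve.tsv", out / "gene_nir.tsv",
                                  out / "nir_length_bins.tsv"])
        logger.info("nir: global NIR@%.0f = %.4f", config.gene_nir_threshold,
                    compute_nir(pairs, config.gene_nir_threshold).nir)

    merged_bed = out / "merged_targets.bed"
    if "filter" in stages:
        _require(pairs_tsv, "pair table", "search")
        annot_path = _require(config.annotation, "annotation GTF", "simulate")
        pairs = read_pairs_table(pairs_tsv)
        genes = read_annotation(annot_path)
        exons = [e for g in genes for e in g.exons]
        repeats = (
            read_bed_intervals(config.repeats)
            if config.repeats and Path(config.repeats).exists()
            else []
        )
        fcfg = FilterConfig(
            max_exon_overlap_frac=config.exon_overlap_frac,
            max_repeat_overlap_frac=config.repeat_overlap_frac,
        )
        retained, reasons = filter_pairs(pairs, exons, repeats, fcfg)
        merged = merge_targets(retained)
        write_pairs_table(retained, out / "retained_pairs.tsv", header=hdr)
        write_pairs_bed12(retained, out / "retained_pairs.bed12", header=hdr)
        write_rejection_report(pairs, reasons, out / "filter_reasons.tsv",
                               header=hdr)
        write_bed6(
            [m.interval for m in merged],
            merged_bed,
            names=[f"target_{i}|maxid={m.max_identity:.1f}"
                   for i, m in enumerate(merged)],
            header=hdr,
        )
        _record(manifest, "filter", [out / "retained_pairs.tsv",
                                     out / "retained_pairs.bed12",
                                     out / "filter_reasons.tsv", merged_bed])
        logger.info("filter: %d/%d pairs retained, %d merged targets",
                    len(retained), len(pairs), len(merged))

    if "expression" in stages:
        retained_tsv = _require(
            out / "retained_pairs.tsv", "retained pair table", "filter"
        )
        cov_dir = _require(config.coverage_dir, "coverage directory", "simulate")
        # expression support is assessed on the strongly homologous group
        retained = read_pairs_table(retained_tsv)
        strong = [
            p for p in retained
            if p.hit.identity >= config.expression_min_identity
        ]
        merged = [m.interval for m in merge_targets(strong)]
        import pyfaidx

        genome_path = _require(config.genome, "genome FASTA", "simulate")
        genome = pyfaidx.Fasta(str(genome_path))
        chrom_lengths = {c: len(genome[c]) for c in genome.keys()}
        pairs_ctrl = match_controls(
            merged, chrom_lengths, config.seed, config.control_offset
        )
        tracks = {
            p.stem: read_coverage(p)
            for p in sorted(Path(cov_dir).glob("*.bedgraph"))
        }
        cov = coverage_scores(pairs_ctrl, tracks)
        write_scores(cov, out / "coverage_scores.tsv", header=hdr)
        results = tissue_panel_test(cov, min_n=config.min_n)
        write_tissue_tests(results, out / "coverage_tests.tsv", header=hdr)
        outputs = [out / "coverage_scores.tsv", out / "coverage_tests.tsv"]
        if config.junctions and Path(config.junctions).exists():
            jx = read_junctions(config.junctions)
            jscores = junction_scores(pairs_ctrl, jx)
            write_scores(jscores, out / "junction_scores.tsv", header=hdr)
            jresults = tissue_panel_test(jscores, min_n=config.min_n)
            write_tissue_tests(jresults, out / "junction_tests.tsv", header=hdr)
            outputs += [out / "junction_scores.tsv", out / "junction_tests.tsv"]
        if config.conservation and Path(config.conservation).exists():
            cons = read_coverage(config.conservation, label="conservation")
            comparison = conservation_compare(cons, pairs_ctrl)
            write_conservation(comparison, out / "conservation.tsv", header=hdr)
            outputs.append(out / "conservation.tsv")
        _record(manifest, "expression", outputs)
        logger.info("expression: %d regions scored in %d tissues",
                    len(pairs_ctrl), len(tracks))

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
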