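"""Local alignment and iterative homology search."""
import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

import tandemdup as td
from tandemdup.genome_io import ExonRecord, GeneModel
from tandemdup.homology import (
    AlignmentHit,
    ScoringParams,
    SearchConfig,
    SearchWindow,
    build_search_window,
    find_targets,
    is_self_hit,
    local_align,
    oriented_target_sequence,
    reverse_complement,
    run_search,
)
from tandemdup.intervals import GenomicInterval
from tandemdup.simulate import mutate_sequence, random_sequence


def _rescore_path(path, target_seq, query_seq):
    """Independent column-by-column re-scoring of a reported path."""
    matches = columns = 0
    for (t0, q0), (t1, q1) in zip(path, path[1:]):
        dt, dq = t1 - t0, q1 - q0
        if dt and dq:
            assert dt == dq
            for a, b in zip(target_seq[t0:t1], query_seq[q0:q1]):
                columns += 1
                if a == b and a in "ACGT":
                    matches += 1
        else:
            columns += max(dt, dq)
    return matches, columns


def _full_window_oracle(query, window, params=ScoringParams()):
    """Reference: Biopython local alignment over the whole window."""
    m = np.full((5, 5), params.mismatch)
    for i in range(4):
        m[i, i] = params.match
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.Array(
        alphabet="ACGTN", dims=2, data=m
    )
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner.align(window, query).score


class TestLocalAlign:
    def test_identical_sequence_is_100_percent(self):
        seq = random_sequence(60, 0.5, np.random.default_rng(0))
        aln = local_align(seq, seq)
        assert aln.identity == 100.0
        assert aln.blocks == ((0, 60),)
        assert aln.matches == 60 and aln.aligned_columns == 60

    def test_planted_substitutions_recovered(self):
        rng = np.random.default_rng(1)
        q = random_sequence(100, 0.5, rng)
        copy = list(q)
        pos = rng.choice(100, size=10, replace=False)
        for i in pos:
            copy[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[i]]
        window = (
            random_sequence(300, 0.5, rng)
            + "".join(copy)
            + random_sequence(300, 0.5, rng)
        )
        aln = local_align(q, window)
        if aln.aligned_columns == 100:  # optimum trimmed nothing
            assert 88.0 <= aln.identity <= 90.0
        else:
            assert aln.identity >= 90.0 * aln.matches / aln.aligned_columns
        # DP-reported statistics match an independent path re-scoring
        m, c = _rescore_path(
            [(t - aln.target_span[0], qq) for t, qq in aln.path],
            window[aln.target_span[0] : aln.target_span[1]],
            q,
        )
        assert (m, c) == (aln.matches, aln.aligned_columns)

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")
        with pytest.raises(ValueError):
            local_align("ACGT", "")

    def test_score_matches_full_window_dp(self):
        # the crop-based search must reproduce whole-window exhaustive DP
        rng = np.random.default_rng(2)
        for i in range(15):
            q = random_sequence(int(rng.integers(30, 120)), 0.45, rng)
            window = random_sequence(int(rng.integers(200, 2500)), 0.45, rng)
            if i % 3 == 0:  # sometimes embed a diverged copy
                mut, _ = mutate_sequence(q, 0.15, 0.3, rng)
                k = int(rng.integers(0, len(window) - len(mut)))
                window = window[:k] + mut + window[k + len(mut) :]
            aln = local_align(q, window)
            assert aln.score == pytest.approx(_full_window_oracle(q, window))

    def test_n_never_matches(self):
        aln = local_align("ACGTNACGT", "ACGTNACGT")
        assert aln.matches == 8  # the N column is a mismatch against itself


class TestSearchWindow:
    GENOME = {"c1": random_sequence(4000, 0.5, np.random.default_rng(7))}

    def _gene(self, start, end, strand="+"):
        iv = GenomicInterval("c1", start, end, strand)
        exon = ExonRecord("g", GenomicInterval("c1", start, start + 100, strand))
        return GeneModel("g", iv, [exon], [])

    def test_fifteen_percent_extension(self):
        w = build_search_window(self._gene(1000, 2000), self.GENOME, 0.15)
        assert (w.interval.start, w.interval.end) == (850, 2150)

    def test_clipped_at_chromosome_start(self):
        w = build_search_window(self._gene(0, 1000), self.GENOME, 0.15)
        assert (w.interval.start, w.interval.end) == (0, 1150)

    def test_zero_extension_equals_gene_span(self):
        w = build_search_window(self._gene(1000, 2000), self.GENOME, 0.0)
        assert (w.interval.start, w.interval.end) == (1000, 2000)

    def test_missing_chromosome_is_error(self):
        gene = GeneModel(
            "g",
            GenomicInterval("cX", 0, 100, "+"),
            [ExonRecord("g", GenomicInterval("cX", 0, 50, "+"))],
            [],
        )
        with pytest.raises(KeyError):
            build_search_window(gene, self.GENOME)

    def test_minus_strand_sequence_reverse_complemented(self):
        w = build_search_window(self._gene(1000, 2000, "-"), self.GENOME, 0.0)
        assert w.sequence == reverse_complement(self.GENOME["c1"][1000:2000])


def _planted_window(rng, n_copies, divergence, exon_len=100):
    """A plus-strand window with one exon plus n diverged copies; returns
    (window, exon, copy spans)."""
    exon_seq = random_sequence(exon_len, 0.5, rng)
    parts = [random_sequence(200, 0.5, rng), exon_seq]
    spans = []
    cursor = 200 + exon_len
    for _ in range(n_copies):
        gap = random_sequence(150, 0.5, rng)
        mut, _ = mutate_sequence(exon_seq, divergence, 0.0, rng)
        parts += [gap, mut]
        cursor += 150
        spans.append((cursor, cursor + len(mut)))
        cursor += len(mut)
    parts.append(random_sequence(200, 0.5, rng))
    window_seq = "".join(parts)
    window = SearchWindow(
        "g", GenomicInterval("c1", 0, len(window_seq), "+"), window_seq
    )
    exon_iv = GenomicInterval("c1", 200, 200 + exon_len, "+")
    return window, ExonRecord("g", exon_iv), spans


class TestFindTargets:
    def test_self_plus_one_copy(self):
        rng = np.random.default_rng(3)
        window, exon, _ = _planted_window(rng, 1, 0.15)
        # cutoff 70 excludes the short ~50%-identity noise alignments a
        # random window always contains
        hits = find_targets(exon, window, min_identity=70)
        assert len(hits) == 2
        assert hits[0].identity == 100.0
        assert is_self_hit(exon, hits[0])
        assert 75.0 <= hits[1].identity <= 95.0
        assert not is_self_hit(exon, hits[1])

    def test_chance_alignments_stay_below_homolog_regime(self):
        # chance local alignments between unrelated sequences sit in the
        # mid-50s/60s; genuine homologs used downstream sit at >= 80
        rng = np.random.default_rng(4)
        for _ in range(5):
            q = random_sequence(80, 0.5, rng)
            window = random_sequence(1000, 0.5, rng)
            aln = local_align(q, window)
            assert aln is None or aln.identity < 70.0

    def test_three_copies_disjoint_footprints(self):
        rng = np.random.default_rng(5)
        window, exon, spans = _planted_window(rng, 3, 0.05)
        hits = find_targets(exon, window, min_identity=80)
        assert len(hits) == 4
        footprints = sorted(
            (h.target_interval.start, h.target_interval.end) for h in hits
        )
        for (a0, a1), (b0, b1) in zip(footprints, footprints[1:]):
            assert a1 <= b0
        # every planted span is recovered by some hit
        for s, e in spans:
            assert any(
                h.target_interval.start < e and s < h.target_interval.end
                for h in hits
            )

    def test_strand_flip_preserves_genomic_footprints(self):
        rng = np.random.default_rng(6)
        window_p, exon_p, _ = _planted_window(rng, 2, 0.10)
        # same genomic DNA presented as a minus-strand gene
        flipped_seq = reverse_complement(window_p.sequence)
        window_m = SearchWindow(
            "g",
            GenomicInterval("c1", 0, len(flipped_seq), "-"),
            window_p.sequence,  # oriented sequence = revcomp of genome
        )
        genome_m = {"c1": flipped_seq}
        exon_m = ExonRecord(
            "g",
            GenomicInterval(
                "c1",
                len(flipped_seq) - exon_p.interval.end,
                len(flipped_seq) - exon_p.interval.start,
                "-",
            ),
        )
        hits_p = find_targets(exon_p, window_p, min_identity=70)
        hits_m = find_targets(exon_m, window_m, min_identity=70)
        fp_p = sorted(
            (
                len(flipped_seq) - h.target_interval.end,
                len(flipped_seq) - h.target_interval.start,
            )
            for h in hits_p
        )
        fp_m = sorted(
            (h.target_interval.start, h.target_interval.end) for h in hits_m
        )
        assert fp_p == fp_m
        del genome_m


class TestSelfHitRule:
    def _hit(self, start, end):
        return AlignmentHit(
            (0, end - start),
            GenomicInterval("c1", start, end, "+"),
            end - start,
            end - start,
            ((start, end),),
            5.0 * (end - start),
        )

    def test_identical_interval_is_self(self):
        exon = ExonRecord("g", GenomicInterval("c1", 100, 200, "+"))
        assert is_self_hit(exon, self._hit(100, 200))

    def test_distant_target_not_self(self):
        exon = ExonRecord("g", GenomicInterval("c1", 100, 200, "+"))
        assert not is_self_hit(exon, self._hit(2100, 2200))

    def test_ten_percent_overlap_not_self(self):
        exon = ExonRecord("g", GenomicInterval("c1", 100, 200, "+"))
        assert not is_self_hit(exon, self._hit(190, 290))


class TestRunSearch:
    def test_self_hits_only_without_duplications(self):
        from tandemdup.simulate import SimConfig, simulate_genome

        cfg = SimConfig(
            seed=21, n_genes=4, n_duplications=0, exons_per_gene=(3, 4),
            exon_len=(60, 120), intron_len=(200, 400),
        )
        fx = simulate_genome(cfg)
        genes = _genes_from_fixture(fx)
        pairs = run_search(genes, fx.genome, SearchConfig(min_identity=60))
        n_exons = sum(len(g.exons) for g in genes)
        self_pairs = [p for p in pairs if p.is_self]
        assert len(self_pairs) == n_exons
        assert all(p.hit.identity == 100.0 for p in self_pairs)

    def test_planted_copies_recovered(self, base_fixture, genes, searched_pairs):
        nonself = [p for p in searched_pairs if not p.is_self]
        recovered = 0
        inside = [
            d for d in base_fixture.manifest.duplications
            if not d.outside_window
        ]
        for d in inside:
            hit = any(
                p.hit.target_interval.overlap_length(d.insertion)
                > 0.5 * len(d.insertion)
                and p.hit.identity >= 80
                for p in nonself
            )
            recovered += hit
        assert recovered >= 0.9 * len(inside)

    def test_widening_window_never_loses_pairs(self, base_fixture, genes):
        subset = genes[:3]
        narrow = run_search(
            subset, base_fixture.genome, SearchConfig(extension_fraction=0.15)
        )
        wide = run_search(
            subset, base_fixture.genome, SearchConfig(extension_fraction=0.30)
        )
        assert len(wide) >= len(narrow)

    def test_rescoring_reported_paths(self, base_fixture, searched_pairs):
        genome = base_fixture.genome
        for pair in searched_pairs[:300]:
            hit = pair.hit
            tseq = oriented_target_sequence(hit, genome)
            qseq = _query_sequence(pair, genome)
            m, c = _rescore_path(hit.path, tseq, qseq)
            assert (m, c) == (hit.matches, hit.aligned_columns)
            assert hit.identity == pytest.approx(100.0 * m / c)

    def test_thread_count_does_not_change_results(self, base_fixture, genes):
        subset = genes[:3]
        serial = run_search(subset, base_fixture.genome)
        threaded = run_search(subset, base_fixture.genome, n_jobs=3)
        assert serial == threaded


def _genes_from_fixture(fx):
    import tempfile
    from pathlib import Path

    from tandemdup.simulate import write_fixture

    with tempfile.TemporaryDirectory() as d:
        write_fixture(fx, d)
        return td.read_annotation(Path(d) / "annotation.gtf")


def _query_sequence(pair, genome):
    from tandemdup.genome_io import fetch_sequence

    iv = pair.query.interval
    seq = fetch_sequence(genome, iv.chrom, iv.start, iv.end)
    return reverse_complement(seq) if iv.strand == "-" else seq
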