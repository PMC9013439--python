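# Methods

## The detection model

An intra-genic tandem exon duplication leaves a homolog of an annotated
exon near that exon, usually in an intron or in the untranslated
flanks. The pipeline therefore searches each annotated exon only within
its parent gene's neighbourhood: the gene span extended by
`extension_fraction` (default 0.15, i.e. 15% of the gene length,
rounded down and clipped to the chromosome) on each side, on the gene's
strand. Using a fraction rather than a fixed window keeps the search
region proportionate across genomes whose gene lengths differ by orders
of magnitude. Duplications farther away than the window — and all
ectopic (trans) duplications — are invisible by design.

### Alignment

Local alignment is exhaustive affine-gap dynamic programming
(Smith–Waterman semantics). Scoring defaults: match +5, mismatch −4,
gap open 12, gap extend 4, where a gap of length L costs
`open + (L−1)·extend`. Percent identity is defined as
`100 · matches / aligned_columns`, aligned columns counting match,
mismatch **and gap** columns — a conservative choice that penalizes
gappy alignments and is applied consistently everywhere (the identity
of an ungapped self-hit is exactly 100). The ambiguity code `N` scores
as a mismatch against every symbol including itself; exons that are
more than 30% `N` are skipped with a warning.

Implementation detail: a fast score/endpoint scan (numba-compiled DP)
locates the optimum over the full window; the traceback is then
recovered by Biopython's `PairwiseAligner` on a window crop
`[end − (3·|query| + 64), end]`. Under this scoring an optimal local
alignment of an m-nt query spans at most 2.25·m target positions
(every deleted target base costs ≥ 4 while at most m matched columns
contribute ≤ 5m), so the crop provably contains the optimum and the
two-stage procedure is exactly equivalent to whole-window DP (a
property test asserts score equality against whole-window alignment).
Score ties break deterministically: earliest optimal end offset, then
smallest target start, then fewest columns (examining up to 32
co-optimal traceback paths; enumerating all of them can be exponential
for low-complexity sequence).

Multiple hits per exon come from iterative hard-masking: the best hit's
target footprint is replaced by a mask symbol that cannot occur in an
aligned column, and the search repeats until the best alignment falls
below `min_identity` (default 50%), spans fewer than `min_hit_len`
(default 30) target positions, or `max_hits` (default 20) is reached.
The 50% cutoff is intentionally permissive; chance local alignments
between unrelated sequences reach the mid-50s/low-60s percent identity
over short spans under this scoring, so downstream analyses that need
genuine homologs work at the 80% threshold (see below). A hit is a
*self-hit* when its target overlaps the query exon's own location by
more than 50% of the shorter of the two lengths.

### Nucleotide increase ratio

For pairs P and threshold t:

    NIR(t) = union_nt{ target(p) : p ∈ P, identity(p) ≥ t or self(p) }
             ─────────────────────────────────────────────────────────
             union_nt{ query(p) : p ∈ P }

The denominator is threshold-independent and self-hits always qualify,
which yields the construction guarantees NIR ≥ 1 (equality iff no
non-self target adds coverage) and monotone non-increase in t. Scopes:
global, per gene, per region class, per exon-length bin. Exons are
classified CDS/UTR/mixed/noncoding against the union of their gene's
CDS intervals; *mixed* exons (partially coding) are excluded from both
the CDS-only and UTR-only scopes so the two class-restricted values
partition cleanly. Length bins are equal-width on the length axis
spanning [min, max] exon length (default 10 bins; the top edge closes
the last bin; empty bins carry an undefined marker). The per-gene
frequency distribution uses logarithmic histogram bins; the gene-level
default threshold is 80% identity, the midpoint of the 60–100% band in
which genuine targets concentrate.

### Filtering and merging

A pair is removed — first matching reason wins — when it is a self-hit
(`self`), its target overlaps annotated exons by more than 5% of the
**target's** length (`exon`), or overlaps repeat annotation by more
than 10% (`repeat`). Both boundaries are strict (exactly 5%/10% is
retained). Overlap is computed against the union of features, so many
small overlapping features are counted once; a per-feature reading is
available via `FilterConfig(union_overlap=False)`. Retained targets are
merged strand-blind, with touching intervals coalescing (the behaviour
of `bedtools merge`).

### Expression and conservation support

Support is scored on the *strongly homologous* group: merged targets
built from retained pairs with identity ≥ 80%
(`expression_min_identity`). Each target gets one control region of the
same length, offset 30 nt (`control_offset`) up- or downstream, the
side drawn uniformly; if the drawn side leaves the chromosome the other
side is used, and a target with no valid side is dropped with a log
message. Controls are deliberately not screened against exons or
repeats (matching the minimal matched-control design); the simulator's
acceptance fixtures therefore plant copies with enough intronic margin
(`copy_margin`) that controls remain in background sequence.

Per tissue, `logFC_i = log10(1 + target_i) − log10(1 + control_i)`
where the values are mean per-base coverage (uncovered bases count 0)
or, for the junction metric, the summed unique-read counts of junctions
with at least one end (donor or acceptor position) inside the region.
Tissues with fewer than `min_n` (default 20) logFC values are excluded.
The per-tissue vector is tested with the two-sided Wilcoxon signed-rank
test: exact zeros dropped; for n ≤ 25 the exact null is computed by a
rank-sum counting recursion (average ranks for ties are doubled to
integers, and the two-sided p counts sign assignments with
`min(W+, W−)` at or beyond the observed value); for n > 25 the normal
approximation with tie and continuity corrections is used.
Benjamini–Hochberg q-values are computed across the included tissues by
the step-up formula. Conservation uses the identical paired design on
mean per-base scores in [0, 1].

## The synthetic study system

`simulate` builds one chromosome: genes drawn with 4–8 exons of 60–240
nt and introns of 300–1200 nt by default, terminal exons left untranslated
(so CDS and UTR query classes both exist), strands random, intergenic
gaps of 600–2000 nt. Copies of annotated exons are mutated (each base
substituted independently with probability p to a different base —
default p = 0.10, expected identity 90% — optionally with one short
1–3 nt indel per copy) and written in place over intron or flank
sequence, so annotation coordinates never shift and every copy lies
inside its source gene's search window by construction (a config knob
plants a fraction just outside the window to exercise the boundary).
Copies are not annotated in the GTF — they are the unannotated truth
the pipeline must rediscover. Repeat records are annotation-only BED
intervals; a configurable fraction of copies receives an overlapping
repeat covering about half the copy, giving the 10% repeat filter true
positives.

Coverage is Poisson noise around a per-base rate profile — background
1.0, annotated exons 10.0, planted copies 5.0 in their expressing
tissues (a five-fold contrast over background) — drawn per 25-nt bin
(bins are just runs; the track's per-base semantics are unchanged).
Conservation values are Beta draws (concentration 10) around a mean
profile of 0.1 background / 0.8 over exons and expressed copies,
clipped to [0, 1]. Junctions appear at every intron boundary in every
tissue (count 1 + Poisson(20)) and at planted-copy boundaries only in
expressing tissues (1 + Poisson(10)). Everything is a deterministic
function of (config, seed), with independent substreams for genome,
coverage, conservation and junctions.

What the generator does **not** emulate: read-level artifacts
(mappability, multi-mapping ambiguity between near-identical copies,
GC bias), splice-isoform structure beyond one transcript per gene,
overlapping genes, real repeat sequence (repeats are labels, not
low-complexity DNA), and indel-rich divergence. Passing tests therefore
demonstrate the pipeline's correctness and calibration under its own
model, not performance on real tissue RNA-seq, where multi-mapping
between highly identical copies is the dominant confounder.

## Problem sizes and numerical choices

The test suite works at desk scale: a shared ~130-kb fixture (10 genes,
10 copies) for unit and consistency checks; a ~0.9-Mb fixture (90
genes, 50 copies at p = 0.10) for the recovery benchmark, which
recovers ≥ 90% of planted copies at ≥ 80% identity with mean
|identity − 100(1−p)| ≤ 3; a 50-tissue null fixture replicated over 20
coverage seeds for the 1,000-vector type-I calibration of the tissue
test (empirical rejection ≈ 0.04 at nominal 0.05, slightly conservative
due to the continuity correction); and a 10-tissue fixture with five
expressing tissues at the five-fold contrast for the expression-truth
check. Identity-accuracy sweeps at p ∈ {0.05, 0.20} use 150–300-nt
exons because local alignment trims mismatch-dense ends, which biases
reported identity upward by an amount that shrinks with exon length.

Degenerate inputs: empty alignment inputs, zero-length regions, empty
NIR scopes and negative counts raise errors; an all-zero difference
vector yields p = 1 with a warning; a tissue panel where nothing passes
`min_n` returns an empty result with a warning. Reports carry a header
naming the package version and a hash of the scientific parameters
(paths excluded), so reruns of the same configuration are byte-identical
wherever the files live.

## Known limitations

- Only intra-genic duplication is searched; homology to other loci is
  out of scope.
- The iterative-masking hit enumeration can, in principle, bridge a
  masked footprint via a long target gap; footprints are therefore
  guaranteed disjoint only at the aligned-column level.
- The empirical identity floor of chance alignments (~55–65%) differs
  from heuristic aligners; analyses should treat the 50–70% identity
  band as noise-dominated.
- The exact signed-rank branch is O(n · Σranks) per test and switches
  to the normal approximation at n > 25.
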