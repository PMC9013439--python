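# tandemdup

Detection and support scoring of **intra-genic tandem exon duplications**
— exons copied to nearby positions within their own gene, a genomic
configuration associated with mutually exclusive splicing.

The package is aimed at computational biologists who want to quantify
duplicated exonic sequence in an annotated genome and to nominate
unannotated duplicated exons with RNA-seq and conservation support. It
runs on standard inputs (FASTA genome, GTF annotation, BED repeat track,
bedGraph coverage/conservation, a splice-junction TSV) and ships a
synthetic-genome generator with a ground-truth manifest, so the whole
pipeline is testable end-to-end without any downloads.

## Method

1. **Homology search.** Every unique annotated exon (the *query*) is
   aligned against the sequence of its parent gene extended by 15% of
   the gene length on each side, strand-specifically. Alignment is
   exhaustive local dynamic programming with affine gaps
   (match +5, mismatch −4, gap open 12, gap extend 4); percent identity
   is `100 · matches / columns` with gap columns counted. Multiple
   *targets* per exon are found by iteratively hard-masking the best
   hit's footprint; hits below 50% identity or 30 aligned positions
   stop the iteration. Every exon recovers itself as a *self-hit* at
   100% identity; self-hits are flagged but kept.

2. **Nucleotide Increase Ratio (NIR).** For a set of query-target pairs
   and an identity threshold *t*,

   `NIR(t) = |union of targets with identity ≥ t| / |union of queries|`

   (in nucleotides, self-hits always included). NIR ≥ 1 by construction
   and is non-increasing in *t*; values above 1 measure duplicated
   sequence beyond the annotation. Computed globally, per gene, per
   region class (CDS/UTR) and per exon-length bin.

3. **Filtering.** A target is removed when it is a self-hit, overlaps
   annotated exons by more than 5% of its length, or overlaps
   interspersed-repeat/low-complexity annotation by more than 10%.
   Survivors are merged into disjoint candidate regions.

4. **Expression & conservation support.** Each merged candidate with at
   least 80% identity to its query is paired with a same-length control
   region 30 nt up- or downstream. Per tissue *i*,
   `logFC_i = log10(1 + target_i) − log10(1 + control_i)` of mean read
   coverage (or summed split-read support) is tested against zero with
   the two-sided Wilcoxon signed-rank test, Benjamini–Hochberg-corrected
   across tissues; per-base conservation scores are compared with the
   same paired design.

## Worked example

```python
import tandemdup as td
from tandemdup.nir import nir_curve
from tandemdup.simulate import SimConfig, simulate_genome

fixture = simulate_genome(SimConfig(seed=7, n_genes=8, n_duplications=6))
# ... parse fixture.gtf_text with td.read_annotation, then:
pairs = td.run_search(genes, fixture.genome)
for p in nir_curve(pairs, [50, 60, 70, 80, 90, 100]):
    print(f"{p.identity_threshold:5.0f}   {p.nir:.4f}")
```

prints

```
   50   4.5501
   60   2.7971
   70   1.1978
   80   1.1518
   90   1.1132
  100   1.0000
```

The fixture plants six exon copies at 10% substitution divergence
(expected identity 90%), so the curve sits well above 1 at low
thresholds (chance local alignments), steps down to ≈1.15 at 80% —
the planted duplications — and reaches exactly 1.0 above the highest
observed identity. The full narrative, including filtering and the
per-tissue expression calls, is in `examples/01…05`; each script prints
the numbers it computes and a line on what they mean. A thin CLI
(`tandemdup simulate|search|nir|filter|expression|all`) orchestrates the
same stages over files.

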