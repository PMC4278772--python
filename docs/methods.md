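# Methods

## Overview

`patseq` analyzes poly(A)-tag (PAT-seq) sequencing data: short single-end
cDNA tags whose junction-adjacent end marks the position of mRNA cleavage
and polyadenylation. Two quantities are derived per gene: the distribution
of tag ends over poly(A) sites (site *usage*), compared between samples, and
the total tag count, used as digital gene expression. The package is built
around a four-genotype comparison design (wild type; a polyadenylation-factor
mutant; two complemented lines, one carrying a calmodulin-binding-deficient
protein), but every operation is generic over sample labels.

## Reference database

Tags derive from transcript 3′ ends, so mapping is restricted to annotated
3′-UTRs extended 500 nt downstream (`extension`, default 500), which keeps
sites produced by inefficient transcription termination recoverable.
Records store the reverse complement of the genomic-sense extended UTR, so
tags align in their sequenced orientation; database coordinates run 3′→5′
of the transcript and carry an exact affine map back to the genome
(`db_to_genome`/`genome_to_db` are inverses, property-tested).

Extensions are deliberately *not* truncated at neighboring genes. Overlapping
records are possible; a tag matching two records equally well is reported as
multimapped and excluded from profiles, which resolves the ambiguity at the
read level rather than by altering the stated database construction.

## Tag processing

* **Demultiplexing** assigns a read to the unique barcode within
  `max_mismatch` (default 0, conservative) of its leading bases; equidistant
  ties are unassigned. The partition is exact: every read lands in exactly
  one output set.
* **Trimming** removes the 5′ adapter by prefix match (tolerating one
  substitution), the leftmost full 3′-adapter occurrence (or a read-terminal
  adapter prefix of ≥4 nt), and the oligo-dT remnant: the maximal terminal
  A-run, extended through at most one non-A base. The interruption is only
  bridged when at least two A's flank it on its 5′ side — a lone A there is
  indistinguishable from genuine tag sequence ending in `A` + non-A and is
  kept. The run is stripped only if it contains ≥5 A's (`a_min`),
  separating remnants from genuinely A-rich 3′ sequence. Results shorter
  than `min_len` = 20 nt are discarded. These constants are declared
  defaults; quality-based trimming is out of scope.

## Alignment

Exact k-mer seeding (k = 16) at offsets 0, k, 2k …, followed by full-length
ungapped verification allowing ≤2 substitutions. With 50-nt tags the seed
set covers every alignment with ≤2 errors (pigeonhole), so the mapper is
deterministic and complete within its mismatch budget; there is no gapped or
spliced alignment. A tag maps iff it has a unique lowest-mismatch location.
The cleavage coordinate is the database position of the tag base adjacent to
the removed remnant (the last aligned base). Mapped tags are exported as SAM
against the database sequences.

## Site profiles and the difference metric

Raw cleavage positions are clustered per gene by single linkage with window
`w` = 24 nt (the typical scale of cleavage microheterogeneity); each
cluster's representative is its modal position, and cluster counts divided
by the gene total give the usage vector. Clustering conserves tag mass
(property-tested).

For a two-sample comparison the two cluster sets are matched by re-running
the same single-linkage rule on the pooled representatives, and the
difference is the total-variation distance D = ½ Σ|pᵢ − qᵢ|. D is
symmetric, bounded in [0, 1], zero iff the profiles are identical and 1 iff
they share no site, matching every documented property of the statistic's
range ("low values = little variability", 1.0 the upper limit attainable).
The exact statistic used by the original comparison tool is published
elsewhere and not reproduced here; the total-variation form is this
package's own choice and numerical equality with previously published curves
is not claimed. Float round-off in ½ Σ|pᵢ − qᵢ| is clamped at 1.0.

Genome-wide, genes with ≥ `min_tags` = 10 tags in *both* samples receive a
D value (variance control; the threshold is a declared default), and each
comparison is summarized as a right-continuous ECDF. The pattern screen for
calmodulin-dependent site choice returns genes with D(wt, C30G) ≤ low and
D(oxt6, C30GM) ≤ low but D(wt, C30GM) ≥ high and D(wt, oxt6) ≥ high
(defaults 0.2 / 0.5).

## Expression analysis

Counts are normalized to tags per million within each sample (column sums
exactly 10⁶). Genes are kept iff strictly greater than 5 tpm in at least one
sample; the filter precedes the +1 pseudocount, which precedes the six
ratios wt/oxt6, C30G/oxt6, wt/C30GM, C30G/C30GM, C30GM/oxt6, wt/C30G and
their log₂. "Absolute value of the expression ratio" is read as the
symmetric fold change max(r, 1/r) — ratios of positive tpm cannot be
negative — equivalent to |log₂ r| > log₂(cutoff). The calmodulin-dependence
filter passes a gene iff the four discriminating fold changes exceed the
cutoff (default 2) and the two control fold changes stay below it.

**Bin enrichment.** Per functional bin (gene→bin TSV, many-to-many), a
two-sided Wilcoxon rank-sum test of member genes' log₂ wt/oxt6 ratios
against all non-members: exact null when min(n₁, n₂) ≤ 8 and no ties,
otherwise the normal approximation with average ranks and continuity
correction (delegated to `scipy.stats.mannwhitneyu`; the exact branch is
verified against exhaustive enumeration in the tests). Uncorrected p-values
are the primary output, reported alongside log₁₀(1/p) for plotting; a
Benjamini–Hochberg column is added for convenience and is not part of the
original workflow.

**Proportions test.** The weighted t-type test on per-replicate tag
proportions: each group's proportion is the library-size-weighted mean of
per-replicate proportions; its variance combines the binomial within-library
term p(1−p)/nᵢ with a between-library component estimated by the method of
moments from the weighted dispersion of replicate proportions (clipped at
zero). The statistic (p̂_A − p̂_B)/√(V_A + V_B) is referred to Student's t
with (k_A − 1) + (k_B − 1) degrees of freedom. With one replicate per group
the between-library term is structurally zero and the normal reference is
used; this single-replicate degeneration is a documented limitation. The
exact variance variant used by commercial implementations is unpublished, so
the formula is isolated in one function for substitution.

## Synthetic data generator

The generator emulates such a sequencing experiment and defines the
conditions under which the pipeline is validated:

* **Genome/annotation**: random chromosomes (2 × 250 genes by default) with
  non-overlapping gene slots; 3′-UTRs of 150–350 nt; homopolymer runs capped
  at 4 nt so remnant trimming cannot displace a junction by more than the
  jitter tolerance (internal-priming artifacts are deliberately not
  modeled).
* **Sites**: 1–3 true poly(A) sites per gene inside the UTR or its 500-nt
  extension, ≥60 nt apart; cleavage jitter is a discretized Gaussian
  (σ = 3 nt) truncated to the extended region, mimicking cleavage
  microheterogeneity.
* **Usage truth**: 10% of genes are APA-shifted — the mutant's dominant site
  moves (dominant mass 0.7–0.9), while both transgenic lines carry the
  wild-type vector (the restoration result); an optional fraction of shifted
  genes can be left unrestored in the calmodulin-mutant line to exercise the
  pattern screen (default 0, matching the finding that the screen yields no
  candidates).
* **Expression truth**: relative abundances are lognormal (σ = 1) with a
  floor of 400 expected tpm. The floor encodes the regime of the real
  analysis: at multi-million-tag library depth the >5 tpm expression filter
  admits only genes with tens of tags, so the synthetic gene set stands for
  the post-filter gene universe; without the floor, desk-scale libraries
  would contain genes at ~10 counts whose Poisson noise alone crosses the
  2-fold filter. 2% of genes (drawn from those ≥1000 expected tpm, so the
  spike-ins are detectable) carry the calmodulin-dependent pattern at fold 5
  (half in each direction); all other genes are expressed identically across
  genotypes (control fold 1).
* **Reads**: layout barcode + 5′ adapter + tag (50 nt, ending at the
  jittered site, taken from the reverse-complemented database so it aligns
  sense) + poly(A) remnant (6–14 A) + 3′ adapter; per-gene counts are
  Poisson around genotype means (simplest model consistent with tag
  counting — swap in an overdispersed sampler via `sample_counts` if
  needed); substitution-only errors at rate 0.001; Phred+33 qualities.
  Read length and error profile are declared defaults, not inferred from
  data. Everything is deterministic given the seed.

What passing tests on this generator do *not* show: robustness to indels,
quality degradation, internal priming, PCR duplicates, overdispersed counts,
or annotation errors — none of which the generator produces.

## Validation scales

The end-to-end checks run at deliberate desk scales chosen as the package's
own validation design: 500 genes × 5 samples × 2×10⁵ tags/sample for the
genome-wide restoration structure; 20 seeds × 10⁵ tags/sample for planted
expression recovery; 100 genes × 4 × 5×10⁴ error-free tags for the sequencing
round trip (≥99% of tags recovered to their source gene within 3σ of a true
site). Statistical comparisons between per-gene D distributions use the
paired one-sided Wilcoxon signed-rank over shared genes — the comparisons
are paired by gene, and the paired test retains power at the 10% planted
fraction where an unpaired rank test does not.

## Known limitations

* The profile-difference metric is this package's own formalization of the
  documented behavior, not a reimplementation of the original tool.
* Single-replicate proportions tests reduce to a two-proportion z-test.
* The mapper is exact-substitution only (≤2), suitable for clean short tags;
  real data with indels would need an external aligner feeding the same SAM
  interface.
* Real-data mode takes any 3′-UTR annotation as given (isoform selection is
  the caller's responsibility).
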