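# Methods

## Model and assumptions

The package scores a genome assembly by the number of accurately assembled
genes (AG) from conserved orthogroups and tunes one assembler parameter to
maximize that score. The underlying model of the data is:

* The genome is diploid. A correctly collapsed locus receives the full
  sequencing depth D; when an assembler emits both alleles separately
  (haplotypic duplication), reads split between the two copies and each sees
  ≈ D/2. Genuine paralogue pairs each see ≈ D.
* Per-base depth behaves approximately like a Poisson(D) count at exonic
  positions. Intron depth is untrusted (transposable-element copies
  elsewhere distort it) and never used.
* Genes of conserved orthogroups are reliably detectable; gene prediction
  and HMM scoring are external, and the package consumes their outputs
  (candidate proteins with bitscores and exon intervals).

AG = (genes in single-copy orthogroups) + (genes in multicopy orthogroups
whose mean exonic coverage strictly exceeds `tm_threshold × Cov(S)`), where
Cov(S) is the median over single-copy genes of per-gene median exonic depth.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| `tm_threshold` | 0.75 | fraction of Cov(S) | TM/FM decision point, midway between the expected full-depth and half-depth modes. If depth is Poisson-like the half-depth mode is narrower, so values slightly below 0.75 are defensible; the default keeps the simple midpoint. Values exactly on the threshold are called FM — the conservative direction when hunting duplications. |
| `budget` | 10 | objective evaluations | golden-section search length; the bracket width ends at ((√5−1)/2)^(budget−2) of the interval (≈ 0.0213 at 10). |
| `n` (orthogroups) | 1000 | count | how many of the most conserved orthogroups to use; datasets smaller than n are used whole. |
| search space | Hifiasm `-s`: [0, 1] identity; Flye `max_divergence`: [0.0001, 0.5] log10 | — | log10 for divergence-like parameters so tuning is fine near 0.01% and coarse near 50%. |
| BUSCO-read e-value ceiling | 1e-5 | — | a read counts as gene-associated when it has a translated hit at least this confident. |
| synthetic `depth` | 30.0 | reads/base | routine long-read budget; 3·√30 < 15, so the D and D/2 modes are separated beyond sampling noise. |
| synthetic `gene_length` / `exons_per_gene` / `read_length` | 300 / 2 / 150 | bases | small genes keep fixtures fast while leaving ≥ 150 exonic bases per gene for a stable median. |

## Numerical and procedural choices

* **Coordinates** are 0-based half-open everywhere; BED and PAF are native,
  anything 1-based converts at the parser boundary.
* **Depth** counts primary alignments only; secondaries multi-map across
  duplicated loci and would erase the halved-coverage signal. An alignment
  covers its full target span (no CIGAR walking — irrelevant to a median).
  Medians over an even count take the mean of the two middle values.
* **Cov(S)** is computed from complete genes of S orthogroups only.
  Fragmented genes are identified but contribute neither to Cov(S) nor to
  AG nor to TM/FM means; multicopy means use complete genes only.
* **Completeness length rule:** `protein_length ≥ length_cutoff − 2·length_sigma`
  from the dataset's per-orthogroup mean and sigma. Exact length bounds vary
  between toolchains; this two-sigma rule is the documented default and the
  rule is injectable (`length_rule=`).
* **Conservation ranking** uses plain mean per-position KL divergence (bits)
  against a uniform amino-acid background, ties broken lexicographically by
  orthogroup id. Other tools' null models differ in detail; uniform is
  reproducible and overridable. The dataset split takes the top-n most
  conserved orthogroups as the assembly part and the remainder as the
  testing part, which reproduces the published partition arithmetic.
* **HMMER3 parsing:** emissions are recovered as exp of the negated stored
  values (`*` → exactly 0). Five-decimal storage makes reconstructed rows
  sum to 1 only within ≈ 5e-6, so rows are validated to 1e-3 and then
  renormalized exactly; parsed profiles always satisfy the 1e-6 invariant.
* **Golden-section details:** the search runs on the unit interval and maps
  through the space transform. On *equal* interior values the right
  sub-interval is discarded, biasing plateaus toward smaller parameters
  (for a duplicate-removal knob, the aggressive direction). The optimum is
  the argmax over all evaluated points, ties toward the smaller parameter —
  robust to mild non-unimodality of integer-valued AG. Evaluations are
  memoized on the parameter rounded to 10 significant digits, so exactly
  `budget` objective calls occur and no point is re-run.
* **Degenerate inputs:** AG of an empty orthogroup set is 0; multicopy
  orthogroups without any single-copy gene are an error (Cov(S) undefined);
  a gene counted by AG without a coverage entry is an error naming the gene.

## The synthetic generator and the mock assembler

`synthetic.generate_fixture` materializes a *fixed* assembly outcome: each
gene on its own contig, exons with intron gaps, and alignment records placed
by a homogeneous Poisson process of read starts (a margin keeps coverage
stationary over the gene body). Gene classes are structural — n single-copy
genes at depth D, paralogue pairs at D, false-duplication copies at D/2 —
so truth proportions match the configuration exactly. At least one
single-copy gene is always emitted (the first single doubles as the anchor)
so Cov(S) is defined for every configuration, including pure
false-duplication fixtures.

`backends.mock_assemble` adds the assembler's decision layer: the
aggressiveness knob acts as a similarity threshold, collapsing a
heterozygous locus iff its allele divergence is within the knob and merging
a paralogue pair into a double-depth chimera iff its copy divergence is
within the knob. Worlds with a gap between allele and paralogue divergences
therefore have a truth-optimal aggressiveness plateau, and
`synthetic.expected_ag` gives the noise-free AG for any setting — the oracle
used in optimizer recovery tests.

What the generator does **not** emulate: base-call errors and frameshifts
(candidates arrive pre-scored), mappability and GC biases, transposable
element landscapes, overlapping gene loci, coverage dependence between
genes, and chimeric junctions inside exons. Passing tests demonstrate that
the metric and the optimizer behave correctly *given* alignments and
scored candidates with the assumed depth structure; they do not validate
upstream gene prediction or alignment on real reads.

## Problem sizes used in tests and the acceptance script

Fixtures use 150–300 bp genes at 30× depth. The accuracy suite classifies
1000 synthetic multicopy orthogroups; optimizer recovery runs 100 (tests)
or 50 (acceptance script) seeded worlds of 11 loci with a 10-evaluation
search each; depth calibration averages 200 seeded fixtures. These sizes
give stable statistics (binomial error on a 99% accuracy estimate at
n = 1000 is ≈ 0.3%) while the whole suite runs in well under a minute.

## Known limitations

* Real-assembler backends construct command lines only; the surrounding
  providers (gene prediction, protein-vs-read search, alignment) are
  consumed as files, not orchestrated. Live Flye-mode runs on noisy reads
  would additionally need frameshift-aware polishing of the gene-only
  assemblies, which is out of scope — AG on such assemblies will read low.
* The TM/FM rule assumes a single genome-wide depth; strong regional
  coverage biases (or polyploidy) violate it.
* Orthogroups whose true copy number exceeds two are handled (any size-k
  multicopy orthogroup is classified by its mean), but the synthetic
  generator only produces pairs.
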