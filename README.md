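# agtuner

Gene-accuracy assembly scoring and assembler parameter tuning.

## The problem

When a diploid genome is assembled, the two alleles of a heterozygous locus
are sometimes emitted as two separate sequences instead of being collapsed
into one. These *haplotypic duplications* masquerade as paralogue pairs and
create illusions of gene-family expansions. Standard completeness metrics do
not see them: a BUSCO-style "complete" percentage counts duplicated
orthogroups as complete, and a contiguity metric like N50 rewards improper
joins. `agtuner` is for genome assembly practitioners who want to (a) score
an assembly by how *accurately* its genes are assembled and (b) tune the one
assembler knob that controls duplicate collapsing so that this score is
maximized.

## The AG metric

Candidate genes from conserved orthogroups are classified as complete when
they pass the orthogroup's bitscore cutoff and a minimum-length rule.
Orthogroups fall into the usual categories: single-copy (S), duplicated /
multicopy (D), fragmented (F), missing (M). The key step is splitting D
orthogroups by read coverage. Let Cov(S) be the median over single-copy genes
of each gene's median *exonic* depth (introns are skipped — transposable
elements distort their coverage). A multicopy orthogroup with mean gene
coverage near Cov(S) is **true multicopy** (TM: real paralogues); one near
Cov(S)/2 is **false multicopy** (FM: uncollapsed alleles — each allele gets
half the reads). The decision threshold is

```
TM  ⇔  mean exonic coverage of the orthogroup's genes > 0.75 × Cov(S)
```

and the score is a count of *genes*, not orthogroups:

```
AG = (# genes in S orthogroups) + (# genes in TM orthogroups)
```

Counting genes matters: losing one copy of a paralogue pair merely moves the
orthogroup from TM to S (orthogroup counts unchanged) but loses one real gene
— AG drops by 1.

## Parameter tuning

AG is maximized over a single assembler parameter by a fixed-budget
golden-section search (default 10 objective evaluations, i.e. 10
assemblies). For Hifiasm the knob is `-s` on `[0, 1]` (searched directly);
for Flye it is a coupled `max_divergence` (`assemble_ovlp_divergence` =
`repeat_graph_ovlp_divergence`, relative divergence off, `--no-alt-contigs`)
searched in log10 space over `[0.0001, 0.5]`. The first two probes are the
golden interior points 0.381966 and 0.618034 of the interval; each later
step shrinks the bracket by the inverse golden ratio. The returned optimum
is the best over *all* evaluated points. An in-process mock assembler — a
world of homozygous loci, heterozygous loci and paralogue pairs with known
divergences — lets the whole loop run in seconds and is used throughout the
tests; real assemblers are exposed as pure command constructors in
`agtuner.backends`.

## Worked example

```
$ agtuner simulate --n-single 8 --n-paralog-pairs 3 --n-false-duplications 3 \
      --depth 30 --seed 11 --out demo/fixture
$ agtuner calculate-ag --paf demo/fixture/alignments.paf \
      --candidates demo/fixture/candidates.tsv \
      --cutoffs demo/fixture/cutoffs.tsv --out demo/report
INFO agtuner: C:100.0%[S:57.1%,D:42.9%],F:0.0%,M:0.0%,n:14,AG:14,TM:3,FM:3,Cov(S):30
```

The fixture has 8 single-copy genes, 3 paralogue pairs (full depth 30×) and
3 uncollapsed heterozygous loci (half depth 15×). All 14 orthogroups are
"complete" in BUSCO terms — completeness cannot see the three false
duplications. The coverage step can: 3 orthogroups are called FM and
contribute nothing, so AG = 8 + 3·2 = 14. `demo/report/per_gene.tsv` holds
one row per gene (category, TM/FM call, median exonic depth) — the data
layer for a sinaplot of the two coverage modes:

```
gene_id  orthogroup_id  category  multicopy_class  status    median_exonic_depth
fm0_g1   og_fm0         D         FM               complete  13.5
fm0_g2   og_fm0         D         FM               complete  15.0
```

Tuning against the mock assembler:

```
$ agtuner optimize --seed 11 --out demo/opt
INFO agtuner: best parameter 0.278640 with AG 16 after 10 evaluations
```

`demo/opt/trace.tsv` lists the 10 evaluated (parameter, AG) points, starting
at 0.381966 and 0.618034. The best aggressiveness collapses every
heterozygous locus without merging any paralogue pair, recovering the
maximal AG of 16 (5 homozygous + 5 heterozygous singles + 3×2 paralogues)
for this world.

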