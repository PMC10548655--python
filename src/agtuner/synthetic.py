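"""Synthetic fixtures with the statistical structure the AG metric assumes.

The generator emulates read depth over a diploid genome after assembly:

* a correctly collapsed single-copy gene sees the full sequencing depth D;
* both copies of an uncollapsed heterozygous locus (a haplotypic
  duplication, "false multicopy") split the reads and each sees ~D/2;
* real paralogue pairs ("true multicopy") each see the full depth D.

Reads are materialized as alignment records only — AG consumes depth, not
base calls — placed by a homogeneous Poisson process of read starts, so the
per-base depth at interior positions is Poisson(D). Gene structure (exon
count, intron gaps) is deterministic; the truth-table classes are structural,
not sampled, so class proportions match the config exactly.

At least one single-copy gene is always generated (the first single acts as
the anchor) so that Cov(S) is defined for every configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import InvalidArgumentError
from .formats_io import (
    AlignmentRecord,
    Cutoffs,
    ExonInterval,
    write_cutoffs_tsv,
    write_exon_bed,
    write_paf,
)
from .gene_classes import GeneCandidate, write_candidates_tsv

#: Gene geometry shared by the fixture generator and the mock assembler.
DEFAULT_GENE_LENGTH = 300
DEFAULT_EXONS_PER_GENE = 2
DEFAULT_READ_LENGTH = 150
INTRON_LENGTH = 50

#: Cutoffs every synthetic candidate passes comfortably.
SYNTHETIC_SCORE_CUTOFF = 100.0
SYNTHETIC_BITSCORE = 150.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one fixture.

    ``depth`` defaults to 30x — a routine long-read budget at which the D
    vs D/2 coverage modes are cleanly separated (3*sqrt(30) < 30/2).
    """

    n_single: int = 20
    n_paralog_pairs: int = 5
    n_false_duplication_loci: int = 5
    depth: float = 30.0
    gene_length: int = DEFAULT_GENE_LENGTH
    exons_per_gene: int = DEFAULT_EXONS_PER_GENE
    seed: int = 0
    read_length: int = DEFAULT_READ_LENGTH

    def __post_init__(self):
        if min(self.n_single, self.n_paralog_pairs, self.n_false_duplication_loci) < 0:
            raise InvalidArgumentError("locus counts must be >= 0")
        if self.depth <= 0:
            raise InvalidArgumentError("depth must be > 0")
        if self.exons_per_gene < 1 or self.gene_length < self.exons_per_gene:
            raise InvalidArgumentError("gene_length must be >= exons_per_gene >= 1")


@dataclass(frozen=True)
class TruthRow:
    gene_id: str
    orthogroup_id: str
    true_class: str  # S / TM / FM
    true_depth: float


@dataclass
class Fixture:
    """Everything a full AG computation consumes, plus the ground truth."""

    exons: list[ExonInterval]
    alignments: list[AlignmentRecord]
    candidates: list[GeneCandidate]
    truth: list[TruthRow]
    cutoffs: dict[str, Cutoffs]

    @property
    def orthogroup_ids(self) -> set[str]:
        return set(self.cutoffs)


def sample_alignments(
    rng: np.random.Generator,
    contig_id: str,
    contig_length: int,
    depth: float,
    read_length: int = DEFAULT_READ_LENGTH,
    read_prefix: str = "r",
) -> list[AlignmentRecord]:
    """Poisson-process read placement giving expected per-base depth ``depth``.

    Read starts are uniform on ``[-read_length + 1, contig_length)`` so that
    interior positions are covered by a stationary Poisson(depth) count;
    spans are clipped to the contig.
    """
    window = contig_length + read_length - 1
    n_reads = int(rng.poisson(depth * window / read_length))
    starts = rng.integers(-read_length + 1, contig_length, size=n_reads)
    records = []
    for i, start in enumerate(sorted(starts.tolist())):
        target_start = max(0, start)
        target_end = min(contig_length, start + read_length)
        if target_start >= target_end:
            continue
        records.append(
            AlignmentRecord(
                read_id=f"{read_prefix}{i}",
                read_length=read_length,
                target_id=contig_id,
                target_start=target_start,
                target_end=target_end,
            )
        )
    return records


def gene_exon_layout(
    gene_length: int, exons_per_gene: int, margin: int
) -> tuple[list[tuple[int, int]], int]:
    """Deterministic exon spans (with intron gaps) and the contig length.

    Exons split ``gene_length`` coding bases into equal parts separated by
    fixed-length introns; a margin on both sides keeps the Poisson coverage
    stationary over the gene body.
    """
    exon_length = gene_length // exons_per_gene
    spans = []
    cursor = margin
    for i in range(exons_per_gene):
        length = exon_length if i < exons_per_gene - 1 else gene_length - exon_length * (
            exons_per_gene - 1
        )
        spans.append((cursor, cursor + length))
        cursor += length + INTRON_LENGTH
    contig_length = cursor - INTRON_LENGTH + margin
    return spans, contig_length


def _emit_gene(
    rng: np.random.Generator,
    gene_id: str,
    orthogroup_id: str,
    depth: float,
    config: SyntheticConfig,
) -> tuple[GeneCandidate, list[AlignmentRecord]]:
    margin = config.read_length
    spans, contig_length = gene_exon_layout(
        config.gene_length, config.exons_per_gene, margin
    )
    contig = f"{gene_id}_ctg"
    exons = tuple(
        ExonInterval(contig, start, end, gene_id, orthogroup_id) for start, end in spans
    )
    candidate = GeneCandidate(
        gene_id=gene_id,
        orthogroup_id=orthogroup_id,
        protein_length=max(1, config.gene_length // 3),
        bitscore=SYNTHETIC_BITSCORE,
        exons=exons,
    )
    alignments = sample_alignments(
        rng, contig, contig_length, depth, config.read_length, read_prefix=f"{gene_id}_r"
    )
    return candidate, alignments


def synthetic_cutoffs(orthogroup_id: str, config: SyntheticConfig) -> Cutoffs:
    protein_length = max(1, config.gene_length // 3)
    return Cutoffs(
        orthogroup_id=orthogroup_id,
        score_cutoff=SYNTHETIC_SCORE_CUTOFF,
        length_cutoff=float(protein_length),
        length_sigma=max(1.0, 0.1 * protein_length),
    )


def generate_fixture(config: SyntheticConfig) -> Fixture:
    """Build one deterministic fixture from the config's seed.

    Gene classes are structural: ``max(n_single, 1)`` single-copy genes at
    depth D, each paralogue pair as two genes at depth D, each false
    duplication as two gene copies at depth D/2.
    """
    rng = np.random.default_rng(config.seed)
    fixture = Fixture(exons=[], alignments=[], candidates=[], truth=[], cutoffs={})

    def add_gene(gene_id: str, og: str, depth: float, true_class: str) -> None:
        candidate, alignments = _emit_gene(rng, gene_id, og, depth, config)
        fixture.candidates.append(candidate)
        fixture.exons.extend(candidate.exons)
        fixture.alignments.extend(alignments)
        fixture.truth.append(TruthRow(gene_id, og, true_class, depth))
        if og not in fixture.cutoffs:
            fixture.cutoffs[og] = synthetic_cutoffs(og, config)

    for i in range(max(config.n_single, 1)):
        add_gene(f"s{i}_g1", f"og_s{i}", config.depth, "S")
    for i in range(config.n_paralog_pairs):
        og = f"og_tm{i}"
        add_gene(f"tm{i}_g1", og, config.depth, "TM")
        add_gene(f"tm{i}_g2", og, config.depth, "TM")
    for i in range(config.n_false_duplication_loci):
        og = f"og_fm{i}"
        add_gene(f"fm{i}_g1", og, config.depth / 2.0, "FM")
        add_gene(f"fm{i}_g2", og, config.depth / 2.0, "FM")
    return fixture


def fixture_expected_ag(config: SyntheticConfig) -> int:
    """Noise-free AG of a generated fixture: singles (with the guaranteed
    anchor) plus both genes of every paralogue pair."""
    return max(config.n_single, 1) + 2 * config.n_paralog_pairs


def expected_ag(world, aggressiveness: float) -> int:
    """Noise-free AG oracle for a mock-assembler world.

    Applies the mock's deterministic collapse/merge rules: a heterozygous
    locus contributes 1 when collapsed (divergence <= aggressiveness), else 0
    (both copies are false multicopy); a paralogue pair contributes 2 when
    kept apart, else 1 (merged into a single chimeric gene, which lands in a
    single-copy orthogroup).
    """
    if not 0.0 <= aggressiveness <= 1.0:
        raise InvalidArgumentError(f"aggressiveness {aggressiveness} outside [0, 1]")
    total = 0
    for locus in world.loci:
        if locus.kind == "single":
            total += 1 if locus.haplotype_divergence <= aggressiveness else 0
        else:
            total += 1 if locus.paralog_divergence <= aggressiveness else 2
    return total


def write_fixture(fixture: Fixture, outdir) -> None:
    """Serialize a fixture to plain-text files (BED/PAF/TSV) under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_exon_bed(fixture.exons, out / "exons.bed")
    write_paf(fixture.alignments, out / "alignments.paf")
    write_candidates_tsv(fixture.candidates, out / "candidates.tsv")
    write_cutoffs_tsv(fixture.cutoffs, out / "cutoffs.tsv")
    with open(out / "truth.tsv", "wt", encoding="utf-8") as handle:
        handle.write("gene_id\torthogroup_id\ttrue_class\ttrue_depth\n")
        for row in fixture.truth:
            handle.write(
                f"{row.gene_id}\t{row.orthogroup_id}\t{row.true_class}\t{row.true_depth:g}\n"
            )


# ---------------------------------------------------------------------------
# synthetic orthogroup datasets (for catalog / CLI tests)
# ---------------------------------------------------------------------------


def make_catalog(n_orthogroups: int, seed: int = 0, max_length: int = 3):
    """A synthetic catalog of ``n_orthogroups`` profiles with Dirichlet
    emissions — enough structure for ranking and splitting to be exercised."""
    from .catalog import Catalog, OrthogroupProfile

    if n_orthogroups < 1:
        raise InvalidArgumentError("n_orthogroups must be >= 1")
    rng = np.random.default_rng(seed)
    profiles = {}
    for i in range(n_orthogroups):
        og = f"og{i:05d}"
        length = int(rng.integers(1, max_length + 1))
        emissions = rng.dirichlet(np.ones(20), size=length)
        emissions /= emissions.sum(axis=1, keepdims=True)
        profiles[og] = OrthogroupProfile(
            orthogroup_id=og,
            length=length,
            emissions=emissions,
            score_cutoff=SYNTHETIC_SCORE_CUTOFF,
            length_cutoff=100.0,
            length_sigma=10.0,
        )
    return Catalog(profiles=profiles)


def write_mock_dataset(outdir, n_orthogroups: int, seed: int = 0) -> None:
    """Write a synthetic BUSCO-style dataset directory (synthetic stand-in for
    a real orthogroup dataset): ``hmms/<id>.hmm``, ``ancestral`` FASTA,
    ``scores_cutoff`` and ``lengths_cutoff``."""
    from .formats_io import AMINO_ACIDS, write_hmm_profile

    out = Path(outdir)
    (out / "hmms").mkdir(parents=True, exist_ok=True)
    catalog = make_catalog(n_orthogroups, seed=seed)
    rng = np.random.default_rng(seed + 1)
    with open(out / "ancestral", "wt", encoding="utf-8") as fasta, open(
        out / "scores_cutoff", "wt", encoding="utf-8"
    ) as scores, open(out / "lengths_cutoff", "wt", encoding="utf-8") as lengths:
        for og in sorted(catalog.profiles):
            profile = catalog.profiles[og]
            write_hmm_profile(profile, out / "hmms" / f"{og}.hmm")
            protein = "".join(rng.choice(list(AMINO_ACIDS), size=30))
            fasta.write(f">{og}\n{protein}\n")
            scores.write(f"{og}\t{profile.score_cutoff:g}\n")
            lengths.write(f"{og}\t0\t{profile.length_sigma:g}\t{profile.length_cutoff:g}\n")
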