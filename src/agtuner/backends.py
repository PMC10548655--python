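"""Assembler backends: command construction for real assemblers and an
in-process mock that makes the whole optimization loop testable.

The real-assembler adapters are *pure command constructors* — they never
touch the filesystem or spawn processes. Hifiasm exposes a haplotypic-
duplication aggressiveness knob ``-s`` in [0, 1] (default 0.55; smaller is
more aggressive) and can reuse intermediate files across ``-s`` values, so
the output prefix is fixed per workdir. Flye has no single such knob: two
divergence settings (disjointig construction and repeat-graph merging) are
coupled into one ``max_divergence`` value, searched in log10 space over
[0.0001, 0.5], with ``assemble_divergence_relative=0`` and
``--no-alt-contigs`` always set. During the search Flye-style runs assemble
only the reads with hits to ancestral orthogroup proteins ("BUSCO reads");
the final run uses all reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import PurePosixPath
from typing import Iterable, Sequence

import numpy as np

from .ag_metric import DEFAULT_TM_THRESHOLD, compute_ag_from_components
from .errors import BackendError, InvalidArgumentError
from .formats_io import AlignmentRecord, Cutoffs, ExonInterval, ProteinHit
from .gene_classes import GeneCandidate
from .optimizer import SearchSpace
from .synthetic import (
    DEFAULT_EXONS_PER_GENE,
    DEFAULT_GENE_LENGTH,
    DEFAULT_READ_LENGTH,
    SYNTHETIC_BITSCORE,
    SyntheticConfig,
    _emit_gene,
    synthetic_cutoffs,
)

#: Hifiasm's stock value of ``-s`` (purge-duplicates similarity threshold).
HIFIASM_DEFAULT_S = 0.55

#: Flye divergence settings coupled into ``max_divergence``; a config
#: template rather than hard-coded flags because Flye versions differ in how
#: overrides are spelled.
FLYE_EXTRA_PARAMS_TEMPLATE = (
    "assemble_ovlp_divergence={param},"
    "repeat_graph_ovlp_divergence={param},"
    "assemble_divergence_relative=0"
)

#: Default e-value ceiling for calling a read a "BUSCO read".
BUSCO_READ_EVALUE_CEILING = 1e-5

HIFIASM_SPACE = SearchSpace(0.0, 1.0, "identity")
FLYE_SPACE = SearchSpace(0.0001, 0.5, "log10")
MOCK_SPACE = SearchSpace(0.0, 1.0, "identity")


@dataclass(frozen=True)
class BackendSpec:
    """Declarative description of an assembler backend."""

    name: str
    parameter_name: str
    space: SearchSpace
    mode_flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.name == "hifiasm" and (
            self.space.transform != "identity"
            or (self.space.lower, self.space.upper) != (0.0, 1.0)
        ):
            raise InvalidArgumentError("hifiasm requires the identity space [0, 1]")
        if self.name == "flye" and (
            self.space.transform != "log10"
            or (self.space.lower, self.space.upper) != (0.0001, 0.5)
        ):
            raise InvalidArgumentError("flye requires the log10 space [0.0001, 0.5]")


HIFIASM_BACKEND = BackendSpec("hifiasm", "-s", HIFIASM_SPACE)
FLYE_BACKEND = BackendSpec(
    "flye", "max_divergence", FLYE_SPACE, mode_flags=("--no-alt-contigs",)
)
MOCK_BACKEND = BackendSpec("mock", "aggressiveness", MOCK_SPACE)


def hifiasm_command(
    param: float, reads: Sequence[str] | str, workdir: str
) -> list[str]:
    """Hifiasm argument list for one ``-s`` value.

    The output prefix is a fixed name inside ``workdir`` so intermediate
    files (error-corrected reads, overlaps) are reused across parameter
    values — only the purge step depends on ``-s``.
    """
    if not 0.0 <= param <= 1.0:
        raise InvalidArgumentError(f"-s value {param} outside [0, 1]")
    read_files = [reads] if isinstance(reads, str) else list(reads)
    prefix = str(PurePosixPath(workdir) / "assembly")
    return ["hifiasm", "-o", prefix, "-s", f"{param:g}", *read_files]


def flye_command(
    param: float,
    all_reads: Sequence[str] | str,
    busco_reads: Sequence[str] | str,
    workdir: str,
    final: bool = False,
    read_type: str = "--nano-raw",
) -> list[str]:
    """Flye argument list for one ``max_divergence`` value.

    Both divergence settings are set to ``param`` (with relative divergence
    disabled) through the extra-parameters template, and ``--no-alt-contigs``
    is always present. Search-phase runs (``final=False``) assemble only the
    BUSCO-read subset; the final run assembles all reads.
    """
    if not FLYE_SPACE.lower <= param <= FLYE_SPACE.upper:
        raise InvalidArgumentError(
            f"max_divergence {param} outside [{FLYE_SPACE.lower}, {FLYE_SPACE.upper}]"
        )
    reads = all_reads if final else busco_reads
    read_files = [reads] if isinstance(reads, str) else list(reads)
    outdir = str(PurePosixPath(workdir) / ("final" if final else f"search_{param:.10g}"))
    return [
        "flye",
        read_type,
        *read_files,
        "--out-dir",
        outdir,
        "--no-alt-contigs",
        "--extra-params",
        FLYE_EXTRA_PARAMS_TEMPLATE.format(param=f"{param:.10g}"),
    ]


def select_busco_reads(
    hits: Iterable[ProteinHit],
    read_ids: Iterable[str],
    evalue_ceiling: float = BUSCO_READ_EVALUE_CEILING,
) -> list[str]:
    """Reads with at least one sufficiently confident hit to an ancestral
    orthogroup protein, in the order the read ids were given."""
    qualified = {h.read_id for h in hits if h.evalue <= evalue_ceiling}
    seen: set[str] = set()
    selected = []
    for read_id in read_ids:
        if read_id in qualified and read_id not in seen:
            seen.add(read_id)
            selected.append(read_id)
    return selected


# ---------------------------------------------------------------------------
# mock assembler
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Locus:
    """One locus of a mock diploid genome.

    ``haplotype_divergence`` is the allele-vs-allele divergence; for paralogue
    pairs ``paralog_divergence`` (copy-vs-copy) must exceed it — paralogues
    are by definition more diverged than alleles.
    """

    locus_id: str
    kind: str  # "single" | "paralog_pair"
    haplotype_divergence: float
    paralog_divergence: float | None = None

    def __post_init__(self):
        if self.kind not in ("single", "paralog_pair"):
            raise InvalidArgumentError(f"locus {self.locus_id}: unknown kind {self.kind!r}")
        if not 0.0 <= self.haplotype_divergence <= 1.0:
            raise InvalidArgumentError(
                f"locus {self.locus_id}: haplotype_divergence outside [0, 1]"
            )
        if self.kind == "paralog_pair":
            if self.paralog_divergence is None:
                raise InvalidArgumentError(
                    f"locus {self.locus_id}: paralog pair without paralog_divergence"
                )
            if not 0.0 <= self.paralog_divergence <= 1.0:
                raise InvalidArgumentError(
                    f"locus {self.locus_id}: paralog_divergence outside [0, 1]"
                )
            if self.paralog_divergence <= self.haplotype_divergence:
                raise InvalidArgumentError(
                    f"locus {self.locus_id}: paralog_divergence must exceed "
                    "haplotype_divergence"
                )


@dataclass(frozen=True)
class MockWorld:
    """A mock genome: loci, sequencing depth and the sampling seed."""

    loci: tuple[Locus, ...]
    depth: float = 30.0
    seed: int = 0
    gene_length: int = DEFAULT_GENE_LENGTH
    exons_per_gene: int = DEFAULT_EXONS_PER_GENE
    read_length: int = DEFAULT_READ_LENGTH

    def __post_init__(self):
        object.__setattr__(self, "loci", tuple(self.loci))
        if self.depth <= 0:
            raise InvalidArgumentError("depth must be > 0")


@dataclass
class MockAssembly:
    """What the mock assembler emits for one aggressiveness value."""

    candidates: list[GeneCandidate]
    exons: list[ExonInterval]
    alignments: list[AlignmentRecord]
    cutoffs: dict[str, Cutoffs]
    truth: dict[str, str]  # gene_id -> S / TM / FM / chimera
    locus_outcomes: dict[str, str]  # locus_id -> collapsed/duplicated/separate/merged

    @property
    def orthogroup_ids(self) -> set[str]:
        return set(self.cutoffs)


def mock_assemble(world: MockWorld, aggressiveness: float) -> MockAssembly:
    """Deterministic mock assembly of a world at one aggressiveness setting.

    The aggressiveness knob plays the role of a similarity threshold: any two
    sequences whose divergence is at most ``aggressiveness`` are collapsed
    into one. Hence a heterozygous locus is correctly collapsed iff its
    allele divergence is within the knob (otherwise both alleles are emitted
    at half depth — a haplotypic duplication), and a paralogue pair is
    wrongly merged into one chimeric gene at double depth iff its copy
    divergence is within the knob.
    """
    if not 0.0 <= aggressiveness <= 1.0:
        raise InvalidArgumentError(f"aggressiveness {aggressiveness} outside [0, 1]")
    rng = np.random.default_rng(
        [world.seed & 0x7FFFFFFF, int(round(aggressiveness * 1_000_000_000))]
    )
    config = SyntheticConfig(
        depth=world.depth,
        gene_length=world.gene_length,
        exons_per_gene=world.exons_per_gene,
        read_length=world.read_length,
        seed=world.seed,
    )
    assembly = MockAssembly(
        candidates=[], exons=[], alignments=[], cutoffs={}, truth={}, locus_outcomes={}
    )

    def add_gene(gene_id: str, og: str, depth: float, label: str) -> None:
        candidate, alignments = _emit_gene(rng, gene_id, og, depth, config)
        assembly.candidates.append(candidate)
        assembly.exons.extend(candidate.exons)
        assembly.alignments.extend(alignments)
        assembly.truth[gene_id] = label
        if og not in assembly.cutoffs:
            assembly.cutoffs[og] = synthetic_cutoffs(og, config)

    for locus in world.loci:
        og = f"og_{locus.locus_id}"
        if locus.kind == "single":
            if locus.haplotype_divergence <= aggressiveness:
                assembly.locus_outcomes[locus.locus_id] = "collapsed"
                add_gene(f"{locus.locus_id}_g1", og, world.depth, "S")
            else:
                assembly.locus_outcomes[locus.locus_id] = "duplicated"
                add_gene(f"{locus.locus_id}_g1", og, world.depth / 2.0, "FM")
                add_gene(f"{locus.locus_id}_g2", og, world.depth / 2.0, "FM")
        else:
            if locus.paralog_divergence <= aggressiveness:
                assembly.locus_outcomes[locus.locus_id] = "merged"
                add_gene(f"{locus.locus_id}_g1", og, 2.0 * world.depth, "chimera")
            else:
                assembly.locus_outcomes[locus.locus_id] = "separate"
                add_gene(f"{locus.locus_id}_g1", og, world.depth, "TM")
                add_gene(f"{locus.locus_id}_g2", og, world.depth, "TM")
    return assembly


class MockBackend:
    """In-process backend wiring the mock assembler into the optimizer.

    The objective assembles the world at the proposed aggressiveness and
    scores the result with the full AG pipeline (classification, exonic
    coverage, Cov(S), TM/FM discrimination).
    """

    spec = MOCK_BACKEND

    def __init__(self, world: MockWorld, tm_threshold: float = DEFAULT_TM_THRESHOLD):
        self.world = world
        self.tm_threshold = tm_threshold
        self.space = MOCK_SPACE

    def objective(self, parameter: float):
        assembly = mock_assemble(self.world, parameter)
        report = compute_ag_from_components(
            assembly.candidates,
            assembly.alignments,
            assembly.cutoffs,
            all_orthogroup_ids=assembly.orthogroup_ids,
            tm_threshold=self.tm_threshold,
        )
        return report.ag, assembly

    def final_assembly(self, parameter: float) -> MockAssembly:
        return mock_assemble(self.world, parameter)


def gapped_world(
    n_anchor: int,
    n_het: int,
    n_pairs: int,
    depth: float = 30.0,
    seed: int = 0,
    het_range: tuple[float, float] = (0.05, 0.40),
    paralog_range: tuple[float, float] = (0.60, 0.95),
    **geometry,
) -> MockWorld:
    """A random world whose heterozygous and paralogue divergences are
    separated by a gap, so a truth-optimal aggressiveness plateau
    ``[max(het), min(paralog))`` exists for parameter-recovery checks.

    Anchor loci have zero allele divergence (always collapsed), keeping
    Cov(S) defined at every aggressiveness.
    """
    rng = np.random.default_rng(seed)
    loci = []
    for i in range(n_anchor):
        loci.append(Locus(f"anchor{i}", "single", 0.0))
    for i in range(n_het):
        loci.append(Locus(f"het{i}", "single", float(rng.uniform(*het_range))))
    for i in range(n_pairs):
        hd = float(rng.uniform(*het_range))
        pd = float(rng.uniform(*paralog_range))
        loci.append(Locus(f"pair{i}", "paralog_pair", hd, pd))
    return MockWorld(loci=tuple(loci), depth=depth, seed=seed, **geometry)


def truth_plateau(world: MockWorld) -> tuple[float, float]:
    """The aggressiveness interval on which expected AG is maximal:
    ``[max heterozygous divergence, min paralogue divergence)``; upper bound
    1 when the world has no paralogue pair."""
    het = [l.haplotype_divergence for l in world.loci if l.kind == "single"]
    par = [l.paralog_divergence for l in world.loci if l.kind == "paralog_pair"]
    lo = max(het) if het else 0.0
    hi = min(par) if par else 1.0
    if lo >= hi:
        raise InvalidArgumentError("world has no truth-optimal plateau (no divergence gap)")
    return lo, hi
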