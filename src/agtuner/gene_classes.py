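"""Simplified BUSCO-style classification of candidate genes and orthogroups.

A candidate gene (predicted by an external gene finder and scored against the
orthogroup's profile HMM) is *complete* when it passes both the bitscore
cutoff (criterion for sequence similarity) and the minimum-length criterion;
*fragmented* when it passes the bitscore cutoff only; *rejected* otherwise.

Orthogroups are then binned into the standard categories: S (exactly one
complete gene), D (two or more complete genes — "multicopy"), F (no complete
gene but at least one fragmented one) and M (nothing passed the bitscore
cutoff). C = S + D always.

The minimum-length rule is operationalized as
``protein_length >= length_cutoff - 2 * length_sigma`` using the dataset's
per-orthogroup mean length and sigma. Dataset-specific length bounds differ
between toolchains; the two-sigma rule is this package's documented,
configurable default (``length_rule=``).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

from .errors import InvalidArgumentError, MalformedInputError
from .formats_io import ExonInterval, _as_lines, _as_output


class GeneStatus(str, Enum):
    COMPLETE = "complete"
    FRAGMENTED = "fragmented"
    REJECTED = "rejected"


class Category(str, Enum):
    S = "S"
    D = "D"
    F = "F"
    M = "M"


@dataclass(frozen=True)
class GeneCandidate:
    """A predicted gene copy: exon structure plus its HMM score and length."""

    gene_id: str
    orthogroup_id: str
    protein_length: int
    bitscore: float
    exons: tuple[ExonInterval, ...]

    def __post_init__(self):
        object.__setattr__(self, "exons", tuple(self.exons))
        if self.protein_length < 1:
            raise InvalidArgumentError(f"gene {self.gene_id}: protein_length < 1")
        contigs = {e.contig_id for e in self.exons}
        if len(contigs) > 1:
            raise InvalidArgumentError(
                f"gene {self.gene_id}: exons span multiple contigs {sorted(contigs)}"
            )
        for exon in self.exons:
            if exon.gene_id != self.gene_id:
                raise InvalidArgumentError(
                    f"gene {self.gene_id}: exon references gene {exon.gene_id}"
                )


@dataclass(frozen=True)
class ClassifiedGene:
    candidate: GeneCandidate
    status: GeneStatus


@dataclass
class OrthogroupStatus:
    orthogroup_id: str
    category: Category
    complete_genes: list[str]
    fragmented_genes: list[str]


def two_sigma_min_length(profile) -> float:
    """Default minimum-length rule: mean length minus two sigma."""
    return profile.length_cutoff - 2.0 * profile.length_sigma


def classify_candidate(
    candidate: GeneCandidate,
    profile,
    length_rule: Callable[[object], float] = two_sigma_min_length,
) -> ClassifiedGene:
    """Apply the two completeness criteria.

    ``profile`` is anything carrying ``orthogroup_id``, ``score_cutoff``,
    ``length_cutoff`` and ``length_sigma`` (an
    :class:`~agtuner.catalog.OrthogroupProfile` or a
    :class:`~agtuner.formats_io.Cutoffs`). Bitscore below the cutoff rejects
    the candidate regardless of length; a passing bitscore with a protein
    shorter than the minimum length yields a fragmented gene.
    """
    if candidate.orthogroup_id != profile.orthogroup_id:
        raise InvalidArgumentError(
            f"candidate {candidate.gene_id} is from orthogroup "
            f"{candidate.orthogroup_id}, profile is {profile.orthogroup_id}"
        )
    if candidate.bitscore < profile.score_cutoff:
        status = GeneStatus.REJECTED
    elif candidate.protein_length < length_rule(profile):
        status = GeneStatus.FRAGMENTED
    else:
        status = GeneStatus.COMPLETE
    return ClassifiedGene(candidate, status)


def categorize_orthogroups(
    classified: Iterable[ClassifiedGene],
    all_orthogroup_ids: Iterable[str],
) -> dict[str, OrthogroupStatus]:
    """Bin every orthogroup into S/D/F/M from its genes' statuses.

    Orthogroups with no candidates at all (but listed in
    ``all_orthogroup_ids``) are missing. Multiple candidates for one
    orthogroup are counted independently; locus-level deduplication is the
    upstream predictor's job.
    """
    all_ids = set(all_orthogroup_ids)
    complete: dict[str, list[str]] = {}
    fragmented: dict[str, list[str]] = {}
    for gene in classified:
        og = gene.candidate.orthogroup_id
        if og not in all_ids:
            raise InvalidArgumentError(
                f"gene {gene.candidate.gene_id}: orthogroup {og} not in the orthogroup set"
            )
        if gene.status is GeneStatus.COMPLETE:
            complete.setdefault(og, []).append(gene.candidate.gene_id)
        elif gene.status is GeneStatus.FRAGMENTED:
            fragmented.setdefault(og, []).append(gene.candidate.gene_id)
    statuses: dict[str, OrthogroupStatus] = {}
    for og in sorted(all_ids):
        n_complete = len(complete.get(og, []))
        if n_complete == 1:
            category = Category.S
        elif n_complete >= 2:
            category = Category.D
        elif fragmented.get(og):
            category = Category.F
        else:
            category = Category.M
        statuses[og] = OrthogroupStatus(
            orthogroup_id=og,
            category=category,
            complete_genes=sorted(complete.get(og, [])),
            fragmented_genes=sorted(fragmented.get(og, [])),
        )
    return statuses


# ---------------------------------------------------------------------------
# candidate TSV interchange
# ---------------------------------------------------------------------------

_CANDIDATE_HEADER = "gene_id\torthogroup_id\tprotein_length\tbitscore\tcontig\texons"


def read_candidates_tsv(source) -> list[GeneCandidate]:
    """Read the candidate TSV: gene_id, orthogroup_id, protein_length,
    bitscore, contig, exon list (``start-end,start-end,...``; 0-based
    half-open)."""
    candidates: list[GeneCandidate] = []
    with _as_lines(source) as lines:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line or (lineno == 1 and line.startswith("gene_id")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise MalformedInputError(f"candidates TSV line {lineno}: expected 6 columns")
            gene_id, og, contig = cols[0], cols[1], cols[4]
            try:
                protein_length = int(cols[2])
                bitscore = float(cols[3])
                exons = []
                for span in cols[5].split(","):
                    start_s, end_s = span.split("-")
                    exons.append(
                        ExonInterval(contig, int(start_s), int(end_s), gene_id, og)
                    )
            except (ValueError, InvalidArgumentError) as exc:
                raise MalformedInputError(f"candidates TSV line {lineno}: {exc}") from exc
            candidates.append(
                GeneCandidate(gene_id, og, protein_length, bitscore, tuple(exons))
            )
    return candidates


def write_candidates_tsv(candidates: Iterable[GeneCandidate], dest) -> None:
    with _as_output(dest) as out:
        out.write(_CANDIDATE_HEADER + "\n")
        for cand in candidates:
            contig = cand.exons[0].contig_id if cand.exons else ""
            spans = ",".join(f"{e.start}-{e.end}" for e in cand.exons)
            out.write(
                f"{cand.gene_id}\t{cand.orthogroup_id}\t{cand.protein_length}\t"
                f"{cand.bitscore:g}\t{contig}\t{spans}\n"
            )
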