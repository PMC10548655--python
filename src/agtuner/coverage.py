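"""Per-gene exonic read depth and the Cov(S) yardstick.

Depth is computed over exonic bases only — introns are excluded because they
may harbour transposable elements whose mis-assembled copies elsewhere
distort local coverage. Per gene, the statistic is the *median* over all
exonic bases (zero-depth bases included); over the single-copy genes, Cov(S)
is the median of those per-gene medians. Medians are robust to the odd
collapsed repeat or dropped region; with an even count the mean of the two
middle values is taken (numpy's convention).

Only primary alignments contribute: duplicated loci attract secondary
multi-mappings, and counting them would erase the halved-coverage signal that
separates uncollapsed alleles from real paralogues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InvalidArgumentError, NoSingleCopyGenesError
from .formats_io import AlignmentRecord, ExonInterval
from .gene_classes import Category, OrthogroupStatus


@dataclass(frozen=True)
class GeneCoverage:
    gene_id: str
    median_exonic_depth: float
    exonic_positions: int


@dataclass
class CoverageSummary:
    """Per-gene coverage plus Cov(S), the median depth of single-copy genes."""

    per_gene: dict[str, GeneCoverage]
    cov_s: float


def exonic_depth_array(
    alignments: Iterable[AlignmentRecord], exons: Sequence[ExonInterval]
) -> np.ndarray:
    """Per-base primary-alignment depth over the (merged) exonic positions.

    Returns one value per exonic base, in genomic order. Exons must be
    non-empty and on a single contig.
    """
    if not exons:
        raise InvalidArgumentError("empty exon list")
    contigs = {e.contig_id for e in exons}
    if len(contigs) > 1:
        raise InvalidArgumentError(f"exons span multiple contigs: {sorted(contigs)}")
    contig = exons[0].contig_id
    spans = _merge_spans([(e.start, e.end) for e in exons])
    offsets = np.cumsum([0] + [end - start for start, end in spans])
    total = int(offsets[-1])
    diff = np.zeros(total + 1, dtype=np.int64)
    for aln in alignments:
        if not aln.is_primary or aln.target_id != contig:
            continue
        for (start, end), offset in zip(spans, offsets):
            lo = max(start, aln.target_start)
            hi = min(end, aln.target_end)
            if lo < hi:
                diff[offset + (lo - start)] += 1
                diff[offset + (hi - start)] -= 1
    return np.cumsum(diff[:-1])


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(spans):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def gene_median_depth(
    alignments: Iterable[AlignmentRecord], exons: Sequence[ExonInterval]
) -> GeneCoverage:
    """Median primary-alignment depth over a gene's exonic bases."""
    depths = exonic_depth_array(alignments, exons)
    return GeneCoverage(
        gene_id=exons[0].gene_id,
        median_exonic_depth=float(np.median(depths)),
        exonic_positions=int(depths.size),
    )


def coverage_by_gene(
    alignments: Iterable[AlignmentRecord], exons: Iterable[ExonInterval]
) -> dict[str, GeneCoverage]:
    """Group exons by gene and compute each gene's median exonic depth.

    Alignments are pre-bucketed by contig so the per-gene pass only scans
    reads mapped to the gene's own contig.
    """
    by_contig: dict[str, list[AlignmentRecord]] = {}
    for aln in alignments:
        if aln.is_primary:
            by_contig.setdefault(aln.target_id, []).append(aln)
    exons_by_gene: dict[str, list[ExonInterval]] = {}
    for exon in exons:
        exons_by_gene.setdefault(exon.gene_id, []).append(exon)
    result: dict[str, GeneCoverage] = {}
    for gene_id, gene_exons in exons_by_gene.items():
        contig_alns = by_contig.get(gene_exons[0].contig_id, [])
        result[gene_id] = gene_median_depth(contig_alns, gene_exons)
    return result


def compute_cov_s(s_gene_coverages: Iterable[GeneCoverage | float]) -> float:
    """Cov(S): median over single-copy genes' median exonic depths.

    Each S orthogroup contributes its single complete gene. With no
    single-copy genes the yardstick (and hence AG) is undefined.
    """
    values = [
        c.median_exonic_depth if isinstance(c, GeneCoverage) else float(c)
        for c in s_gene_coverages
    ]
    if not values:
        raise NoSingleCopyGenesError(
            "no single-copy genes: Cov(S) and the TM/FM threshold are undefined"
        )
    return float(np.median(values))


def orthogroup_mean_coverage(gene_coverages: Iterable[GeneCoverage | float]) -> float:
    """Arithmetic mean of a multicopy orthogroup's per-gene median depths."""
    values = [
        c.median_exonic_depth if isinstance(c, GeneCoverage) else float(c)
        for c in gene_coverages
    ]
    if len(values) < 2:
        raise InvalidArgumentError(
            f"a multicopy orthogroup needs >=2 complete genes, got {len(values)}"
        )
    return float(np.mean(values))


def build_coverage_summary(
    per_gene: Mapping[str, GeneCoverage],
    statuses: Mapping[str, OrthogroupStatus],
) -> CoverageSummary:
    """Assemble a :class:`CoverageSummary`, deriving Cov(S) from the complete
    genes of single-copy orthogroups. ``cov_s`` is NaN when there are no
    single-copy genes *and* nothing multicopy to classify."""
    s_values = [
        per_gene[gene].median_exonic_depth
        for status in statuses.values()
        if status.category is Category.S
        for gene in status.complete_genes
        if gene in per_gene
    ]
    if s_values:
        cov_s = float(np.median(s_values))
    else:
        cov_s = float("nan")
    return CoverageSummary(per_gene=dict(per_gene), cov_s=cov_s)
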