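"""The AG metric: accurately assembled genes.

Multicopy (category D) orthogroups are split by coverage into true multicopy
(TM — genuine paralogues, coverage near Cov(S)) and false multicopy (FM —
uncollapsed alleles of one locus, coverage near Cov(S)/2). The decision
threshold is ``tm_threshold * Cov(S)`` with ``tm_threshold = 0.75`` by
default, the midpoint of the two expected modes; TM requires *strictly*
greater mean coverage, so a value exactly on the threshold is called FM —
the conservative direction when hunting haplotypic duplications. (If the
depth distribution is Poisson-like, the half-coverage mode is narrower, so a
slightly lower factor can be justified; the factor is configurable.)

AG = (number of genes in S orthogroups) + (number of genes in TM
orthogroups). It counts *genes*, not orthogroups: losing one copy of a
paralogue pair moves the orthogroup from TM to S, leaving the orthogroup
count unchanged while one real gene disappeared — gene counting sees that.
Fragmented genes never contribute to AG and never enter TM/FM means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .coverage import (
    CoverageSummary,
    build_coverage_summary,
    coverage_by_gene,
    orthogroup_mean_coverage,
)
from .errors import (
    IncompleteCoverageError,
    InvalidArgumentError,
    NoSingleCopyGenesError,
)
from .formats_io import AlignmentRecord
from .gene_classes import (
    Category,
    ClassifiedGene,
    GeneCandidate,
    OrthogroupStatus,
    categorize_orthogroups,
    classify_candidate,
)

#: Default TM/FM discrimination factor applied to Cov(S).
DEFAULT_TM_THRESHOLD = 0.75


class MulticopyClass(str, Enum):
    TM = "TM"
    FM = "FM"


def classify_multicopy(
    og_mean_coverage: float,
    cov_s: float,
    threshold: float = DEFAULT_TM_THRESHOLD,
) -> MulticopyClass:
    """TM iff the orthogroup's mean coverage strictly exceeds ``threshold * Cov(S)``."""
    if cov_s <= 0 or math.isnan(cov_s):
        raise InvalidArgumentError(f"Cov(S) must be positive, got {cov_s}")
    return (
        MulticopyClass.TM
        if og_mean_coverage > threshold * cov_s
        else MulticopyClass.FM
    )


@dataclass(frozen=True)
class PerGeneRow:
    gene_id: str
    orthogroup_id: str
    category: str
    multicopy_class: str  # "TM"/"FM" for genes of D orthogroups, "" otherwise
    status: str  # complete / fragmented
    median_depth: float


@dataclass
class AGReport:
    n_genes_s: int
    n_genes_tm: int
    n_genes_fm: int
    n_orthogroups: dict[str, int]  # keys S, D, F, M, TM, FM
    cov_s: float
    ag: int
    per_gene_table: list[PerGeneRow] = field(default_factory=list)


def compute_ag(
    statuses: Mapping[str, OrthogroupStatus],
    coverage: CoverageSummary,
    tm_threshold: float = DEFAULT_TM_THRESHOLD,
) -> AGReport:
    """Classify every multicopy orthogroup and sum AG.

    Every complete gene of every D orthogroup must have a coverage entry;
    a missing one raises :class:`IncompleteCoverageError` naming the gene.
    An entirely empty orthogroup set yields AG = 0 with an empty report.
    """
    counts = {"S": 0, "D": 0, "F": 0, "M": 0, "TM": 0, "FM": 0}
    rows: list[PerGeneRow] = []
    n_genes_s = 0
    n_genes_tm = 0
    n_genes_fm = 0

    d_statuses = [s for s in statuses.values() if s.category is Category.D]
    s_statuses = [s for s in statuses.values() if s.category is Category.S]
    if d_statuses and (math.isnan(coverage.cov_s) or not s_statuses):
        raise NoSingleCopyGenesError(
            "multicopy orthogroups present but Cov(S) is undefined "
            "(no complete single-copy gene with coverage)"
        )

    def depth_of(gene_id: str, required: bool) -> float:
        entry = coverage.per_gene.get(gene_id)
        if entry is None:
            if required:
                raise IncompleteCoverageError(
                    f"gene {gene_id} is counted by AG but has no coverage entry"
                )
            return float("nan")
        return entry.median_exonic_depth

    for og in sorted(statuses):
        status = statuses[og]
        counts[status.category.value] += 1
        if status.category is Category.S:
            gene = status.complete_genes[0]
            n_genes_s += 1
            rows.append(
                PerGeneRow(gene, og, "S", "", "complete", depth_of(gene, required=True))
            )
        elif status.category is Category.D:
            depths = [depth_of(g, required=True) for g in status.complete_genes]
            og_class = classify_multicopy(
                orthogroup_mean_coverage(depths), coverage.cov_s, tm_threshold
            )
            counts[og_class.value] += 1
            if og_class is MulticopyClass.TM:
                n_genes_tm += len(status.complete_genes)
            else:
                n_genes_fm += len(status.complete_genes)
            for gene, depth in zip(status.complete_genes, depths):
                rows.append(
                    PerGeneRow(gene, og, "D", og_class.value, "complete", depth)
                )
        for gene in status.fragmented_genes:
            rows.append(
                PerGeneRow(
                    gene, og, status.category.value, "", "fragmented",
                    depth_of(gene, required=False),
                )
            )

    return AGReport(
        n_genes_s=n_genes_s,
        n_genes_tm=n_genes_tm,
        n_genes_fm=n_genes_fm,
        n_orthogroups=counts,
        cov_s=coverage.cov_s,
        ag=n_genes_s + n_genes_tm,
        per_gene_table=rows,
    )


def compute_ag_from_components(
    candidates: Sequence[GeneCandidate],
    alignments: Iterable[AlignmentRecord],
    cutoffs: Mapping[str, object],
    all_orthogroup_ids: Iterable[str] | None = None,
    tm_threshold: float = DEFAULT_TM_THRESHOLD,
    exons=None,
) -> AGReport:
    """End-to-end AG from raw components.

    Classifies candidates against their cutoffs, bins orthogroups, computes
    per-gene exonic depth from the alignments (exons taken from the
    candidates unless ``exons`` overrides them), derives Cov(S) and sums AG.
    ``all_orthogroup_ids`` defaults to the cutoff table's ids, so orthogroups
    without any candidate are counted as missing.
    """
    og_ids = set(all_orthogroup_ids) if all_orthogroup_ids is not None else set(cutoffs)
    classified = []
    for cand in candidates:
        if cand.orthogroup_id not in cutoffs:
            raise InvalidArgumentError(
                f"candidate {cand.gene_id}: no cutoffs for orthogroup {cand.orthogroup_id}"
            )
        classified.append(classify_candidate(cand, cutoffs[cand.orthogroup_id]))
    statuses = categorize_orthogroups(classified, og_ids)
    if exons is None:
        exons = [e for cand in candidates for e in cand.exons]
    per_gene = coverage_by_gene(alignments, exons)
    summary = build_coverage_summary(per_gene, statuses)
    return compute_ag(statuses, summary, tm_threshold)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def summary_line(report: AGReport) -> str:
    """BUSCO-style one-line summary plus the AG-specific counts.

    Percentages are relative to the total orthogroup count, one decimal.
    """
    n = sum(report.n_orthogroups[k] for k in ("S", "D", "F", "M"))

    def pct(key: str) -> float:
        return 100.0 * report.n_orthogroups[key] / n if n else 0.0

    c = pct("S") + pct("D")
    cov_s = "NA" if math.isnan(report.cov_s) else f"{report.cov_s:g}"
    return (
        f"C:{c:.1f}%[S:{pct('S'):.1f}%,D:{pct('D'):.1f}%],"
        f"F:{pct('F'):.1f}%,M:{pct('M'):.1f}%,n:{n},"
        f"AG:{report.ag},TM:{report.n_orthogroups['TM']},"
        f"FM:{report.n_orthogroups['FM']},Cov(S):{cov_s}"
    )


def per_gene_frame(report: AGReport) -> pd.DataFrame:
    """The per-gene table as a DataFrame (sinaplot-ready: one dot per gene)."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "orthogroup_id": r.orthogroup_id,
                "category": r.category,
                "multicopy_class": r.multicopy_class,
                "status": r.status,
                "median_exonic_depth": r.median_depth,
            }
            for r in report.per_gene_table
        ],
        columns=[
            "gene_id",
            "orthogroup_id",
            "category",
            "multicopy_class",
            "status",
            "median_exonic_depth",
        ],
    )


def export_report(report: AGReport, outdir) -> str:
    """Write ``per_gene.tsv`` and ``summary.txt`` under ``outdir``; return the
    summary line."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    per_gene_frame(report).to_csv(out / "per_gene.tsv", sep="\t", index=False)
    line = summary_line(report)
    (out / "summary.txt").write_text(line + "\n", encoding="utf-8")
    return line
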