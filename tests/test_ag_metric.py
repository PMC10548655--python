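"""TM/FM discrimination and the AG sum."""

import math

import numpy as np
import pytest

from agtuner.ag_metric import (
    MulticopyClass,
    classify_multicopy,
    compute_ag,
    compute_ag_from_components,
    export_report,
    per_gene_frame,
    summary_line,
)
from agtuner.coverage import CoverageSummary, GeneCoverage
from agtuner.errors import (
    IncompleteCoverageError,
    InvalidArgumentError,
    NoSingleCopyGenesError,
)
from agtuner.gene_classes import Category, OrthogroupStatus


class TestClassifyMulticopy:
    def test_full_coverage_is_tm(self):
        assert classify_multicopy(100, 100) is MulticopyClass.TM

    def test_half_coverage_is_fm(self):
        assert classify_multicopy(50, 100) is MulticopyClass.FM

    def test_boundary_assigned_to_fm(self):
        assert classify_multicopy(75, 100) is MulticopyClass.FM
        assert classify_multicopy(75.0001, 100) is MulticopyClass.TM

    def test_nonpositive_cov_s_errors(self):
        with pytest.raises(InvalidArgumentError):
            classify_multicopy(50, 0)

    def test_threshold_configurable(self):
        assert classify_multicopy(60, 100, threshold=0.5) is MulticopyClass.TM


def make_state(s_depths, d_orthogroups, fragmented=(), f_orthogroups=0, m_orthogroups=0):
    """Build (statuses, coverage) from per-S-gene depths and per-D-orthogroup
    lists of complete-gene depths."""
    statuses = {}
    per_gene = {}
    for i, depth in enumerate(s_depths):
        og, gene = f"ogS{i}", f"s{i}"
        statuses[og] = OrthogroupStatus(og, Category.S, [gene], [])
        per_gene[gene] = GeneCoverage(gene, float(depth), 100)
    for i, depths in enumerate(d_orthogroups):
        og = f"ogD{i}"
        genes = [f"d{i}_{j}" for j in range(len(depths))]
        statuses[og] = OrthogroupStatus(og, Category.D, genes, [])
        for gene, depth in zip(genes, depths):
            per_gene[gene] = GeneCoverage(gene, float(depth), 100)
    for i, gene in enumerate(fragmented):
        og = f"ogF{i}"
        statuses[og] = OrthogroupStatus(og, Category.F, [], [gene])
    for i in range(m_orthogroups):
        og = f"ogM{i}"
        statuses[og] = OrthogroupStatus(og, Category.M, [], [])
    cov_s = float(np.median(s_depths)) if s_depths else float("nan")
    return statuses, CoverageSummary(per_gene=per_gene, cov_s=cov_s)


class TestComputeAg:
    def test_counts_genes_not_orthogroups(self):
        statuses, coverage = make_state([100] * 3, [[100, 100, 100], [50, 50]])
        report = compute_ag(statuses, coverage)
        assert report.n_genes_s == 3
        assert report.n_genes_tm == 3
        assert report.n_genes_fm == 2
        assert report.ag == 6
        assert report.n_orthogroups == {"S": 3, "D": 2, "F": 0, "M": 0, "TM": 1, "FM": 1}

    def test_empty_input_gives_zero_ag(self):
        report = compute_ag({}, CoverageSummary({}, float("nan")))
        assert report.ag == 0
        assert report.per_gene_table == []

    def test_missing_coverage_names_the_gene(self):
        statuses, coverage = make_state([100], [[100, 100]])
        del coverage.per_gene["d0_1"]
        with pytest.raises(IncompleteCoverageError, match="d0_1"):
            compute_ag(statuses, coverage)

    def test_multicopy_without_single_copy_errors(self):
        statuses, coverage = make_state([], [[100, 100]])
        with pytest.raises(NoSingleCopyGenesError):
            compute_ag(statuses, coverage)

    def test_scale_invariance(self, rng):
        """Multiplying every depth by k > 0 changes no TM/FM call and no AG."""
        s_depths = rng.uniform(50, 150, size=8).tolist()
        d_ogs = [rng.uniform(30, 150, size=int(rng.integers(2, 4))).tolist() for _ in range(6)]
        base = compute_ag(*make_state(s_depths, d_ogs))
        for k in (0.1, 3.0, 250.0):
            scaled = compute_ag(
                *make_state([d * k for d in s_depths], [[d * k for d in og] for og in d_ogs])
            )
            assert scaled.ag == base.ag
            assert scaled.n_orthogroups == base.n_orthogroups

    def test_tm_to_fm_move_decreases_ag_by_gene_count(self):
        statuses, coverage = make_state([100] * 3, [[100, 100, 100]])
        before = compute_ag(statuses, coverage)
        # drop that orthogroup's coverage below the threshold
        statuses2, coverage2 = make_state([100] * 3, [[50, 50, 50]])
        after = compute_ag(statuses2, coverage2)
        assert before.ag - after.ag == 3

    def test_fragmented_genes_never_counted(self):
        statuses, coverage = make_state([100], [], fragmented=["frag0"])
        report = compute_ag(statuses, coverage)
        assert report.ag == 1
        assert report.n_orthogroups["F"] == 1


class TestReporting:
    def test_summary_prefix(self):
        statuses, coverage = make_state([100] * 9, [[100, 100]])
        line = summary_line(compute_ag(statuses, coverage))
        assert line.startswith("C:100.0%[S:90.0%,D:10.0%]")
        assert "AG:11" in line

    def test_export_and_row_bookkeeping(self, tmp_path):
        statuses, coverage = make_state([100] * 2, [[100, 100], [50, 50]], fragmented=["fr0"])
        report = compute_ag(statuses, coverage)
        n_d_genes = 4
        assert len(report.per_gene_table) == report.n_genes_s + n_d_genes + 1
        line = export_report(report, tmp_path)
        assert (tmp_path / "per_gene.tsv").exists()
        assert (tmp_path / "summary.txt").read_text().strip() == line

    def test_empty_report_is_header_only(self, tmp_path):
        report = compute_ag({}, CoverageSummary({}, float("nan")))
        export_report(report, tmp_path)
        lines = (tmp_path / "per_gene.tsv").read_text().splitlines()
        assert len(lines) == 1  # header only


def test_end_to_end_on_synthetic_fixture(small_fixture):
    """Pipeline AG equals the fixture's structural expectation."""
    from agtuner.synthetic import fixture_expected_ag

    config, fixture = small_fixture
    report = compute_ag_from_components(
        fixture.candidates,
        fixture.alignments,
        fixture.cutoffs,
        all_orthogroup_ids=fixture.orthogroup_ids,
    )
    assert report.ag == fixture_expected_ag(config)
    assert report.n_orthogroups["FM"] == config.n_false_duplication_loci
    assert report.n_orthogroups["TM"] == config.n_paralog_pairs
    assert abs(report.cov_s - config.depth) <= 3 * math.sqrt(config.depth)
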