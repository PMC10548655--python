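"""Assembler command constructors, read subsetting and the mock assembler."""

import pytest

from agtuner.backends import (
    FLYE_BACKEND,
    HIFIASM_BACKEND,
    BackendSpec,
    Locus,
    MockWorld,
    flye_command,
    gapped_world,
    hifiasm_command,
    mock_assemble,
    select_busco_reads,
)
from agtuner.errors import InvalidArgumentError
from agtuner.formats_io import ProteinHit
from agtuner.optimizer import SearchSpace
from agtuner.synthetic import expected_ag


class TestHifiasmCommand:
    def test_contains_s_flag(self):
        cmd = hifiasm_command(0.55, "reads.fq", "/work")
        idx = cmd.index("-s")
        assert cmd[idx + 1] == "0.55"

    def test_prefix_fixed_per_workdir(self):
        c1 = hifiasm_command(0.2, "reads.fq", "/work")
        c2 = hifiasm_command(0.8, "reads.fq", "/work")
        assert c1[c1.index("-o") + 1] == c2[c2.index("-o") + 1]

    def test_out_of_range_errors(self):
        with pytest.raises(InvalidArgumentError):
            hifiasm_command(1.5, "reads.fq", "/work")


class TestFlyeCommand:
    def test_divergence_settings_coupled(self):
        cmd = flye_command(0.01, "all.fq", "busco.fq", "/work")
        extra = cmd[cmd.index("--extra-params") + 1]
        assert "assemble_ovlp_divergence=0.01" in extra
        assert "repeat_graph_ovlp_divergence=0.01" in extra
        assert "assemble_divergence_relative=0" in extra

    def test_no_alt_contigs_always_present(self):
        for param in (0.0001, 0.05, 0.5):
            assert "--no-alt-contigs" in flye_command(param, "a.fq", "b.fq", "/w")

    def test_final_flag_switches_reads_only(self):
        search = flye_command(0.01, "all.fq", "busco.fq", "/w", final=False)
        final = flye_command(0.01, "all.fq", "busco.fq", "/w", final=True)
        assert "busco.fq" in search and "all.fq" not in search
        assert "all.fq" in final and "busco.fq" not in final
        assert search[search.index("--extra-params") + 1] == final[final.index("--extra-params") + 1]

    def test_out_of_range_errors(self):
        with pytest.raises(InvalidArgumentError):
            flye_command(0.6, "a.fq", "b.fq", "/w")


class TestBackendSpec:
    def test_builtin_specs_valid(self):
        assert HIFIASM_BACKEND.space.transform == "identity"
        assert FLYE_BACKEND.space.transform == "log10"
        assert "--no-alt-contigs" in FLYE_BACKEND.mode_flags

    def test_wrong_space_rejected(self):
        with pytest.raises(InvalidArgumentError):
            BackendSpec("hifiasm", "-s", SearchSpace(0.0001, 0.5, "log10"))
        with pytest.raises(InvalidArgumentError):
            BackendSpec("flye", "max_divergence", SearchSpace(0.0, 1.0, "identity"))


class TestSelectBuscoReads:
    def test_reads_with_hits_kept_in_order(self):
        hits = [ProteinHit("r1", "p1", 100, 1e-30)]
        assert select_busco_reads(hits, ["r2", "r1"]) == ["r1"]

    def test_no_hits(self):
        assert select_busco_reads([], ["r1", "r2"]) == []

    def test_duplicates_collapse(self):
        hits = [ProteinHit("r1", "p1", 100, 1e-30), ProteinHit("r1", "p2", 90, 1e-10)]
        assert select_busco_reads(hits, ["r1", "r1"]) == ["r1"]

    def test_evalue_ceiling_filters(self):
        hits = [ProteinHit("r1", "p1", 100, 1e-3)]
        assert select_busco_reads(hits, ["r1"]) == []
        assert select_busco_reads(hits, ["r1"], evalue_ceiling=1e-2) == ["r1"]


class TestMockWorld:
    def test_paralog_divergence_must_exceed_haplotype(self):
        with pytest.raises(InvalidArgumentError):
            Locus("l1", "paralog_pair", 0.5, 0.4)

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidArgumentError):
            Locus("l1", "triplet", 0.1)


WORLD = MockWorld(
    loci=(
        Locus("anchor", "single", 0.0),
        Locus("het1", "single", 0.3),
        Locus("het2", "single", 0.4),
        Locus("pair1", "paralog_pair", 0.1, 0.7),
    ),
    depth=30.0,
    seed=42,
)


class TestMockAssemble:
    def test_zero_aggressiveness_duplicates_every_het_locus(self):
        asm = mock_assemble(WORLD, 0.0)
        assert asm.locus_outcomes["het1"] == "duplicated"
        assert asm.locus_outcomes["het2"] == "duplicated"
        assert asm.locus_outcomes["anchor"] == "collapsed"  # zero divergence
        assert asm.locus_outcomes["pair1"] == "separate"

    def test_full_aggressiveness_merges_every_pair(self):
        asm = mock_assemble(WORLD, 1.0)
        assert asm.locus_outcomes["pair1"] == "merged"
        assert all(
            asm.locus_outcomes[l.locus_id] == "collapsed"
            for l in WORLD.loci
            if l.kind == "single"
        )

    def test_gap_aggressiveness_is_truth_optimal(self):
        asm = mock_assemble(WORLD, 0.5)
        assert sorted(asm.truth.values()).count("FM") == 0
        assert sorted(asm.truth.values()).count("chimera") == 0
        assert expected_ag(WORLD, 0.5) == 3 + 2  # 3 singles + 1 pair

    def test_expected_ag_regimes(self):
        world = gapped_world(2, 3, 2, seed=1)
        plateau_mid = 0.5
        assert expected_ag(world, plateau_mid) == 2 + 3 + 2 * 2
        # at zero aggressiveness het loci duplicate (score 0), pairs stay apart
        assert expected_ag(world, 0.0) == 2 + 0 + 2 * 2
        assert expected_ag(world, 1.0) == 2 + 3 + 2  # pairs merged to chimeras
        assert expected_ag(world, 0.0) < expected_ag(world, plateau_mid)
        assert expected_ag(world, 1.0) < expected_ag(world, plateau_mid)

    def test_deterministic_for_same_world_and_parameter(self):
        a1 = mock_assemble(WORLD, 0.5)
        a2 = mock_assemble(WORLD, 0.5)
        assert a1.alignments == a2.alignments
        assert a1.candidates == a2.candidates

    def test_depths_track_outcomes(self):
        from agtuner.coverage import coverage_by_gene

        asm = mock_assemble(WORLD, 0.0)
        per_gene = coverage_by_gene(asm.alignments, asm.exons)
        for gene_id, label in asm.truth.items():
            depth = per_gene[gene_id].median_exonic_depth
            expected = {"S": 30, "TM": 30, "FM": 15, "chimera": 60}[label]
            assert abs(depth - expected) <= 3 * (expected ** 0.5)

    def test_invalid_aggressiveness(self):
        with pytest.raises(InvalidArgumentError):
            mock_assemble(WORLD, 1.5)
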