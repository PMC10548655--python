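"""Parsers and writers for the external formats."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from agtuner.catalog import OrthogroupProfile
from agtuner.errors import (
    InconsistentDatasetError,
    InvalidArgumentError,
    MalformedInputError,
    MalformedProfileError,
)
from agtuner.formats_io import (
    AlignmentRecord,
    ExonInterval,
    parse_blasttab,
    parse_hmm_profile,
    parse_paf,
    read_cutoff_tables,
    read_exon_bed,
    write_exon_bed,
    write_hmm_profile,
    write_paf,
)

PAF_LINE = "r1\t100\t0\t100\t+\tctg1\t1000\t200\t300\t95\t100\t60"


class TestPaf:
    def test_mandatory_columns_map_to_record(self):
        (rec,) = parse_paf([PAF_LINE])
        assert rec == AlignmentRecord("r1", 100, "ctg1", 200, 300, "+", True, 60)

    def test_tp_tag_marks_secondary(self):
        (rec,) = parse_paf([PAF_LINE + "\ttp:A:S"])
        assert not rec.is_primary
        (rec,) = parse_paf([PAF_LINE + "\ttp:A:P"])
        assert rec.is_primary

    @pytest.mark.parametrize(
        "line",
        [
            "r1\t100\t0",  # truncated
            PAF_LINE.replace("200", "2x0"),  # non-integer coordinate
            "r1\t100\t0\t100\t+\tctg1\t1000\t300\t200\t95\t100\t60",  # start >= end
            "r1\t100\t0\t100\t+\tctg1\t250\t200\t300\t95\t100\t60",  # end > contig
        ],
    )
    def test_malformed_lines_name_the_line(self, line):
        with pytest.raises(MalformedInputError, match="line 1"):
            parse_paf([line])

    @given(
        st.lists(
            st.builds(
                AlignmentRecord,
                read_id=st.text(
                    alphabet=st.characters(min_codepoint=33, max_codepoint=126, exclude_characters="\t"),
                    min_size=1,
                    max_size=8,
                ),
                read_length=st.integers(1, 10_000),
                target_id=st.sampled_from(["ctgA", "ctgB"]),
                target_start=st.integers(0, 500),
                target_end=st.integers(501, 1000),
                strand=st.sampled_from("+-"),
                is_primary=st.booleans(),
                mapping_quality=st.integers(0, 255),
            ),
            max_size=20,
        )
    )
    def test_round_trip(self, records):
        buf = io.StringIO()
        write_paf(records, buf)
        assert parse_paf(io.StringIO(buf.getvalue())) == records


class TestExonBed:
    def test_basic_interval(self):
        (exon,) = read_exon_bed(["ctg1\t10\t20\tg1|og1"])
        assert exon == ExonInterval("ctg1", 10, 20, "g1", "og1")

    def test_abutting_intervals_merge(self):
        exons = read_exon_bed(["ctg1\t10\t20\tg1|og1", "ctg1\t20\t30\tg1|og1"])
        assert [(e.start, e.end) for e in exons] == [(10, 30)]

    def test_distinct_genes_not_merged(self):
        exons = read_exon_bed(["ctg1\t10\t20\tg1|og1", "ctg1\t20\t30\tg2|og1"])
        assert len(exons) == 2

    def test_inverted_interval_errors(self):
        with pytest.raises(MalformedInputError, match="line 1"):
            read_exon_bed(["ctg1\t20\t10\tg1|og1"])

    def test_round_trip(self):
        exons = read_exon_bed(["ctg1\t10\t20\tg1|og1", "ctg2\t5\t9\tg2|og2"])
        buf = io.StringIO()
        write_exon_bed(exons, buf)
        assert read_exon_bed(io.StringIO(buf.getvalue())) == exons


class TestBlastTab:
    ROW = "read1\tprotA\t95.0\t50\t2\t0\t1\t150\t1\t50\t1e-30\t120"

    def test_basic_row(self):
        (hit,) = parse_blasttab([self.ROW])
        assert hit.read_id == "read1"
        assert hit.protein_id == "protA"
        assert hit.bitscore == 120
        assert hit.evalue == 1e-30

    def test_empty_stream(self):
        assert parse_blasttab([]) == []

    def test_eleven_columns_error(self):
        with pytest.raises(MalformedInputError):
            parse_blasttab(["\t".join(self.ROW.split("\t")[:11])])

    def test_non_numeric_bitscore_error(self):
        with pytest.raises(MalformedInputError):
            parse_blasttab([self.ROW.replace("120", "abc")])


class TestCutoffTables:
    def test_merge(self):
        cutoffs = read_cutoff_tables(["og1 85.0"], ["og1 0 30.0 310"])
        assert cutoffs["og1"].score_cutoff == 85.0
        assert cutoffs["og1"].length_cutoff == 310
        assert cutoffs["og1"].length_sigma == 30.0

    def test_id_in_one_table_only(self):
        with pytest.raises(InconsistentDatasetError, match="og2"):
            read_cutoff_tables(["og1 85.0", "og2 90.0"], ["og1 0 30.0 310"])

    def test_empty_tables(self):
        assert read_cutoff_tables([], []) == {}


def _make_profile(emissions):
    emissions = np.asarray(emissions, dtype=float)
    return OrthogroupProfile("ogX", emissions.shape[0], emissions)


class TestHmmProfile:
    def test_uniform_reconstruction(self):
        """20 stored values of -ln(0.05) recover a uniform 0.05 distribution."""
        stored = f"{-math.log(0.05):.5f}"
        text = (
            "HMMER3/f [3.4]\nNAME  og1\nLENG  1\nALPH  amino\n"
            "HMM  A C D E F G H I K L M N P Q R S T V W Y\n"
            "     m->m m->i m->d i->m i->i d->m d->d\n"
            "  1  " + "  ".join([stored] * 20) + "\n"
            "     " + "  ".join(["2.99573"] * 20) + "\n"
            "     0.1 2.9 2.9 0.7 0.7 0.7 0.7\n//\n"
        )
        profile = parse_hmm_profile(io.StringIO(text))
        assert profile.length == 1
        np.testing.assert_allclose(profile.emissions, 0.05, atol=1e-6)

    def test_star_means_zero_probability(self):
        stored = f"{-math.log(1 / 19):.6f}"
        text = (
            "HMMER3/f [3.4]\nNAME  og1\nLENG  1\nALPH  amino\n"
            "HMM  A C\n     transitions\n"
            "  1  *  " + "  ".join([stored] * 19) + "\n"
            "     " + "  ".join(["2.99573"] * 20) + "\n"
            "     0.1 2.9 2.9 0.7 0.7 0.7 0.7\n//\n"
        )
        profile = parse_hmm_profile(io.StringIO(text))
        assert profile.emissions[0, 0] == 0.0
        np.testing.assert_allclose(profile.emissions[0, 1:], 1 / 19, atol=1e-6)

    def test_leng_mismatch_errors(self, rng):
        em = rng.dirichlet(np.ones(20), size=5)
        em /= em.sum(axis=1, keepdims=True)
        buf = io.StringIO()
        write_hmm_profile(_make_profile(em), buf)
        text = buf.getvalue().replace("LENG  5", "LENG  6")
        with pytest.raises(MalformedProfileError, match="LENG"):
            parse_hmm_profile(io.StringIO(text))

    def test_missing_hmm_section_errors(self):
        with pytest.raises(MalformedProfileError, match="HMM section"):
            parse_hmm_profile(io.StringIO("NAME og1\nLENG 3\n"))

    def test_unnormalized_emissions_error(self):
        text = (
            "HMMER3/f [3.4]\nNAME  og1\nLENG  1\nALPH  amino\n"
            "HMM  A\n  transitions\n"
            "  1  " + "  ".join(["0.10000"] * 20) + "\n"  # exp(-.1)*20 >> 1
            "     " + "  ".join(["2.99573"] * 20) + "\n"
            "     0.1 2.9 2.9 0.7 0.7 0.7 0.7\n//\n"
        )
        with pytest.raises(MalformedProfileError, match="sum"):
            parse_hmm_profile(io.StringIO(text))

    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_normalized(self, seed):
        """Writer/parser round trip; every parsed row sums to 1 within 1e-6."""
        rng = np.random.default_rng(seed)
        em = rng.dirichlet(np.ones(20), size=int(rng.integers(1, 5)))
        em /= em.sum(axis=1, keepdims=True)
        buf = io.StringIO()
        write_hmm_profile(_make_profile(em), buf)
        parsed = parse_hmm_profile(io.StringIO(buf.getvalue()))
        np.testing.assert_allclose(parsed.emissions.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(parsed.emissions, em, atol=1e-4)

    def test_agrees_with_pyhmmer(self, rng, tmp_path):
        """Independent cross-check: pyhmmer reads the same file to the same
        emission probabilities."""
        pyhmmer = pytest.importorskip("pyhmmer")
        em = rng.dirichlet(np.ones(20), size=3)
        em /= em.sum(axis=1, keepdims=True)
        path = tmp_path / "og.hmm"
        write_hmm_profile(_make_profile(em), path)
        ours = parse_hmm_profile(path)
        with pyhmmer.plan7.HMMFile(str(path)) as handle:
            theirs = np.asarray(next(iter(handle)).match_emissions)[1:]
        np.testing.assert_allclose(ours.emissions, theirs, atol=1e-5)
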