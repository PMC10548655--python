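"""Readers and writers for the external formats the tool touches.

All coordinates are 0-based half-open internally: BED and PAF are native,
anything 1-based is converted at the parser boundary. Downstream modules only
ever see the typed records defined here (or in :mod:`agtuner.catalog`).

Secondary alignments are parsed but flagged (``is_primary=False``); depth
computation uses primaries only, because secondary mappings double-count
duplicated loci — the very signal the AG metric measures.
"""

from __future__ import annotations

import io
import math
import os
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import numpy as np

from .errors import (
    InconsistentDatasetError,
    InvalidArgumentError,
    MalformedInputError,
    MalformedProfileError,
)

#: HMMER's amino-acid column order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_AMINO_ACIDS = len(AMINO_ACIDS)


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-assembly alignment (the span it covers on the target).

    Clipping and indel structure are deliberately ignored: an alignment covers
    its full target span, which is all a median depth statistic needs.
    """

    read_id: str
    read_length: int
    target_id: str
    target_start: int
    target_end: int
    strand: str = "+"
    is_primary: bool = True
    mapping_quality: int = 255

    def __post_init__(self):
        if not self.read_id:
            raise InvalidArgumentError("alignment record with empty read_id")
        if not (0 <= self.target_start < self.target_end):
            raise InvalidArgumentError(
                f"alignment {self.read_id}: bad target span "
                f"[{self.target_start}, {self.target_end})"
            )
        if self.strand not in "+-":
            raise InvalidArgumentError(f"alignment {self.read_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class ExonInterval:
    """A half-open exon interval attributed to one gene of one orthogroup."""

    contig_id: str
    start: int
    end: int
    gene_id: str
    orthogroup_id: str

    def __post_init__(self):
        if self.start >= self.end:
            raise InvalidArgumentError(
                f"exon of gene {self.gene_id}: start {self.start} >= end {self.end}"
            )


@dataclass(frozen=True)
class ProteinHit:
    """A translated-read-vs-protein hit (blast tabular row)."""

    read_id: str
    protein_id: str
    bitscore: float
    evalue: float

    def __post_init__(self):
        if self.bitscore < 0:
            raise InvalidArgumentError(f"hit {self.read_id}->{self.protein_id}: negative bitscore")
        if self.evalue < 0:
            raise InvalidArgumentError(f"hit {self.read_id}->{self.protein_id}: negative evalue")


@dataclass(frozen=True)
class Cutoffs:
    """Per-orthogroup completeness cutoffs from a BUSCO-style dataset.

    ``score_cutoff`` is the minimum HMM bitscore (criterion for sequence
    similarity); ``length_cutoff`` is the dataset's mean protein length and
    ``length_sigma`` its spread, combined downstream into the minimum-length
    criterion.
    """

    orthogroup_id: str
    score_cutoff: float
    length_cutoff: float
    length_sigma: float


@dataclass(frozen=True)
class CutoffDialect:
    """Column layout of the two whitespace-separated cutoff tables.

    The default matches the BUSCO dataset dialect: ``scores_cutoff`` rows are
    ``(id, cutoff)``; ``lengths_cutoff`` rows are ``(id, ignored, sigma,
    mean_length)``. Override the column indices for other layouts.
    """

    score_id_col: int = 0
    score_col: int = 1
    length_id_col: int = 0
    sigma_col: int = 2
    length_col: int = 3


# ---------------------------------------------------------------------------
# stream plumbing
# ---------------------------------------------------------------------------


@contextmanager
def _as_lines(source) -> Iterator[Iterable[str]]:
    """Yield an iterable of lines from a path, file object, string or iterable."""
    if isinstance(source, (str, os.PathLike)):
        with open(source, "rt", encoding="utf-8") as handle:
            yield handle
    elif isinstance(source, io.TextIOBase):
        yield source
    elif hasattr(source, "read"):
        yield source
    else:
        yield iter(source)


@contextmanager
def _as_output(dest) -> Iterator[TextIO]:
    if isinstance(dest, (str, os.PathLike)):
        with open(dest, "wt", encoding="utf-8") as handle:
            yield handle
    else:
        yield dest


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------


def parse_paf(source) -> list[AlignmentRecord]:
    """Parse PAF (12 mandatory tab-separated columns, optional SAM-style tags).

    The ``tp:A:`` tag is honoured when present: ``tp:A:S`` marks a secondary
    alignment; untagged lines default to primary. A line with fewer than 12
    columns or non-integer coordinates raises :class:`MalformedInputError`
    naming the line number.
    """
    records: list[AlignmentRecord] = []
    with _as_lines(source) as lines:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise MalformedInputError(
                    f"PAF line {lineno}: expected >=12 columns, found {len(cols)}"
                )
            try:
                read_length = int(cols[1])
                target_length = int(cols[6])
                target_start = int(cols[7])
                target_end = int(cols[8])
                mapping_quality = int(cols[11])
            except ValueError as exc:
                raise MalformedInputError(f"PAF line {lineno}: non-integer coordinate") from exc
            strand = cols[4].replace("−", "-")
            is_primary = True
            for tag in cols[12:]:
                if tag.startswith("tp:A:"):
                    is_primary = tag[5:] != "S"
            if not (0 <= target_start < target_end <= target_length):
                raise MalformedInputError(
                    f"PAF line {lineno}: target span [{target_start}, {target_end}) "
                    f"outside contig of length {target_length}"
                )
            try:
                records.append(
                    AlignmentRecord(
                        read_id=cols[0],
                        read_length=read_length,
                        target_id=cols[5],
                        target_start=target_start,
                        target_end=target_end,
                        strand=strand,
                        is_primary=is_primary,
                        mapping_quality=mapping_quality,
                    )
                )
            except InvalidArgumentError as exc:
                raise MalformedInputError(f"PAF line {lineno}: {exc}") from exc
    return records


def write_paf(records: Iterable[AlignmentRecord], dest) -> None:
    """Write records as minimal valid PAF (round-trips through :func:`parse_paf`).

    The query span is reported as the full read and the target length as
    ``target_end``, the tightest length consistent with the record.
    """
    with _as_output(dest) as out:
        for rec in records:
            span = rec.target_end - rec.target_start
            cols = [
                rec.read_id,
                str(rec.read_length),
                "0",
                str(rec.read_length),
                rec.strand,
                rec.target_id,
                str(rec.target_end),
                str(rec.target_start),
                str(rec.target_end),
                str(span),
                str(span),
                str(rec.mapping_quality),
                "tp:A:P" if rec.is_primary else "tp:A:S",
            ]
            out.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# BED exons
# ---------------------------------------------------------------------------


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting half-open intervals (canonical form)."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def read_exon_bed(source) -> list[ExonInterval]:
    """Read exons from BED; column 4 encodes ``gene_id|orthogroup_id``.

    Within one gene (on one contig) overlapping or abutting intervals are
    merged — equivalent representations for coverage, canonicalized here.
    """
    per_gene: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    order: list[tuple[str, str, str]] = []
    with _as_lines(source) as lines:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise MalformedInputError(f"BED line {lineno}: expected >=4 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise MalformedInputError(f"BED line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise MalformedInputError(
                    f"BED line {lineno}: start {start} >= end {end}"
                )
            name = cols[3]
            if "|" not in name:
                raise MalformedInputError(
                    f"BED line {lineno}: name {name!r} is not 'gene_id|orthogroup_id'"
                )
            gene_id, orthogroup_id = name.split("|", 1)
            key = (cols[0], gene_id, orthogroup_id)
            if key not in per_gene:
                per_gene[key] = []
                order.append(key)
            per_gene[key].append((start, end))
    exons: list[ExonInterval] = []
    for key in order:
        contig_id, gene_id, orthogroup_id = key
        for start, end in _merge_intervals(per_gene[key]):
            exons.append(ExonInterval(contig_id, start, end, gene_id, orthogroup_id))
    return exons


def write_exon_bed(exons: Iterable[ExonInterval], dest) -> None:
    with _as_output(dest) as out:
        for exon in exons:
            out.write(
                f"{exon.contig_id}\t{exon.start}\t{exon.end}\t"
                f"{exon.gene_id}|{exon.orthogroup_id}\n"
            )


# ---------------------------------------------------------------------------
# blast tabular (outfmt 6)
# ---------------------------------------------------------------------------


def parse_blasttab(source) -> list[ProteinHit]:
    """Parse 12-column blast tabular (outfmt 6): qseqid=read, sseqid=protein."""
    hits: list[ProteinHit] = []
    with _as_lines(source) as lines:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise MalformedInputError(
                    f"blast tabular line {lineno}: expected 12 columns, found {len(cols)}"
                )
            try:
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise MalformedInputError(
                    f"blast tabular line {lineno}: non-numeric evalue/bitscore"
                ) from exc
            hits.append(ProteinHit(cols[0], cols[1], bitscore, evalue))
    return hits


# ---------------------------------------------------------------------------
# cutoff tables
# ---------------------------------------------------------------------------


def read_cutoff_tables(
    scores_source,
    lengths_source,
    dialect: CutoffDialect = CutoffDialect(),
) -> dict[str, Cutoffs]:
    """Merge the per-orthogroup score and length cutoff tables.

    Every id must appear in both tables; otherwise the dataset is
    inconsistent and :class:`InconsistentDatasetError` is raised.
    """
    scores: dict[str, float] = {}
    with _as_lines(scores_source) as lines:
        for lineno, raw in enumerate(lines, start=1):
            parts = raw.split()
            if not parts:
                continue
            try:
                scores[parts[dialect.score_id_col]] = float(parts[dialect.score_col])
            except (IndexError, ValueError) as exc:
                raise MalformedInputError(f"scores table line {lineno}: {raw!r}") from exc
    lengths: dict[str, tuple[float, float]] = {}
    with _as_lines(lengths_source) as lines:
        for lineno, raw in enumerate(lines, start=1):
            parts = raw.split()
            if not parts:
                continue
            try:
                lengths[parts[dialect.length_id_col]] = (
                    float(parts[dialect.length_col]),
                    float(parts[dialect.sigma_col]),
                )
            except (IndexError, ValueError) as exc:
                raise MalformedInputError(f"lengths table line {lineno}: {raw!r}") from exc
    only_scores = set(scores) - set(lengths)
    only_lengths = set(lengths) - set(scores)
    if only_scores or only_lengths:
        missing = sorted(only_scores | only_lengths)[:5]
        raise InconsistentDatasetError(
            f"ids present in only one cutoff table: {', '.join(missing)}"
        )
    return {
        og: Cutoffs(og, scores[og], lengths[og][0], lengths[og][1])
        for og in scores
    }


def read_cutoffs_tsv(source) -> dict[str, Cutoffs]:
    """Read the package's own single-file cutoff TSV (header row)."""
    cutoffs: dict[str, Cutoffs] = {}
    with _as_lines(source) as lines:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line or (lineno == 1 and line.startswith("orthogroup_id")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise MalformedInputError(f"cutoffs TSV line {lineno}: expected 4 columns")
            try:
                cutoffs[cols[0]] = Cutoffs(cols[0], float(cols[1]), float(cols[2]), float(cols[3]))
            except ValueError as exc:
                raise MalformedInputError(f"cutoffs TSV line {lineno}: non-numeric value") from exc
    return cutoffs


def write_cutoffs_tsv(cutoffs: Mapping[str, Cutoffs], dest) -> None:
    with _as_output(dest) as out:
        out.write("orthogroup_id\tscore_cutoff\tlength_cutoff\tlength_sigma\n")
        for og in sorted(cutoffs):
            c = cutoffs[og]
            out.write(f"{c.orthogroup_id}\t{c.score_cutoff:g}\t{c.length_cutoff:g}\t{c.length_sigma:g}\n")


# ---------------------------------------------------------------------------
# HMMER3 text profiles
# ---------------------------------------------------------------------------

# Reconstructed per-position sums can drift from 1 by ~5e-6 with HMMER's
# 5-decimal storage; accept up to this and renormalize exactly.
_EMISSION_SUM_TOLERANCE = 1e-3


def _neg_log_to_prob(token: str, context: str) -> float:
    if token == "*":  # HMMER's -ln(0) convention
        return 0.0
    try:
        return math.exp(-float(token))
    except ValueError as exc:
        raise MalformedProfileError(f"{context}: bad emission value {token!r}") from exc


def parse_hmm_profile(source, orthogroup_id: str | None = None):
    """Parse one HMMER3/f text profile into an :class:`~agtuner.catalog.OrthogroupProfile`.

    Match-emission lines store negative natural-log probabilities; they are
    recovered as probabilities (``exp`` of the negated value, ``*`` meaning
    exactly zero) and renormalized, so every returned position sums to 1
    within 1e-6. ``LENG`` and ``NAME`` are honoured; the ``COMPO`` line is
    parsed as the model's average composition but is *not* used as the
    entropy background (see :mod:`agtuner.catalog`).
    """
    from .catalog import OrthogroupProfile  # late import: catalog owns the type

    name = None
    length = None
    compo = None
    emissions: list[np.ndarray] = []
    in_model = False
    pending_skip = 0
    saw_hmm_header = False

    with _as_lines(source) as lines:
        for raw in lines:
            line = raw.rstrip("\n")
            stripped = line.strip()
            if not stripped:
                continue
            if not in_model:
                if stripped.startswith("NAME"):
                    name = stripped.split(maxsplit=1)[1]
                elif stripped.startswith("LENG"):
                    try:
                        length = int(stripped.split()[1])
                    except (IndexError, ValueError) as exc:
                        raise MalformedProfileError(f"bad LENG line: {line!r}") from exc
                elif stripped.startswith("HMM "):
                    in_model = True
                    saw_hmm_header = True
                    pending_skip = 1  # the m->m transition header line
                continue
            if pending_skip > 0:
                pending_skip -= 1
                continue
            if stripped == "//":
                break
            tokens = stripped.split()
            if tokens[0] == "COMPO":
                if len(tokens) < 1 + N_AMINO_ACIDS:
                    raise MalformedProfileError("truncated COMPO line")
                compo = np.array(
                    [_neg_log_to_prob(t, "COMPO") for t in tokens[1 : 1 + N_AMINO_ACIDS]]
                )
                pending_skip = 2  # insert-emission and transition lines
                continue
            try:
                node_index = int(tokens[0])
            except ValueError as exc:
                raise MalformedProfileError(
                    f"expected a node index, found {tokens[0]!r}"
                ) from exc
            if len(tokens) < 1 + N_AMINO_ACIDS:
                raise MalformedProfileError(f"node {node_index}: truncated match-emission line")
            row = np.array(
                [
                    _neg_log_to_prob(t, f"node {node_index}")
                    for t in tokens[1 : 1 + N_AMINO_ACIDS]
                ]
            )
            total = row.sum()
            if abs(total - 1.0) > _EMISSION_SUM_TOLERANCE:
                raise MalformedProfileError(
                    f"node {node_index}: emissions sum to {total:.6f}, not 1"
                )
            emissions.append(row / total)
            pending_skip = 2

    if not saw_hmm_header:
        raise MalformedProfileError("missing HMM section")
    if length is None:
        raise MalformedProfileError("missing LENG line")
    if len(emissions) != length:
        raise MalformedProfileError(
            f"LENG {length} but {len(emissions)} match-emission lines"
        )
    profile_id = orthogroup_id or name
    if not profile_id:
        raise MalformedProfileError("profile has neither NAME nor an explicit id")
    return OrthogroupProfile(
        orthogroup_id=profile_id,
        length=length,
        emissions=np.vstack(emissions),
        compo=compo,
    )


def _prob_to_neg_log(p: float) -> str:
    return "*" if p <= 0.0 else f"{-math.log(p):.5f}"


def write_hmm_profile(profile, dest) -> None:
    """Write a minimal but well-formed HMMER3/f text profile (fixture quality).

    Insert emissions are uniform and transitions are a fixed valid set; only
    the match emissions carry information. The output is accepted by HMMER
    parsers (including pyhmmer) and round-trips through
    :func:`parse_hmm_profile`.
    """
    uniform = _prob_to_neg_log(1.0 / N_AMINO_ACIDS)
    insert_line = "  ".join([uniform] * N_AMINO_ACIDS)
    # m->m m->i m->d i->m i->i d->m d->d as -ln p; rows sum to 1
    trans = [0.9, 0.05, 0.05, 0.5, 0.5, 0.5, 0.5]
    trans_line = "  ".join(f"{-math.log(p):.5f}" for p in trans)
    last_trans_line = "  ".join(
        [f"{-math.log(p):.5f}" for p in [0.95, 0.05]]
        + ["*", f"{-math.log(0.5):.5f}", f"{-math.log(0.5):.5f}", "0.00000", "*"]
    )
    compo = profile.emissions.mean(axis=0)
    with _as_output(dest) as out:
        out.write("HMMER3/f [3.4 | Aug 2023]\n")
        out.write(f"NAME  {profile.orthogroup_id}\n")
        out.write(f"LENG  {profile.length}\n")
        out.write("ALPH  amino\n")
        out.write("RF    no\nMM    no\nCONS  yes\nCS    no\nMAP   yes\n")
        out.write("HMM          " + "        ".join(AMINO_ACIDS) + "\n")
        out.write(
            "            m->m     m->i     m->d     i->m     i->i     d->m     d->d\n"
        )
        out.write("  COMPO   " + "  ".join(_prob_to_neg_log(p) for p in compo) + "\n")
        out.write("          " + insert_line + "\n")
        out.write("          " + trans_line + "\n")
        for i in range(profile.length):
            row = profile.emissions[i]
            out.write(
                f"{i + 1:7d}   "
                + "  ".join(_prob_to_neg_log(p) for p in row)
                + f"      {i + 1} x - - -\n"
            )
            out.write("          " + insert_line + "\n")
            if i == profile.length - 1:
                out.write("          " + last_trans_line + "\n")
            else:
                out.write("          " + trans_line + "\n")
        out.write("//\n")


# ---------------------------------------------------------------------------
# hmmsearch --domtblout (for real-data candidate scoring)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomtblHit:
    """One row of ``hmmsearch --domtblout``: a predicted protein vs an orthogroup HMM."""

    gene_id: str
    orthogroup_id: str
    bitscore: float
    protein_length: int


def read_domtblout(source) -> list[DomtblHit]:
    """Parse hmmsearch ``--domtblout``: target name, target length, query (HMM)
    name and full-sequence bitscore. Comment lines are skipped."""
    hits: list[DomtblHit] = []
    with _as_lines(source) as lines:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 8:
                raise MalformedInputError(f"domtblout line {lineno}: too few columns")
            try:
                hits.append(
                    DomtblHit(
                        gene_id=parts[0],
                        protein_length=int(parts[2]),
                        orthogroup_id=parts[3],
                        bitscore=float(parts[7]),
                    )
                )
            except ValueError as exc:
                raise MalformedInputError(f"domtblout line {lineno}: bad numeric field") from exc
    return hits
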