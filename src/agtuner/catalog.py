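"""Orthogroup dataset model and conservation ranking.

A BUSCO-style dataset ships, per orthogroup, a profile HMM over amino acids,
an ancestral (last-common-ancestor) protein, a bitscore cutoff and a length
cutoff. Assembly-quality evaluation does not need every orthogroup: the most
conserved ones — those whose profiles are *least* surprising relative to a
background composition, i.e. have the least mean positional relative entropy
— are the ones whose genes are reliably found even in diverged genomes, so
they are selected first.

The background distribution defaults to uniform (1/20 per residue). The exact
null model of other toolchains is not standardized, so uniform is the
documented, reproducible choice; pass ``background=`` to override with an
amino-acid frequency table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    InconsistentDatasetError,
    InvalidArgumentError,
    InvalidSplitError,
    UndefinedEntropyError,
)
from . import formats_io
from .formats_io import AMINO_ACIDS, N_AMINO_ACIDS


def uniform_background() -> np.ndarray:
    return np.full(N_AMINO_ACIDS, 1.0 / N_AMINO_ACIDS)


@dataclass
class OrthogroupProfile:
    """One orthogroup's profile: match-state emissions plus dataset metadata.

    ``emissions`` is a ``(length, 20)`` array of per-position probability
    distributions (HMMER column order ``ACDEFGHIKLMNPQRSTVWY``), each row
    summing to 1 within 1e-6.
    """

    orthogroup_id: str
    length: int
    emissions: np.ndarray
    ancestral_protein: str = ""
    score_cutoff: float = 0.0
    length_cutoff: float = 0.0
    length_sigma: float = 0.0
    compo: np.ndarray | None = None

    def __post_init__(self):
        self.emissions = np.asarray(self.emissions, dtype=float)
        if self.length < 1:
            raise InvalidArgumentError(f"profile {self.orthogroup_id}: length < 1")
        if self.emissions.shape != (self.length, N_AMINO_ACIDS):
            raise InvalidArgumentError(
                f"profile {self.orthogroup_id}: emissions shape {self.emissions.shape} "
                f"!= ({self.length}, {N_AMINO_ACIDS})"
            )
        sums = self.emissions.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise InvalidArgumentError(
                f"profile {self.orthogroup_id}: emission rows do not sum to 1"
            )
        if self.score_cutoff < 0:
            raise InvalidArgumentError(f"profile {self.orthogroup_id}: negative score cutoff")


@dataclass
class Catalog:
    """A set of orthogroup profiles plus the background composition."""

    profiles: dict[str, OrthogroupProfile]
    background: np.ndarray = field(default_factory=uniform_background)

    def __post_init__(self):
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise InvalidArgumentError("background does not sum to 1")

    def __len__(self) -> int:
        return len(self.profiles)

    def __contains__(self, orthogroup_id: str) -> bool:
        return orthogroup_id in self.profiles


def mean_positional_relative_entropy(
    profile: OrthogroupProfile, background: np.ndarray | None = None
) -> float:
    """Mean per-position KL divergence (bits) of emissions from the background.

    ``(1/L) * sum_i sum_a p_ia * log2(p_ia / q_a)`` with the ``0*log(0/q)=0``
    convention. Non-negative; zero iff every position equals the background.
    Orthogroups with the *least* mean relative entropy are ranked as the most
    conserved and selected first for assembly-quality evaluation.
    """
    q = uniform_background() if background is None else np.asarray(background, dtype=float)
    p = profile.emissions
    if np.any((p > 0) & (q <= 0)[None, :]):
        raise UndefinedEntropyError(
            f"profile {profile.orthogroup_id}: emission positive where background is zero"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q[None, :]), 0.0)
    return float(terms.sum() / profile.length)


def select_conserved(catalog: Catalog, n: int) -> list[str]:
    """The ``min(n, |catalog|)`` most conserved orthogroup ids.

    Sorted by ascending mean positional relative entropy, ties broken
    lexicographically by id (deterministic across platforms).
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    ranked = sorted(
        catalog.profiles,
        key=lambda og: (
            mean_positional_relative_entropy(catalog.profiles[og], catalog.background),
            og,
        ),
    )
    return ranked[: min(n, len(ranked))]


def split_dataset(catalog: Catalog, n_assembly: int) -> tuple[list[str], list[str]]:
    """Split the catalog into an assembly part and a disjoint testing part.

    The ``n_assembly`` most conserved orthogroups go to the assembly part
    (the ones an optimizer would consume); the remainder forms the testing
    part used to score the final assembly without circularity. The two parts
    partition the catalog.
    """
    if not 1 <= n_assembly < len(catalog):
        raise InvalidSplitError(
            f"n_assembly={n_assembly} must satisfy 1 <= n_assembly < |catalog|={len(catalog)}"
        )
    ranked = select_conserved(catalog, len(catalog))
    return ranked[:n_assembly], ranked[n_assembly:]


def load_catalog(
    dataset_dir,
    background: np.ndarray | None = None,
    dialect: formats_io.CutoffDialect = formats_io.CutoffDialect(),
) -> Catalog:
    """Load a dataset directory: ``hmms/<id>.hmm``, ``ancestral`` FASTA,
    ``scores_cutoff`` and ``lengths_cutoff`` tables.

    Every profile must have cutoffs; ancestral proteins are attached when the
    FASTA is present (ids must match orthogroup ids).
    """
    from Bio import SeqIO

    root = Path(dataset_dir)
    hmm_dir = root / "hmms"
    if not hmm_dir.is_dir():
        raise InconsistentDatasetError(f"no hmms/ directory under {root}")
    cutoffs = formats_io.read_cutoff_tables(
        root / "scores_cutoff", root / "lengths_cutoff", dialect=dialect
    )
    ancestral: dict[str, str] = {}
    ancestral_path = root / "ancestral"
    if ancestral_path.exists():
        for record in SeqIO.parse(str(ancestral_path), "fasta"):
            ancestral[record.id] = str(record.seq)
    profiles: dict[str, OrthogroupProfile] = {}
    for hmm_path in sorted(hmm_dir.glob("*.hmm")):
        profile = formats_io.parse_hmm_profile(hmm_path)
        og = profile.orthogroup_id
        if og not in cutoffs:
            raise InconsistentDatasetError(f"profile {og} has no cutoff entries")
        c = cutoffs[og]
        profiles[og] = replace(
            profile,
            ancestral_protein=ancestral.get(og, ""),
            score_cutoff=c.score_cutoff,
            length_cutoff=c.length_cutoff,
            length_sigma=c.length_sigma,
        )
    return Catalog(
        profiles=profiles,
        background=uniform_background() if background is None else background,
    )
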