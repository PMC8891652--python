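"""Combinatorial library specifications: diversity accounting, parent checks, sampling.

A site-saturation library over a tRNA/aminoacyl-tRNA-synthetase (aaRS) pair is
described position by position: amino-acid positions carry an IUPAC degenerate
codon, single-nucleotide positions (e.g. the tRNA anticodon loop) carry one
IUPAC symbol.  From such a spec this module computes

* per-position codon/nucleotide counts and (stop-aware) amino-acid counts,
* exact DNA-level and expressed (protein)-level total diversities,
* whether the parent residue is reachable at each position,
* uniformly sampled concrete clones, and
* expected library coverage for a given number of transformants.

Totals are exact integers internally; the two-significant-figure presentation
(e.g. ``4.1e+10``) is formatting only.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genetic_code import (
    IUPAC_DNA,
    STANDARD_CODE,
    GeneticCode,
    amino_acid_set,
    expand_degenerate,
)

__all__ = [
    "LibraryPosition",
    "LibrarySpec",
    "PositionDiversity",
    "DiversityReport",
    "Clone",
    "diversity_report",
    "parent_included",
    "sample_clone",
    "expected_coverage",
    "agg_screening_library",
    "format_sig2",
]


def format_sig2(x: float) -> str:
    """Round to two significant figures in scientific notation, e.g. ``4.1e+10``."""
    if x == 0:
        return "0.0"
    return f"{float(x):.1e}"


@dataclass(frozen=True)
class LibraryPosition:
    """One varied (or fixed) position of a combinatorial library.

    ``kind`` is ``"codon"`` for an amino-acid position (three-symbol IUPAC
    degeneracy, single-letter parent amino acid) or ``"nucleotide"`` for a
    single varied nucleotide (one IUPAC symbol, single-letter parent base).
    """

    name: str
    kind: str
    degeneracy: str
    parent: str

    def __post_init__(self):
        if self.kind not in ("codon", "nucleotide"):
            raise ValueError(f"position {self.name!r}: kind must be 'codon' or 'nucleotide'")
        deg = self.degeneracy.upper().replace("U", "T")
        want = 3 if self.kind == "codon" else 1
        if len(deg) != want:
            raise ValueError(
                f"position {self.name!r}: a {self.kind} position needs {want} IUPAC "
                f"symbol(s), got {self.degeneracy!r}"
            )
        for ch in deg:
            if ch not in IUPAC_DNA:
                raise ValueError(
                    f"position {self.name!r}: invalid IUPAC symbol {ch!r} in {self.degeneracy!r}"
                )
        object.__setattr__(self, "degeneracy", deg)
        object.__setattr__(self, "parent", self.parent.upper().replace("U", "T")
                           if self.kind == "nucleotide" else self.parent.upper())
        if len(self.parent) != 1:
            raise ValueError(f"position {self.name!r}: parent must be a single symbol")

    def options(self) -> tuple[str, ...]:
        """Concrete codons (or nucleotides) available at this position."""
        if self.kind == "codon":
            return expand_degenerate(self.degeneracy)
        return tuple(sorted(IUPAC_DNA[self.degeneracy]))


@dataclass(frozen=True)
class LibrarySpec:
    """An ordered collection of library positions with an optional name."""

    positions: tuple[LibraryPosition, ...]
    name: str = "library"

    def __post_init__(self):
        object.__setattr__(self, "positions", tuple(self.positions))
        if not self.positions:
            raise ValueError("library spec must contain at least one position")

    def codon_positions(self) -> tuple[LibraryPosition, ...]:
        return tuple(p for p in self.positions if p.kind == "codon")

    def nucleotide_positions(self) -> tuple[LibraryPosition, ...]:
        return tuple(p for p in self.positions if p.kind == "nucleotide")

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "positions": [
                {"name": p.name, "kind": p.kind, "degeneracy": p.degeneracy, "parent": p.parent}
                for p in self.positions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LibrarySpec":
        try:
            positions = [LibraryPosition(**p) for p in d["positions"]]
        except KeyError as e:
            raise ValueError(f"library spec JSON missing required key: {e}") from None
        return cls(positions=tuple(positions), name=d.get("name", "library"))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LibrarySpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def agg_screening_library() -> LibrarySpec:
    """The packaged anticodon-binding-domain / anticodon-loop library spec.

    Nine aaRS amino-acid positions (230-233, 261, 283-286) varied with
    restricted degenerate codons chosen to retain each parent residue, plus
    three varied tRNA anticodon-loop nucleotides (32, 37, 38; the universally
    conserved U33 is fixed).  DNA-level diversity 4.1e10, expressed-level
    4.1e9 (two significant figures).
    """
    with resources.files("scrkit.data").joinpath("agg_library.json").open() as fh:
        return LibrarySpec.from_dict(json.load(fh))


# -- diversity accounting ---------------------------------------------------


@dataclass(frozen=True)
class PositionDiversity:
    name: str
    kind: str
    degeneracy: str
    n_codons: int          # codon count, or nucleotide count for nucleotide positions
    n_amino_acids: int | None  # None for nucleotide positions
    parent: str
    parent_included: bool


@dataclass(frozen=True)
class DiversityReport:
    """Per-position counts plus exact DNA- and protein-level totals."""

    positions: tuple[PositionDiversity, ...]
    dna_diversity: int
    protein_diversity: int

    @property
    def dna_diversity_2sig(self) -> str:
        return format_sig2(self.dna_diversity)

    @property
    def protein_diversity_2sig(self) -> str:
        return format_sig2(self.protein_diversity)

    def aa_diversity_vector(self) -> tuple[int, ...]:
        """Amino-acid counts over the codon positions, in spec order."""
        return tuple(p.n_amino_acids for p in self.positions if p.kind == "codon")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "position": p.name,
                    "kind": p.kind,
                    "degeneracy": p.degeneracy,
                    "n_codons": p.n_codons,
                    "n_amino_acids": p.n_amino_acids,
                    "parent": p.parent,
                    "parent_included": p.parent_included,
                }
                for p in self.positions
            ]
        )

    def summary(self) -> dict:
        return {
            "dna_diversity": self.dna_diversity,
            "protein_diversity": self.protein_diversity,
            "dna_diversity_2sig": self.dna_diversity_2sig,
            "protein_diversity_2sig": self.protein_diversity_2sig,
            "aa_diversity_vector": list(self.aa_diversity_vector()),
        }


def _position_parent_included(pos: LibraryPosition, code: GeneticCode) -> bool:
    if pos.kind == "nucleotide":
        return pos.parent in IUPAC_DNA[pos.degeneracy]
    return pos.parent in amino_acid_set(pos.degeneracy, code, exclude_stops=False)


def diversity_report(
    spec: LibrarySpec,
    code: GeneticCode = STANDARD_CODE,
    *,
    exclude_stops: bool = True,
) -> DiversityReport:
    """Exact combinatorial diversity of a library spec.

    DNA-level diversity is the product of codon counts over codon positions and
    nucleotide counts over nucleotide positions; protein-level diversity uses
    the distinct amino-acid count per codon position (stops excluded by
    default, the convention for quoting expressed diversity).
    """
    rows = []
    d_dna = 1
    d_protein = 1
    for pos in spec.positions:
        if pos.kind == "codon":
            n_cod = len(expand_degenerate(pos.degeneracy))
            n_aa = len(amino_acid_set(pos.degeneracy, code, exclude_stops=exclude_stops))
            d_dna *= n_cod
            d_protein *= n_aa
        else:
            n_cod = len(IUPAC_DNA[pos.degeneracy])
            n_aa = None
            d_dna *= n_cod
            d_protein *= n_cod
        rows.append(
            PositionDiversity(
                name=pos.name,
                kind=pos.kind,
                degeneracy=pos.degeneracy,
                n_codons=n_cod,
                n_amino_acids=n_aa,
                parent=pos.parent,
                parent_included=_position_parent_included(pos, code),
            )
        )
    return DiversityReport(positions=tuple(rows), dna_diversity=d_dna, protein_diversity=d_protein)


def parent_included(spec: LibrarySpec, code: GeneticCode = STANDARD_CODE) -> dict[str, bool]:
    """Per-position flag: can the degeneracy reproduce the parent residue/base?

    A ``False`` at any position means the designed degeneracy cannot encode the
    stated parent — either a deliberate design choice or an inconsistency in
    the specification (a warning is emitted so it is never silent).
    """
    result = {p.name: _position_parent_included(p, code) for p in spec.positions}
    missing = [name for name, ok in result.items() if not ok]
    if missing:
        warnings.warn(
            f"library {spec.name!r}: parent residue not encodable at position(s) "
            f"{', '.join(missing)}",
            stacklevel=2,
        )
    return result


# -- clone sampling ---------------------------------------------------------


@dataclass(frozen=True)
class Clone:
    """A concrete library member: one chosen codon/nucleotide per position."""

    choices: dict[str, str]     # position name -> concrete codon or nucleotide
    residues: dict[str, str]    # codon positions only: translated amino acid

    def __str__(self) -> str:
        return ";".join(f"{k}={v}" for k, v in self.choices.items())


def sample_clone(
    spec: LibrarySpec,
    seed: int | np.random.Generator | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> Clone:
    """Draw one clone uniformly over each position's expansion, independently.

    Sampling is uniform over *codons*, not amino acids, mirroring
    transformation of a degenerate-oligo library: an amino acid encoded by two
    codons in the expansion is twice as likely as a one-codon amino acid.
    Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    choices: dict[str, str] = {}
    residues: dict[str, str] = {}
    for pos in spec.positions:
        opts = pos.options()
        pick = opts[rng.integers(len(opts))]
        choices[pos.name] = pick
        if pos.kind == "codon":
            residues[pos.name] = code.translate(pick)
    return Clone(choices=choices, residues=residues)


# -- coverage ---------------------------------------------------------------


def expected_coverage(transformants: float, diversity: float, *, method: str = "exact") -> float:
    """Expected fraction of distinct library variants present among transformants.

    Assuming each transformant is an independent uniform draw from ``diversity``
    equally likely variants, the expected occupancy is ``1 - (1 - 1/D)**T``
    (``method="exact"``); the Poisson approximation ``1 - exp(-T/D)``
    (``method="poisson"``) is numerically indistinguishable at library scales
    (D >= 1e6).  This is occupancy, not fold-coverage.
    """
    T = float(transformants)
    D = float(diversity)
    if D <= 0:
        raise ValueError("diversity must be positive")
    if T <= 0:
        raise ValueError("transformant count must be positive")
    if method == "exact":
        # -expm1(T*log1p(-1/D)) is stable for huge D
        return -math.expm1(T * math.log1p(-1.0 / D))
    if method == "poisson":
        return -math.expm1(-T / D)
    raise ValueError(f"unknown coverage method {method!r}")


def enumerate_variants(spec: LibrarySpec, *, limit: int = 10**6) -> Iterable[tuple[str, ...]]:
    """Brute-force cross-product of all positions (guarded by ``limit``).

    Intended for validation against :func:`diversity_report` on small specs.
    """
    total = math.prod(len(p.options()) for p in spec.positions)
    if total > limit:
        raise ValueError(f"spec has {total} variants, above the enumeration limit {limit}")
    return itertools.product(*(p.options() for p in spec.positions))
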