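"""Intact-protein mass accounting for codon-reassignment species.

Fractional reassignment of a sense codon produces full-length protein with
either the canonical residue or the delivered amino acid at the target site;
the two species differ by a fixed residue-mass delta, visible in deconvoluted
intact-protein electrospray spectra.  This module enumerates expected species
masses (site options x optional covalent modifications such as a +14 Da
methylation) and assigns observed neutral-mass peaks to them within a
tolerance.

Masses are *average* masses by default: deconvoluted intact-protein masses at
~8 kDa are average-mass centroids, not monoisotopic peaks (a monoisotopic
table is available via ``average=False``).  Canonical residue masses come from
the standard elemental compositions; the two noncanonical residues are defined
compositionally:

* para-azidophenylalanine (pAzF) = Phe + N3 - H  (azide replaces a ring H)
* para-aminophenylalanine (pAmF) = Phe + NH2 - H (its reduced, amine form)

giving the characteristic shifts at an arginine target site of +7 Da for Tyr,
+32 Da for pAzF and +6 Da for pAmF.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as pmass
from scipy.signal import find_peaks

__all__ = [
    "ResidueMassTable",
    "SpeciesHypothesis",
    "DeconvolutedSpectrum",
    "PeakAssignment",
    "AssignmentResult",
    "AmbiguousAssignmentWarning",
    "residue_delta",
    "protein_average_mass",
    "enumerate_species",
    "assign_peaks",
    "pick_peaks",
    "DEFAULT_TOLERANCE_DA",
]

#: Default peak-matching tolerance.  The species of interest differ by >= 6 Da,
#: so 1.5 Da separates them — except Tyr (+7) vs the amine form of pAzF (+6),
#: which is surfaced as an ambiguity warning rather than silently resolved.
DEFAULT_TOLERANCE_DA = 1.5


def _composition_mass(comp: pmass.Composition, average: bool) -> float:
    return pmass.calculate_mass(composition=comp, average=average)


class ResidueMassTable:
    """Residue masses (Da) for the canonical amino acids plus pAzF and pAmF.

    Keys are one-letter codes for canonical residues and the multi-letter
    symbols ``"pAzF"`` / ``"pAmF"``.  ``modifications`` maps modification
    names to mass deltas; the default carries ``"methyl"`` (+CH2).
    """

    def __init__(self, *, average: bool = True,
                 modifications: Mapping[str, float] | None = None):
        self.average = average
        comps = {aa: c for aa, c in pmass.std_aa_comp.items()
                 if len(aa) == 1 and aa.isalpha()}
        phe = comps["F"]
        comps["pAzF"] = phe + pmass.Composition({"N": 3}) - pmass.Composition({"H": 1})
        comps["pAmF"] = phe + pmass.Composition({"N": 1, "H": 1})
        self._masses = {aa: _composition_mass(c, average) for aa, c in comps.items()}
        self.water = _composition_mass(pmass.Composition("H2O"), average)
        ch2 = _composition_mass(pmass.Composition({"C": 1, "H": 2}), average)
        self.modifications = dict(modifications) if modifications is not None else {
            "methyl": ch2,
        }

    def __getitem__(self, residue: str) -> float:
        try:
            return self._masses[residue]
        except KeyError:
            raise KeyError(
                f"unknown residue symbol {residue!r}; known: "
                f"{sorted(self._masses)}"
            ) from None

    def __contains__(self, residue: str) -> bool:
        return residue in self._masses

    def residues(self) -> tuple[str, ...]:
        return tuple(sorted(self._masses))


def residue_delta(
    from_aa: str,
    to_aa: str,
    table: ResidueMassTable | None = None,
    *,
    rounded: bool = False,
) -> float:
    """Mass shift (Da) of substituting ``from_aa`` by ``to_aa`` at one site.

    >>> round(residue_delta("R", "Y"))
    7
    """
    table = table if table is not None else ResidueMassTable()
    delta = table[to_aa] - table[from_aa]
    return float(round(delta)) if rounded else float(delta)


def protein_average_mass(
    sequence: Sequence[str] | str,
    table: ResidueMassTable | None = None,
) -> float:
    """Intact neutral mass of a linear chain: sum of residue masses plus water.

    ``sequence`` is a plain one-letter string, or an iterable of symbols when
    noncanonical residues (``"pAzF"``, ``"pAmF"``) are present.
    """
    table = table if table is not None else ResidueMassTable()
    return float(sum(table[aa] for aa in sequence) + table.water)


@dataclass(frozen=True)
class SpeciesHypothesis:
    """A candidate protein species: site residue + modifications -> expected mass."""

    label: str
    mass_da: float

    def __str__(self) -> str:
        return f"{self.label} ({self.mass_da:.1f} Da)"


def enumerate_species(
    base_mass_da: float,
    site_options: Sequence[str],
    modifications: Mapping[str, float] | None = None,
    table: ResidueMassTable | None = None,
    *,
    reference_residue: str = "R",
    dedupe_da: float = 0.1,
) -> list[SpeciesHypothesis]:
    """Expected masses for every site residue x modification subset.

    ``base_mass_da`` is the intact mass of the species carrying
    ``reference_residue`` at the target site (supplied by the user when the
    full sequence is not available); each option's mass is the base plus its
    residue delta, plus the sum over each subset of the modification deltas.
    Hypotheses closer than ``dedupe_da`` are merged (first label wins).
    Sorted by mass.
    """
    if not site_options:
        raise ValueError("need at least one site option")
    table = table if table is not None else ResidueMassTable()
    mods = dict(modifications) if modifications is not None else {}
    out: list[SpeciesHypothesis] = []
    for aa in site_options:
        m0 = base_mass_da + residue_delta(reference_residue, aa, table)
        mod_names = list(mods)
        for r in range(len(mod_names) + 1):
            for subset in itertools.combinations(mod_names, r):
                label = aa if not subset else aa + "+" + "+".join(subset)
                out.append(SpeciesHypothesis(label, m0 + sum(mods[s] for s in subset)))
    out.sort(key=lambda h: (h.mass_da, h.label))
    deduped: list[SpeciesHypothesis] = []
    for h in out:
        if deduped and abs(h.mass_da - deduped[-1].mass_da) < dedupe_da:
            continue
        deduped.append(h)
    return deduped


@dataclass(frozen=True)
class DeconvolutedSpectrum:
    """Neutral-mass peak list (or profile) from charge-state deconvolution."""

    mass_da: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mass_da, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if len(m) != len(i):
            raise ValueError("mass and intensity arrays must have equal length")
        if np.any(np.diff(m) <= 0):
            raise ValueError("masses must be strictly increasing")
        if np.any(i < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "mass_da", m)
        object.__setattr__(self, "intensity", i)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DeconvolutedSpectrum":
        df = pd.read_csv(path)
        missing = [c for c in ("mass_da", "intensity") if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
        df = df.sort_values("mass_da")
        return cls(df["mass_da"].to_numpy(), df["intensity"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"mass_da": self.mass_da, "intensity": self.intensity}).to_csv(
            path, index=False
        )


class AmbiguousAssignmentWarning(UserWarning):
    """More than one hypothesis lies within tolerance of the same peak."""


@dataclass(frozen=True)
class PeakAssignment:
    peak_mass_da: float
    peak_intensity: float
    hypothesis: SpeciesHypothesis
    delta_da: float          # peak - hypothesis
    ambiguous: bool = False


@dataclass(frozen=True)
class AssignmentResult:
    assignments: tuple[PeakAssignment, ...]
    unassigned: tuple[tuple[float, float], ...]   # (mass, intensity)

    def species_abundance(self) -> dict[str, float]:
        """Assigned intensity per species over total assigned intensity.

        Semi-quantitative: electrospray response is assumed equal across
        species, which holds only approximately for single-residue variants.
        """
        totals: dict[str, float] = {}
        for a in self.assignments:
            totals[a.hypothesis.label] = totals.get(a.hypothesis.label, 0.0) + a.peak_intensity
        grand = sum(totals.values())
        if grand <= 0:
            return {}
        return {k: v / grand for k, v in sorted(totals.items())}


def pick_peaks(
    spectrum: DeconvolutedSpectrum,
    *,
    min_rel_intensity: float = 0.05,
) -> DeconvolutedSpectrum:
    """Reduce a gridded profile spectrum to local-maximum centroids.

    Keeps local maxima above ``min_rel_intensity`` of the base peak.  A
    spectrum that is already a sparse peak list passes through unchanged in
    the common case (every point a local maximum).
    """
    inten = spectrum.intensity
    if len(inten) < 3:
        return spectrum
    floor = min_rel_intensity * float(inten.max())
    idx, _ = find_peaks(inten, height=floor)
    # end points can be maxima too
    ends = [i for i in (0, len(inten) - 1)
            if inten[i] >= floor and inten[i] >= inten[1 if i == 0 else -2]]
    keep = np.unique(np.concatenate([idx, np.asarray(ends, dtype=int)])) if len(idx) or ends \
        else np.array([], dtype=int)
    return DeconvolutedSpectrum(spectrum.mass_da[keep], inten[keep])


def assign_peaks(
    spectrum: DeconvolutedSpectrum,
    hypotheses: Sequence[SpeciesHypothesis],
    tolerance_da: float = DEFAULT_TOLERANCE_DA,
) -> AssignmentResult:
    """Match each peak to the nearest hypothesis within tolerance.

    Distance ties break toward the lower-mass hypothesis.  Peaks with no
    hypothesis in range are listed as unassigned (never fatal).  When two or
    more hypotheses fall within tolerance of one peak the assignment is
    flagged ambiguous and an :class:`AmbiguousAssignmentWarning` is emitted —
    mass alone cannot separate species closer than the tolerance (e.g. a +7 Da
    and a +6 Da species), which is why +/- ncAA control spectra matter.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance must be positive")
    if not hypotheses:
        raise ValueError("need at least one species hypothesis")
    hyps = sorted(hypotheses, key=lambda h: h.mass_da)
    hyp_masses = np.array([h.mass_da for h in hyps])

    assignments: list[PeakAssignment] = []
    unassigned: list[tuple[float, float]] = []
    for m, inten in zip(spectrum.mass_da, spectrum.intensity):
        dist = np.abs(hyp_masses - m)
        in_range = np.flatnonzero(dist <= tolerance_da)
        if in_range.size == 0:
            unassigned.append((float(m), float(inten)))
            continue
        # argmin over sorted-by-mass hypotheses: ties go to the lower mass
        best = int(in_range[np.argmin(dist[in_range])])
        ambiguous = in_range.size > 1
        if ambiguous:
            labels = ", ".join(hyps[i].label for i in in_range)
            warnings.warn(
                f"peak at {m:.1f} Da matches multiple hypotheses within "
                f"{tolerance_da} Da: {labels}",
                AmbiguousAssignmentWarning,
                stacklevel=2,
            )
        assignments.append(
            PeakAssignment(
                peak_mass_da=float(m),
                peak_intensity=float(inten),
                hypothesis=hyps[best],
                delta_da=float(m - hyps[best].mass_da),
                ambiguous=ambiguous,
            )
        )
    return AssignmentResult(tuple(assignments), tuple(unassigned))
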