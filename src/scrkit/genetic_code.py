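"""Codon/anticodon algebra: IUPAC degenerate expansion, translation, and wobble decoding.

Combinatorial mutagenesis libraries are written with IUPAC ambiguity symbols
(e.g. ``NHH`` or ``KMT``), each symbol standing for a set of nucleotides.  This
module expands such degenerate triplets into concrete codons, translates them
under the standard genetic code, and converts between codons and tRNA
anticodons, including the classical wobble rules that let a single anticodon
read more than one codon at the third codon position.

Conventions
-----------
* Codons are held in the DNA alphabet (``T``); anticodons in the RNA alphabet
  (``U``).  Either alphabet is accepted on input and normalised.
* Anticodons are written 5'->3' (tRNA positions 34-35-36); position 34 is the
  wobble position and pairs with codon position 3.
* Outputs are always concrete, lexicographically sorted sets — ambiguity
  symbols never appear on output.
"""

from __future__ import annotations

import itertools
from typing import FrozenSet, Iterable, Mapping

from Bio.Data import CodonTable, IUPACData

__all__ = [
    "STOP",
    "IUPAC_DNA",
    "CRICK_WOBBLE_34",
    "GeneticCode",
    "STANDARD_CODE",
    "expand_degenerate",
    "amino_acid_set",
    "anticodon_to_codon",
    "codon_to_anticodon",
    "wobble_codons",
]

STOP = "*"

#: IUPAC nucleotide ambiguity symbols mapped to their concrete DNA base sets
#: (the 15 standard symbols; the non-standard alias ``X`` is excluded).
IUPAC_DNA: Mapping[str, FrozenSet[str]] = {
    sym: frozenset(bases)
    for sym, bases in IUPACData.ambiguous_dna_values.items()
    if sym != "X"
}

_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Classical wobble pairing at anticodon position 34: which codon third-position
#: bases (mRNA alphabet) each unmodified anticodon base can read.
CRICK_WOBBLE_34: Mapping[str, tuple[str, ...]] = {
    "G": ("C", "U"),
    "U": ("A", "G"),
    "C": ("G",),
    "A": ("U",),
}

WOBBLE_RULESETS = {"crick": CRICK_WOBBLE_34}


def _normalize(seq: str, *, alphabet: str = "dna", what: str = "sequence") -> str:
    """Uppercase and convert to the requested alphabet; reject junk characters."""
    s = str(seq).strip().upper()
    s = s.replace("U", "T") if alphabet == "dna" else s.replace("T", "U")
    valid = set("ACGT") if alphabet == "dna" else set("ACGU")
    for ch in s:
        if ch not in valid and not (alphabet == "dna" and ch in IUPAC_DNA):
            raise ValueError(f"invalid {alphabet.upper()} symbol {ch!r} in {what} {seq!r}")
    return s


def _check_degenerate(codon: str) -> str:
    s = str(codon).strip().upper().replace("U", "T")
    if len(s) != 3:
        raise ValueError(f"degenerate codon must have exactly 3 symbols, got {codon!r}")
    for ch in s:
        if ch not in IUPAC_DNA:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in degenerate codon {codon!r}")
    return s


def expand_degenerate(codon: str) -> tuple[str, ...]:
    """Expand an IUPAC degenerate triplet into its concrete DNA codons.

    The result is sorted and its length equals the product of the per-symbol
    set sizes (e.g. ``KMT`` -> 2 x 2 x 1 = 4 codons).

    >>> expand_degenerate("KMT")
    ('GAT', 'GCT', 'TAT', 'TCT')
    """
    s = _check_degenerate(codon)
    sets = [sorted(IUPAC_DNA[ch]) for ch in s]
    return tuple("".join(p) for p in itertools.product(*sets))


class GeneticCode:
    """A total map from the 64 concrete DNA codons to amino acids (``*`` = stop)."""

    def __init__(self, table: Mapping[str, str]):
        mapping = { _normalize(c, what="codon"): aa for c, aa in table.items() }
        if len(mapping) != 64:
            raise ValueError(f"genetic code must define all 64 codons, got {len(mapping)}")
        self._table = dict(mapping)

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard genetic code (3 stop codons)."""
        tab = CodonTable.unambiguous_dna_by_name["Standard"]
        table = dict(tab.forward_table)
        for stop in tab.stop_codons:
            table[stop] = STOP
        return cls(table)

    def translate(self, codon: str) -> str:
        """One-letter amino acid (or ``*``) for a concrete codon; T/U both accepted."""
        return self._table[_normalize(codon, what="codon")]

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == STOP

    def __getitem__(self, codon: str) -> str:
        return self.translate(codon)

    def items(self):
        return self._table.items()

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self._table.items() if aa == STOP)


STANDARD_CODE = GeneticCode.standard()


def amino_acid_set(
    codon: str,
    code: GeneticCode = STANDARD_CODE,
    *,
    exclude_stops: bool = True,
) -> frozenset[str]:
    """Distinct amino acids encoded by a degenerate codon's expansion.

    Stops are excluded by default, which is the convention used when quoting
    the "amino acid diversity" of a library position (``NHH`` encodes 15 amino
    acids plus the TAA stop; its diversity is quoted as 15).
    """
    aas = {code.translate(c) for c in expand_degenerate(codon)}
    if exclude_stops:
        aas.discard(STOP)
    return frozenset(aas)


def anticodon_to_codon(anticodon: str) -> str:
    """The codon a tRNA anticodon reads by Watson-Crick pairing, as mRNA 5'->3'.

    >>> anticodon_to_codon("CCU")
    'AGG'
    """
    ac = _normalize(anticodon, alphabet="rna", what="anticodon")
    if len(ac) != 3:
        raise ValueError(f"anticodon must have exactly 3 nucleotides, got {anticodon!r}")
    dna = ac.replace("U", "T")
    codon_dna = "".join(_DNA_COMPLEMENT[b] for b in reversed(dna))
    return codon_dna.replace("T", "U")


def codon_to_anticodon(codon: str) -> str:
    """The Watson-Crick anticodon (5'->3', RNA) for a concrete codon.

    Inverse of :func:`anticodon_to_codon`.
    """
    c = _normalize(codon, what="codon")
    if len(c) != 3 or any(ch not in "ACGT" for ch in c):
        raise ValueError(f"codon must be a concrete triplet, got {codon!r}")
    ac_dna = "".join(_DNA_COMPLEMENT[b] for b in reversed(c))
    return ac_dna.replace("T", "U")


def wobble_codons(anticodon: str, ruleset: str = "crick") -> tuple[str, ...]:
    """All codons an anticodon can read under a wobble ruleset (mRNA 5'->3').

    The first two codon positions pair strictly Watson-Crick with anticodon
    positions 36 and 35; codon position 3 expands according to the wobble rule
    for anticodon position 34.  Under the classical rules an unmodified U34
    reads both A and G at codon position 3 (the G/U wobble), G34 reads C and U,
    while C34 and A34 are strict.

    >>> wobble_codons("UCU")
    ('AGA', 'AGG')
    """
    try:
        rules = WOBBLE_RULESETS[ruleset]
    except KeyError:
        raise ValueError(
            f"unknown wobble ruleset {ruleset!r}; available: {sorted(WOBBLE_RULESETS)}"
        ) from None
    ac = _normalize(anticodon, alphabet="rna", what="anticodon")
    if len(ac) != 3:
        raise ValueError(f"anticodon must have exactly 3 nucleotides, got {anticodon!r}")
    wc = anticodon_to_codon(ac)
    return tuple(sorted(wc[:2] + third for third in rules[ac[0]]))
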