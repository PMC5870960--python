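"""Standard genetic code bookkeeping.

Every codon-usage statistic in this package is anchored on one immutable
description of the standard nuclear code: the codon -> amino-acid map, the
synonymous families, each family's degeneracy class (2, 3, 4 or 6 codons),
and the codons excluded from synonymous-usage statistics — the three stop
codons plus the two single-codon amino acids Met (ATG) and Trp (TGG).

Codons are handled internally in the DNA alphabet; reports print them in
RNA form (see :func:`to_rna`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from Bio.Data import CodonTable

BASES = "ACGT"

#: The 64 codons in lexicographic DNA order; fixes the layout of every
#: 64-long count vector in the package.
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

CODON_INDEX: Mapping[str, int] = MappingProxyType({c: i for i, c in enumerate(CODONS)})

STOP_SYMBOL = "*"


def to_rna(codon: str) -> str:
    """Render a DNA codon in the RNA alphabet (T -> U) for display."""
    return codon.upper().replace("T", "U")


def to_dna(codon: str) -> str:
    """Normalize a codon to the internal DNA alphabet (U -> T, upper-case)."""
    return codon.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """The standard nuclear genetic code with synonymous-family structure.

    Attributes
    ----------
    codon_to_aa
        All 64 DNA codons mapped to one-letter amino acids, stops to ``"*"``.
    families
    	Amino acid -> alphabetically ordered tuple of its codons.
    degeneracy
        Amino acid -> family size (1, 2, 3, 4 or 6 in the standard code).
    stop_codons
        The three stop triplets.
    """

    codon_to_aa: Mapping[str, str]
    families: Mapping[str, tuple[str, ...]]
    degeneracy: Mapping[str, int]
    stop_codons: frozenset[str]
    _syn_set: frozenset[str] = field(repr=False, default=frozenset())

    @classmethod
    def standard(cls) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[1]
        stops = frozenset(table.stop_codons)
        codon_to_aa = {c: table.forward_table[c] for c in CODONS if c not in stops}
        fams: dict[str, list[str]] = {}
        for codon in CODONS:
            if codon in stops:
                continue
            fams.setdefault(codon_to_aa[codon], []).append(codon)
        families = {aa: tuple(sorted(cs)) for aa, cs in sorted(fams.items())}
        degeneracy = {aa: len(cs) for aa, cs in families.items()}
        full = dict(codon_to_aa)
        full.update({c: STOP_SYMBOL for c in stops})
        syn = frozenset(
            c for aa, cs in families.items() if len(cs) >= 2 for c in cs
        )
        return cls(
            codon_to_aa=MappingProxyType(full),
            families=MappingProxyType(families),
            degeneracy=MappingProxyType(degeneracy),
            stop_codons=stops,
            _syn_set=syn,
        )

    # -- derived views -------------------------------------------------

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """The 61 non-stop codons, lexicographic order."""
        return tuple(c for c in CODONS if c not in self.stop_codons)

    @property
    def synonymous_codons(self) -> tuple[str, ...]:
        """The 59 codons of multi-codon amino acids (Met, Trp, stops excluded)."""
        return tuple(c for c in CODONS if c in self._syn_set)

    @property
    def single_codon_aas(self) -> tuple[str, ...]:
        return tuple(aa for aa, k in self.degeneracy.items() if k == 1)

    def family_of(self, codon: str) -> tuple[str, ...]:
        """Synonymous family containing ``codon`` (raises for stop codons)."""
        aa = self.codon_to_aa[codon]
        if aa == STOP_SYMBOL:
            raise KeyError(f"{codon} is a stop codon and belongs to no family")
        return self.families[aa]

    def degeneracy_of(self, codon: str) -> int:
        return len(self.family_of(codon))

    def is_synonymous(self, codon: str) -> bool:
        """True for codons of families with >= 2 members."""
        return codon in self._syn_set


#: Module-level singleton; the code never changes within a run.
STANDARD_CODE = GeneticCode.standard()
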