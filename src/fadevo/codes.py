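"""Genetic code tables and their synonymous-family structure.

Everything downstream — RSCU, ENc, GC3s, NG86 site counting, the GY94
simulator — is parameterized by a :class:`GeneticCode`.  Two NCBI translation
tables matter here: table 1 (standard) and table 6 (ciliate nuclear, used by
*Tetrahymena*), under which TAA and TAG encode glutamine and only TGA is a
stop.  A "synonymous family" is the set of sense codons encoding one amino
acid; its size is the degeneracy k (1, 2, 3, 4 or 6 for these tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Dict, List, Mapping, Tuple

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
STOP = "*"

#: All 64 codons in lexicographic (A<C<G<T) order.
ALL_CODONS: Tuple[str, ...] = tuple("".join(p) for p in product(NUCLEOTIDES, repeat=3))


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map plus derived synonymous-family structure.

    Attributes
    ----------
    table_id:
        NCBI translation table number (1 = standard, 6 = ciliate nuclear).
    codon_to_aa:
        Map over all 64 codons; stop codons map to ``"*"``.
    families:
        Amino acid -> tuple of its sense codons (sorted), partitioning the
        sense codons.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    families: Mapping[str, Tuple[str, ...]]
    name: str = field(default="", compare=False)

    # ------------------------------------------------------------------ #

    @property
    def sense_codons(self) -> Tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] != STOP)

    @property
    def stop_codons(self) -> Tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] == STOP)

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == STOP

    def translate_codon(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def family_of(self, codon: str) -> Tuple[str, ...]:
        """The synonymous family (tuple of codons) containing *codon*."""
        aa = self.codon_to_aa[codon]
        if aa == STOP:
            raise ValueError(f"{codon} is a stop codon under table {self.table_id}")
        return self.families[aa]

    def degeneracy(self, codon: str) -> int:
        return len(self.family_of(codon))

    def degeneracy_classes(self) -> Dict[int, List[str]]:
        """Map degeneracy k -> list of amino acids whose family has size k."""
        out: Dict[int, List[str]] = {}
        for aa, fam in self.families.items():
            out.setdefault(len(fam), []).append(aa)
        for aas in out.values():
            aas.sort()
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneticCode(table_id={self.table_id}, name={self.name!r})"


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 1) -> GeneticCode:
    """Build a :class:`GeneticCode` from an NCBI translation table.

    >>> genetic_code(6).translate_codon("TAA")
    'Q'
    """
    try:
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError as exc:
        raise ValueError(f"unknown NCBI translation table id {table_id}") from exc
    codon_to_aa = {}
    for codon in ALL_CODONS:
        if codon in tbl.stop_codons:
            codon_to_aa[codon] = STOP
        else:
            codon_to_aa[codon] = tbl.forward_table[codon]
    families: Dict[str, List[str]] = {}
    for codon in ALL_CODONS:
        aa = codon_to_aa[codon]
        if aa != STOP:
            families.setdefault(aa, []).append(codon)
    frozen = {aa: tuple(sorted(cods)) for aa, cods in families.items()}
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        families=frozen,
        name=tbl.names[0] if tbl.names else "",
    )


#: Convenient aliases for the two tables this package is used with.
STANDARD_CODE_ID = 1
CILIATE_CODE_ID = 6
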