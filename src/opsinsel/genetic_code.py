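"""Genetic code tables for codon models.

The standard (vertebrate nuclear) code is the default everywhere; alternative
codes can be injected for testing. Sense codons are kept in a fixed
lexicographic order over {A, C, G, T} so that every rate matrix, frequency
vector and likelihood in the package is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

NUCLEOTIDES = "ACGT"

#: IUPAC ambiguity codes expanded to the plain bases they may stand for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT",
}

_STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: the sense-codon state space of every codon model.

    ``sense_codons`` is lexicographic over {A, C, G, T}; its order defines
    the row/column order of all 61x61 matrices in the package.
    """

    codon_to_aa: dict[str, str]
    sense_codons: tuple[str, ...] = field(init=False)
    stop_codons: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        all_codons = ["".join(c) for c in product(NUCLEOTIDES, repeat=3)]
        missing = set(all_codons) - set(self.codon_to_aa)
        if missing:
            raise ValueError(f"code table incomplete, missing {sorted(missing)}")
        sense = tuple(c for c in all_codons if self.codon_to_aa[c] != "*")
        stops = frozenset(c for c in all_codons if self.codon_to_aa[c] == "*")
        object.__setattr__(self, "sense_codons", sense)
        object.__setattr__(self, "stop_codons", stops)

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def index(self, codon: str) -> int:
        return self.sense_codons.index(codon)

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def expand_ambiguous(self, codon: str) -> list[int]:
        """Sense-codon state indices compatible with an (ambiguous) codon.

        A codon whose every compatible resolution is a stop returns an empty
        list; callers treat that as a validation failure.
        """
        try:
            choices = [IUPAC[b] for b in codon.upper()]
        except KeyError as exc:
            raise ValueError(f"invalid nucleotide {exc} in codon {codon!r}")
        idx = {c: i for i, c in enumerate(self.sense_codons)}
        out = []
        for b1 in choices[0]:
            for b2 in choices[1]:
                for b3 in choices[2]:
                    i = idx.get(b1 + b2 + b3)
                    if i is not None:
                        out.append(i)
        return out


STANDARD_CODE = GeneticCode(codon_to_aa=dict(_STANDARD_TABLE))
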