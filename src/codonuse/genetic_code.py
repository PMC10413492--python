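"""Standard genetic code model and the fixed 64-codon ordering.

Every 64-long vector in this package is indexed by :data:`CODONS`, the
lexicographic ordering of DNA codons over the alphabet (A, C, G, T).  Codons
are always uppercase DNA (T, never U); RNA input is converted at the I/O
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BASES = "ACGT"

#: Fixed codon ordering for all 64-vectors: lexicographic over (A, C, G, T).
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

#: Inverse lookup, codon -> position in :data:`CODONS`.
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

#: Symbol used for translation-stop "amino acid".
STOP = "*"

# Synonymous families of the standard code, each family listed in the
# conventional codon-table order (third base T, C, A, G; two-box families of
# the six-fold amino acids appended last).
_STANDARD_FAMILIES: dict[str, tuple[str, ...]] = {
    "F": ("TTT", "TTC"),
    "L": ("CTT", "CTC", "CTA", "CTG", "TTA", "TTG"),
    "I": ("ATT", "ATC", "ATA"),
    "M": ("ATG",),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "Y": ("TAT", "TAC"),
    "H": ("CAT", "CAC"),
    "Q": ("CAA", "CAG"),
    "N": ("AAT", "AAC"),
    "K": ("AAA", "AAG"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "C": ("TGT", "TGC"),
    "W": ("TGG",),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    STOP: ("TAA", "TAG", "TGA"),
}


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: codon -> amino acid plus synonymous-family structure.

    Attributes
    ----------
    codon_to_aa
        Map from each of the 64 DNA codons to a one-letter amino-acid symbol,
        with ``"*"`` for stop.
    families
        Map from amino acid to its ordered tuple of synonymous codons.
    degeneracy
        Map from amino acid to its family size ``n_i`` (1, 2, 3, 4 or 6 under
        the standard code).
    """

    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]] = field(default=None)  # type: ignore[assignment]
    degeneracy: dict[str, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(CODONS):
            raise ValueError("genetic code must map exactly the 64 DNA codons")
        if self.families is None:
            fams: dict[str, list[str]] = {}
            for codon in CODONS:
                fams.setdefault(self.codon_to_aa[codon], []).append(codon)
            object.__setattr__(
                self, "families", {aa: tuple(v) for aa, v in fams.items()}
            )
        if self.degeneracy is None:
            object.__setattr__(
                self,
                "degeneracy",
                {aa: len(v) for aa, v in self.families.items() if aa != STOP},
            )

    # -- derived views ---------------------------------------------------

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return self.families[STOP]

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """The 61 codons that encode an amino acid, in :data:`CODONS` order."""
        return tuple(c for c in CODONS if self.codon_to_aa[c] != STOP)

    @property
    def synonymous_sense_codons(self) -> tuple[str, ...]:
        """Sense codons excluding the single-codon families (Met, Trp): 59."""
        return tuple(
            c
            for c in self.sense_codons
            if self.degeneracy[self.codon_to_aa[c]] > 1
        )

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == STOP

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard nuclear/plastid genetic code (NCBI table 11 sense
        assignments equal table 1 for chloroplast CDS)."""
        codon_to_aa = {
            codon: aa for aa, fam in _STANDARD_FAMILIES.items() for codon in fam
        }
        fams = {aa: tuple(f) for aa, f in _STANDARD_FAMILIES.items()}
        deg = {aa: len(f) for aa, f in _STANDARD_FAMILIES.items() if aa != STOP}
        return cls(codon_to_aa=codon_to_aa, families=fams, degeneracy=deg)


#: Module-level singleton; the standard code is the only one shipped.
STANDARD_CODE = GeneticCode.standard()

#: Degeneracy classes used by Wright's effective-number-of-codons estimator:
#: class size -> number of amino-acid families of that size in the standard code.
DEGENERACY_CLASS_SIZES = {1: 2, 2: 9, 3: 1, 4: 5, 6: 3}
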