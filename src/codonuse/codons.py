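"""Codon counting and positional base composition.

These are the substrate operations for every downstream index: a CDS is
reduced to a 64-long count vector (fixed lexicographic codon order, see
:mod:`codonuse.genetic_code`), and GC/base fractions by codon position are
computed from counts alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import AlphabetError, EmptyInputError, FrameError, UndefinedMetricError
from .genetic_code import CODON_INDEX, CODONS, STOP, GeneticCode, STANDARD_CODE

_VALID = frozenset("ACGT")

#: Amino acids whose third positions enter the classical PR2 construction:
#: the four-fold degenerate families, where the third base is free of
#: amino-acid constraint.
FOURFOLD_AMINO_ACIDS = ("A", "G", "P", "T", "V")


@dataclass
class CodonCountVector:
    """64 non-negative codon counts for one gene or a pooled scope."""

    scope: str
    counts: np.ndarray  # shape (64,), integer

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (64,):
            raise ValueError("counts must be a 64-long vector")
        if (arr < 0).any():
            raise ValueError("codon counts must be non-negative")
        self.counts = arr

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, codon: str) -> int:
        return int(self.counts[CODON_INDEX[codon.upper()]])

    def as_dict(self, nonzero_only: bool = False) -> dict[str, int]:
        d = {c: int(n) for c, n in zip(CODONS, self.counts)}
        if nonzero_only:
            d = {c: n for c, n in d.items() if n}
        return d

    def __add__(self, other: "CodonCountVector") -> "CodonCountVector":
        return CodonCountVector(scope="pooled", counts=self.counts + other.counts)

    @classmethod
    def zeros(cls, scope: str = "empty") -> "CodonCountVector":
        return cls(scope=scope, counts=np.zeros(64, dtype=np.int64))


def count_codons(sequence: str, scope: str = "gene") -> CodonCountVector:
    """Count codons in a frame-locked CDS.

    The reading frame is fixed at the first base; the sequence length must be
    a multiple of three and the alphabet strictly A/C/G/T (case-insensitive).
    Quality control upstream guarantees clean input, so ambiguity codes raise
    rather than being skipped silently.
    """
    seq = sequence.upper()
    if len(seq) % 3:
        raise FrameError(
            f"sequence length {len(seq)} is not a multiple of 3 ({scope})"
        )
    if not _VALID.issuperset(seq):
        bad = sorted(set(seq) - _VALID)
        raise AlphabetError(f"non-ACGT symbol(s) {bad} in sequence ({scope})")
    counts = np.zeros(64, dtype=np.int64)
    for i in range(0, len(seq), 3):
        counts[CODON_INDEX[seq[i : i + 3]]] += 1
    return CodonCountVector(scope=scope, counts=counts)


def aggregate_counts(per_gene: Sequence[CodonCountVector]) -> CodonCountVector:
    """Element-wise sum of per-gene vectors, scope ``"pooled"``."""
    if not per_gene:
        raise EmptyInputError("aggregate_counts needs at least one vector")
    total = np.zeros(64, dtype=np.int64)
    for v in per_gene:
        total += v.counts
    return CodonCountVector(scope="pooled", counts=total)


@dataclass(frozen=True)
class PositionalComposition:
    """GC and base fractions by codon position.

    ``gc1``/``gc2``/``gc3`` are computed over all codons of the CDS including
    the stop codon (matching the cusp convention).  ``gc3s`` is the GC
    fraction at third positions of synonymous codons only — Met, Trp and
    stops excluded — and is NaN when no such codon occurs.  ``a3``..``c3``
    are third-position base fractions over the PR2 codon set in force when
    the composition was computed.
    """

    gc1: float
    gc2: float
    gc3: float
    gc3s: float
    a3: float
    t3: float
    g3: float
    c3: float

    @property
    def gc_mean(self) -> float:
        return (self.gc1 + self.gc2 + self.gc3) / 3.0

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2.0

    @property
    def gc3s_defined(self) -> bool:
        return not math.isnan(self.gc3s)


def _position_base_counts(counts: np.ndarray, position: int) -> dict[str, int]:
    out = {b: 0 for b in "ACGT"}
    for codon, n in zip(CODONS, counts):
        if n:
            out[codon[position]] += int(n)
    return out


def positional_composition(
    counts: CodonCountVector,
    code: GeneticCode = STANDARD_CODE,
    pr2_codon_set: str = "fourfold",
) -> PositionalComposition:
    """Positional GC content and third-position base fractions.

    Parameters
    ----------
    pr2_codon_set
        ``"fourfold"`` (default) restricts the a3/t3/g3/c3 fractions to third
        positions of the four-fold degenerate amino-acid families, the
        classical parity-rule-2 construction; ``"all"`` uses every sense
        codon.
    """
    if counts.total == 0:
        raise UndefinedMetricError(
            f"positional composition undefined for zero counts ({counts.scope})"
        )
    if pr2_codon_set not in ("fourfold", "all"):
        raise ValueError("pr2_codon_set must be 'fourfold' or 'all'")

    total = counts.total
    gc = []
    for pos in range(3):
        by_base = _position_base_counts(counts.counts, pos)
        gc.append((by_base["G"] + by_base["C"]) / total)

    # GC3s: third positions of synonymous sense codons (Met/Trp/stop excluded)
    syn = set(code.synonymous_sense_codons)
    syn_n = gc3_n = 0
    for codon, n in zip(CODONS, counts.counts):
        if n and codon in syn:
            syn_n += int(n)
            if codon[2] in "GC":
                gc3_n += int(n)
    gc3s = gc3_n / syn_n if syn_n else math.nan

    # PR2 third-position base fractions
    if pr2_codon_set == "fourfold":
        pr2_codons = {
            c for aa in FOURFOLD_AMINO_ACIDS for c in code.families[aa]
        }
    else:
        pr2_codons = set(code.sense_codons)
    base3 = {b: 0 for b in "ACGT"}
    for codon, n in zip(CODONS, counts.counts):
        if n and codon in pr2_codons:
            base3[codon[2]] += int(n)
    pr2_total = sum(base3.values())
    if pr2_total:
        a3, t3, g3, c3 = (base3[b] / pr2_total for b in "ATGC")
    else:
        a3 = t3 = g3 = c3 = math.nan

    return PositionalComposition(
        gc1=gc[0], gc2=gc[1], gc3=gc[2], gc3s=gc3s, a3=a3, t3=t3, g3=g3, c3=c3
    )
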