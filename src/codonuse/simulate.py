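"""Synthetic CDS sets with known codon-usage structure.

Every pipeline stage is testable offline against sequences whose usage
model is known exactly.  A :class:`UsageModel` holds, per amino acid, a
target codon distribution; the effective sampling distribution mixes the
uniform family distribution (selection strength 0) with the target
(strength 1).  Genes are built as ATG + random amino acids + one stop, so a
clean model never produces internal stops or frame problems, and the
default length range (101–1000 codons, i.e. 303–3000 bp) keeps every gene
past the 300 bp acceptance rule.

Two factory models matter most:

* :func:`mutation_only_model` — third-position base usage set purely by a
  GC3 parameter, the null hypothesis of the ENc-plot;
* :func:`at_preference_model` — each family's A/T-ending codons favoured,
  emulating an AT-rich chloroplast genome.  At the default selection
  strength 0.6 and uniform amino-acid usage the expected overall GC3 is
  (2 + 9·(1−s))/20 ≈ 0.28, the level typical of these genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ModelError
from .genetic_code import CODONS, STOP, GeneticCode, STANDARD_CODE
from .seqio import CdsRecord


#: Rough amino-acid composition of plastid-encoded proteins (fractions),
#: available as a more realistic alternative to the uniform default.
PLANT_LIKE_AA = {
    "A": 0.055, "R": 0.050, "N": 0.045, "D": 0.040, "C": 0.012, "Q": 0.040,
    "E": 0.050, "G": 0.070, "H": 0.022, "I": 0.075, "L": 0.105, "K": 0.045,
    "M": 0.025, "F": 0.065, "P": 0.045, "S": 0.075, "T": 0.050, "W": 0.020,
    "Y": 0.035, "V": 0.066,
}


@dataclass
class UsageModel:
    """Parameterised per-amino-acid codon distribution.

    ``target_probs`` maps each amino acid to a probability vector over its
    family (family order of the genetic code); the effective distribution is
    ``(1 − s) · uniform + s · target`` with ``s = selection_strength``.
    ``aa_probs`` (uniform over the 20 amino acids by default) governs
    internal positions; genes always start with Met and end with one stop
    codon drawn from ``stop_probs``.
    """

    target_probs: dict[str, np.ndarray]
    selection_strength: float = 1.0
    length_range: tuple[int, int] = (101, 1000)  # codons incl. start and stop
    aa_probs: dict[str, float] | None = None
    stop_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    code: GeneticCode = field(default_factory=lambda: STANDARD_CODE)

    def __post_init__(self) -> None:
        if not 0.0 <= self.selection_strength <= 1.0:
            raise ModelError("selection_strength must lie in [0, 1]")
        if self.length_range[0] <= 100 or self.length_range[0] > self.length_range[1]:
            raise ModelError(
                "length range must satisfy 100 < min <= max (codons), so every "
                "clean gene clears the 300 bp rule"
            )
        for aa, probs in self.target_probs.items():
            p = np.asarray(probs, dtype=float)
            fam = self.code.families[aa]
            if p.shape != (len(fam),) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ModelError(f"target probabilities for {aa} are not a distribution")
            self.target_probs[aa] = p
        if self.aa_probs is not None:
            tot = sum(self.aa_probs.values())
            if abs(tot - 1.0) > 1e-6 or min(self.aa_probs.values()) < 0:
                raise ModelError("aa_probs must be a distribution over amino acids")

    # -- effective distributions ----------------------------------------

    def effective_probs(self, aa: str) -> np.ndarray:
        fam = self.code.families[aa]
        uniform = np.full(len(fam), 1.0 / len(fam))
        s = self.selection_strength
        return (1.0 - s) * uniform + s * self.target_probs[aa]

    def _aa_items(self) -> tuple[list[str], np.ndarray]:
        if self.aa_probs is None:
            aas = sorted(self.code.degeneracy)
            return aas, np.full(len(aas), 1.0 / len(aas))
        aas = sorted(self.aa_probs)
        return aas, np.array([self.aa_probs[a] for a in aas])

    def expected_gc3(self) -> float:
        """Expected pooled third-position GC of a generated set (start, stop
        and length distribution included)."""
        aas, pa = self._aa_items()
        q_internal = 0.0
        for aa, w in zip(aas, pa):
            probs = self.effective_probs(aa)
            gc = sum(
                p for p, codon in zip(probs, self.code.families[aa]) if codon[2] in "GC"
            )
            q_internal += w * gc
        q_stop = sum(
            p
            for p, codon in zip(self.stop_probs, self.code.families[STOP])
            if codon[2] in "GC"
        )
        mean_len = (self.length_range[0] + self.length_range[1]) / 2.0
        return (1.0 + (mean_len - 2.0) * q_internal + q_stop) / mean_len

    # -- plain-text round trip -------------------------------------------

    def to_config_text(self) -> str:
        lines = [
            f"selection_strength = {self.selection_strength!r}",
            f"length_min = {self.length_range[0]}",
            f"length_max = {self.length_range[1]}",
        ]
        for aa in sorted(self.target_probs):
            for codon, p in zip(self.code.families[aa], self.target_probs[aa]):
                lines.append(f"target.{aa}.{codon} = {float(p)!r}")
        if self.aa_probs:
            for aa in sorted(self.aa_probs):
                lines.append(f"aa.{aa} = {float(self.aa_probs[aa])!r}")
        for codon, p in zip(self.code.families[STOP], self.stop_probs):
            lines.append(f"stop.{codon} = {float(p)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config_text(cls, text: str, code: GeneticCode = STANDARD_CODE) -> "UsageModel":
        kv = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        target: dict[str, dict[str, float]] = {}
        aa_probs: dict[str, float] = {}
        stop_probs: dict[str, float] = {}
        for key, val in kv.items():
            if key.startswith("target."):
                _, aa, codon = key.split(".")
                target.setdefault(aa, {})[codon] = float(val)
            elif key.startswith("aa."):
                aa_probs[key.split(".", 1)[1]] = float(val)
            elif key.startswith("stop."):
                stop_probs[key.split(".", 1)[1]] = float(val)
        target_probs = {
            aa: np.array([d[c] for c in code.families[aa]]) for aa, d in target.items()
        }
        stops = tuple(
            stop_probs.get(c, 1 / 3) for c in code.families[STOP]
        )
        return cls(
            target_probs=target_probs,
            selection_strength=float(kv.get("selection_strength", 1.0)),
            length_range=(int(kv.get("length_min", 101)), int(kv.get("length_max", 1000))),
            aa_probs=aa_probs or None,
            stop_probs=stops,  # type: ignore[arg-type]
            code=code,
        )


# ---------------------------------------------------------------------------
# Factories


def uniform_model(code: GeneticCode = STANDARD_CODE, **kwargs) -> UsageModel:
    """No codon preference at all: every family uniform (selection 0)."""
    targets = {
        aa: np.full(len(fam), 1.0 / len(fam))
        for aa, fam in code.families.items()
        if aa != STOP
    }
    kwargs.setdefault("selection_strength", 0.0)
    return UsageModel(target_probs=targets, code=code, **kwargs)


def mutation_only_model(
    gc3: float, code: GeneticCode = STANDARD_CODE, **kwargs
) -> UsageModel:
    """Third positions driven purely by a GC3 parameter (ENc-plot null).

    Within each family a codon's weight is the probability of its third base
    under P(G) = P(C) = gc3/2, P(A) = P(T) = (1 − gc3)/2, renormalised.  The
    stop codon follows the same base weights.
    """
    if not 0.0 < gc3 < 1.0:
        raise ModelError("gc3 must lie strictly inside (0, 1)")
    base_p = {"G": gc3 / 2, "C": gc3 / 2, "A": (1 - gc3) / 2, "T": (1 - gc3) / 2}
    targets = {}
    for aa, fam in code.families.items():
        if aa == STOP:
            continue
        w = np.array([base_p[c[2]] for c in fam])
        targets[aa] = w / w.sum()
    stop_w = np.array([base_p[c[2]] for c in code.families[STOP]])
    kwargs.setdefault("stop_probs", tuple(stop_w / stop_w.sum()))
    kwargs.setdefault("selection_strength", 1.0)
    return UsageModel(target_probs=targets, code=code, **kwargs)


def at_preference_model(
    selection_strength: float = 0.6,
    code: GeneticCode = STANDARD_CODE,
    **kwargs,
) -> UsageModel:
    """AT-rich chloroplast-like preference.

    The target spreads each family's mass uniformly over its A/T-ending
    codons, so after mixing with the uniform distribution every A/T-ending
    synonymous codon has expected RSCU ``1 + s`` and every G/C-ending one
    ``1 − s`` (the standard code has exactly 30 A/T-ending codons in
    multi-codon families).  At the default strength 0.6 this yields the
    usage band ~0.4–1.6 and an expected overall GC3 of
    (2 + 9·(1−s))/20 ≈ 0.28 under uniform amino-acid usage — the AT-rich
    regime typical of chloroplast genomes."""
    targets = {}
    for aa, fam in code.families.items():
        if aa == STOP:
            continue
        at = np.array([1.0 if c[2] in "AT" else 0.0 for c in fam])
        targets[aa] = at / at.sum() if at.sum() else np.full(len(fam), 1.0 / len(fam))
    kwargs.setdefault("stop_probs", (0.5, 0.3, 0.2))  # mild TAA preference
    return UsageModel(
        target_probs=targets, selection_strength=selection_strength, code=code, **kwargs
    )


# ---------------------------------------------------------------------------
# Generation


def generate_cds_set(
    model: UsageModel,
    n_genes: int,
    seed: int | np.random.Generator,
    species: str = "synthetic",
    id_prefix: str = "syn",
) -> list[CdsRecord]:
    """Sample a set of clean CDS records; deterministic under a fixed seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    code = model.code
    aas, pa = model._aa_items()
    eff = {aa: model.effective_probs(aa) for aa in aas}
    fams = {aa: code.families[aa] for aa in aas}
    stops = code.families[STOP]
    records = []
    lo, hi = model.length_range
    for g in range(n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        internal = rng.choice(len(aas), size=n_codons - 2, p=pa)
        codons = np.empty(n_codons - 2, dtype=object)
        for idx in range(len(aas)):  # vectorised per amino acid
            mask = internal == idx
            n = int(mask.sum())
            if not n:
                continue
            aa = aas[idx]
            picks = rng.choice(len(fams[aa]), size=n, p=eff[aa])
            codons[mask] = np.array(fams[aa], dtype=object)[picks]
        parts = ["ATG", *codons.tolist()]
        parts.append(stops[int(rng.choice(3, p=np.asarray(model.stop_probs)))])
        records.append(
            CdsRecord(
                id=f"{id_prefix}{g + 1:03d}", species=species, sequence="".join(parts)
            )
        )
    return records


def generate_qc_violations(code: GeneticCode = STANDARD_CODE) -> list[CdsRecord]:
    """Records each violating exactly one acceptance rule.

    The first record is a clean template (it is the only one a quality
    filter should keep); the last is its verbatim duplicate, failing the
    repeat rule only.  The records in between each fail exactly one of:
    frame, start codon, stop codon, internal stop, length, alphabet.
    """
    template = "ATG" + "AAA" * 100 + "TAA"  # 306 bp, clean
    mk = lambda i, seq: CdsRecord(id=f"qc{i}", species="qc", sequence=seq)
    return [
        mk("_clean", template),
        mk("_frame", template + "A"),
        mk("_start", "ATT" + template[3:]),
        mk("_stop", template[:-3] + "AAG"),
        mk("_internal_stop", "ATGAAATAA" + template[9:]),
        mk("_short", "ATG" + "AAA" * 98 + "TAA"),  # exactly 300 bp
        mk("_ambiguous", "ATGAAN" + template[6:]),
        mk("_duplicate", template),
    ]


def planted_preference_libraries(
    base_model: UsageModel,
    shifted_codons: list[str],
    delta: float,
    n_genes: int = 40,
    seed: int = 0,
) -> tuple[list[CdsRecord], list[CdsRecord]]:
    """Two gene sets whose pooled RSCU differs by ≈ ``delta`` exactly on the
    shifted codons — and by construction nowhere else.

    The "low" set is sampled from ``base_model``.  The "high" set is built
    from the very same sequences by direct codon arithmetic: within each
    shifted codon's family, per gene, ``round(delta · N_fam / n_i)``
    occurrences of its synonymous mates (taken in sequence order, so mates
    lose usage in proportion to their frequency) are rewritten to the
    shifted codon, raising that codon's RSCU by ≈ ``delta``.  Families not
    containing a shifted codon are byte-identical between the libraries, so
    their ΔRSCU is exactly zero — planted-preference recovery is free of
    sampling noise outside the planted codons.
    """
    code = base_model.code
    if delta < 0:
        raise ModelError("delta must be non-negative")
    by_family: dict[str, list[str]] = {}
    for codon in shifted_codons:
        aa = code.codon_to_aa[codon]
        if aa == STOP or len(code.families[aa]) == 1:
            raise ModelError(f"cannot shift codon {codon} (no synonymous family)")
        by_family.setdefault(aa, []).append(codon)

    low = generate_cds_set(base_model, n_genes, seed, species="low", id_prefix="lo")
    high = []
    for g, rec in enumerate(low):
        codons = [rec.sequence[i : i + 3] for i in range(0, len(rec.sequence), 3)]
        for aa, targets in by_family.items():
            fam = set(code.families[aa])
            n_i = len(fam)
            positions = [i for i, c in enumerate(codons) if c in fam]
            for target in targets:
                n_fam = len(positions)
                k = round(delta * n_fam / n_i)
                mates = [i for i in positions if codons[i] != target]
                if k > len(mates):
                    raise ModelError(
                        f"shift of {delta} on {target} exceeds available "
                        f"synonymous usage in gene {rec.id}"
                    )
                for i in mates[:k]:
                    codons[i] = target
        high.append(
            CdsRecord(id=f"hi{g + 1:03d}", species="high", sequence="".join(codons))
        )
    return high, low
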