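"""Codon usage indices: RSCU, RFSC, ENc, CAI, Laa; high-frequency and
optimal codons.

Definitions
-----------
For amino acid *i* with ``n_i`` synonymous codons and codon counts ``X_ij``:

* ``RSCU_ij = X_ij / ((1 / n_i) * sum_j X_ij)`` — observed over expected
  under uniform synonymous usage; 1 means no bias.
* ``RFSC_ij = X_ij / sum_j X_ij`` — the codon's share of its family, so
  ``RSCU = RFSC * n_i``.
* ENc is Wright's effective number of codons, estimated from family
  homozygosities ``F = (n * sum p^2 - 1) / (n - 1)`` averaged per degeneracy
  class: ``ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``, clamped to [20, 61].
* CAI is the Sharp–Li geometric mean of relative adaptiveness weights
  ``w_c = RSCU_c / max RSCU in family`` taken from a highly expressed
  reference set; Met, Trp and stops are excluded.

Optimal codons follow the two-tail expression-library construction: genes
are ranked by ENc, the lowest-ENc 10% form the high-expression library (a
strongly biased gene is the standard proxy for high expression — note this
choice flips the sign of ΔRSCU if reversed), the highest-ENc 10% the low
library, and a codon is optimal when its high-library RSCU exceeds 1 and
ΔRSCU = RSCU_high − RSCU_low exceeds 0.08 (both strict).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import CodonCountVector, positional_composition
from .errors import InsufficientDataError, UndefinedMetricError
from .genetic_code import CODONS, STOP, GeneticCode, STANDARD_CODE

logger = logging.getLogger(__name__)

ENC_MIN, ENC_MAX = 20.0, 61.0


@dataclass
class RscuTable:
    """Per-codon RSCU/RFSC values for one scope (gene or pooled genome).

    ``table`` is indexed by the 61 sense codons (fixed lexicographic order)
    with columns ``aa``, ``family_size``, ``count``, ``rscu``, ``rfsc``.
    Codons of a family that never occurs carry NaN, not 0.
    """

    scope: str
    table: pd.DataFrame

    def rscu(self, codon: str) -> float:
        return float(self.table.loc[codon.upper(), "rscu"])

    def rfsc(self, codon: str) -> float:
        return float(self.table.loc[codon.upper(), "rfsc"])

    def preferred_codons(self) -> list[str]:
        """Codons with RSCU > 1 (strict)."""
        t = self.table
        return list(t.index[t["rscu"] > 1.0])


def _rscu_rfsc_frame(
    counts: CodonCountVector, code: GeneticCode
) -> pd.DataFrame:
    if counts.total == 0:
        raise UndefinedMetricError(f"RSCU undefined for all-zero counts ({counts.scope})")
    rows = []
    for codon in CODONS:
        aa = code.codon_to_aa[codon]
        if aa == STOP:
            continue
        fam = code.families[aa]
        n_i = len(fam)
        fam_total = sum(counts[c] for c in fam)
        x = counts[codon]
        if fam_total == 0:
            rscu = rfsc = math.nan
        else:
            rfsc = x / fam_total
            rscu = rfsc * n_i
        rows.append((codon, aa, n_i, x, rscu, rfsc))
    return pd.DataFrame(
        rows, columns=["codon", "aa", "family_size", "count", "rscu", "rfsc"]
    ).set_index("codon")


def compute_rscu(
    counts: CodonCountVector, code: GeneticCode = STANDARD_CODE
) -> RscuTable:
    """Relative synonymous codon usage for every sense codon."""
    return RscuTable(scope=counts.scope, table=_rscu_rfsc_frame(counts, code))


def compute_rfsc(
    counts: CodonCountVector, code: GeneticCode = STANDARD_CODE
) -> RscuTable:
    """Synonymous-usage fractions; same table as :func:`compute_rscu`
    (both columns are always carried, related by ``rscu = rfsc * n_i``)."""
    return compute_rscu(counts, code)


def mean_gene_rscu(
    per_gene: Sequence[CodonCountVector], code: GeneticCode = STANDARD_CODE
) -> RscuTable:
    """Mean of per-gene RSCU values (NaN-aware), an alternative to pooled-count
    RSCU for genome-scope summaries."""
    frames = [_rscu_rfsc_frame(c, code) for c in per_gene]
    base = frames[0].copy()
    base["rscu"] = np.nanmean(np.stack([f["rscu"].to_numpy() for f in frames]), axis=0)
    base["rfsc"] = np.nanmean(np.stack([f["rfsc"].to_numpy() for f in frames]), axis=0)
    base["count"] = np.sum(np.stack([f["count"].to_numpy() for f in frames]), axis=0)
    return RscuTable(scope="mean_of_genes", table=base)


# ---------------------------------------------------------------------------
# ENc


def compute_enc(
    counts: CodonCountVector, code: GeneticCode = STANDARD_CODE
) -> float:
    """Wright's effective number of codons, clamped to [20, 61].

    Family homozygosity F is estimated only for families observed at least
    twice.  If the single three-fold class (Ile) is missing, the usual
    fallback F3 ≈ (F2 + F4)/2 is applied; if any other class has no
    estimable family (or a zero mean F), ENc is undefined and raises.
    """
    if counts.total == 0:
        raise UndefinedMetricError(f"ENc undefined for all-zero counts ({counts.scope})")
    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in code.families.items():
        if aa == STOP or len(fam) == 1:
            continue
        fam_counts = np.array([counts[c] for c in fam], dtype=float)
        n = fam_counts.sum()
        if n < 2:
            continue
        p = fam_counts / n
        f_hat = (n * float(np.square(p).sum()) - 1.0) / (n - 1.0)
        per_class[len(fam)].append(f_hat)

    f_bar: dict[int, float] = {}
    for k, vals in per_class.items():
        if vals:
            f_bar[k] = float(np.mean(vals))
    if 3 not in f_bar and 2 in f_bar and 4 in f_bar:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0
    missing = [k for k in (2, 3, 4, 6) if k not in f_bar or f_bar[k] <= 0.0]
    if missing:
        raise UndefinedMetricError(
            f"ENc undefined: degeneracy class(es) {missing} not estimable "
            f"({counts.scope})"
        )
    enc = 2.0 + 9.0 / f_bar[2] + 1.0 / f_bar[3] + 5.0 / f_bar[4] + 3.0 / f_bar[6]
    return min(ENC_MAX, max(ENC_MIN, enc))


def enc_expected(gc3s: float) -> float:
    """Expected ENc under mutation pressure alone at third-position GC ``s``:
    ``2 + s + 29 / (s^2 + (1 - s)^2)``."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"gc3s must lie in [0, 1], got {gc3s}")
    s = float(gc3s)
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


# ---------------------------------------------------------------------------
# CAI


def relative_adaptiveness(
    reference_counts: CodonCountVector,
    code: GeneticCode = STANDARD_CODE,
    floor: float = 0.01,
) -> dict[str, float]:
    """Sharp–Li weights w_c from a reference (high-expression) codon set.

    ``w_c = RSCU_c / max RSCU in family``; codons unobserved in the reference
    (including whole absent families) are floored at ``floor`` so a gene
    using them is penalised rather than undefined.
    """
    ref = compute_rscu(reference_counts, code)
    w: dict[str, float] = {}
    for aa, fam in code.families.items():
        if aa == STOP:
            continue
        rscus = {c: ref.rscu(c) for c in fam}
        finite = [v for v in rscus.values() if not math.isnan(v) and v > 0]
        vmax = max(finite) if finite else math.nan
        for c in fam:
            v = rscus[c]
            if math.isnan(vmax) or math.isnan(v) or v <= 0:
                w[c] = floor
            else:
                w[c] = max(floor, v / vmax)
    return w


def compute_cai(
    counts: CodonCountVector,
    reference_weights: Mapping[str, float],
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Codon adaptation index: length-normalised geometric mean of weights.

    Met, Trp and stop codons never enter the mean (their weight is trivially
    1 in any reference set)."""
    include = set(code.synonymous_sense_codons)
    log_sum = 0.0
    n = 0
    for codon in include:
        x = counts[codon]
        if not x:
            continue
        w = reference_weights[codon]
        if w <= 0:
            raise ValueError(f"reference weight for {codon} must be positive")
        log_sum += x * math.log(w)
        n += x
    if n == 0:
        raise UndefinedMetricError(
            f"CAI undefined: no synonymous sense codons in {counts.scope}"
        )
    return math.exp(log_sum / n)


def build_reference_weights(
    gene_rows: Sequence[tuple[str, CodonCountVector, float]],
    tail_fraction: float = 0.10,
    code: GeneticCode = STANDARD_CODE,
) -> dict[str, float]:
    """CAI weights from the internal high-expression library.

    The library is the ``ceil(tail_fraction * N)`` genes with the LOWEST ENc
    (strongest bias); weights come from the pooled RSCU of that library.
    This self-contained reference replaces any organism-specific built-in
    set on purpose: no external expression data exist for these genomes.
    """
    high, _ = expression_libraries(gene_rows, tail_fraction)
    pooled = CodonCountVector(
        scope="high_expression",
        counts=np.sum([c.counts for _, c, _ in high], axis=0),
    )
    return relative_adaptiveness(pooled, code)


def expression_libraries(
    gene_rows: Sequence[tuple[str, CodonCountVector, float]],
    tail_fraction: float = 0.10,
) -> tuple[list[tuple[str, CodonCountVector, float]], list[tuple[str, CodonCountVector, float]]]:
    """Split genes into (high, low) expression libraries by ENc tails.

    Genes are stably sorted on (ENc, gene id) — ties across the tail
    boundary resolve deterministically and are logged.  The low-ENc tail is
    the high-expression library.
    """
    n = len(gene_rows)
    if n < 10:
        raise InsufficientDataError(f"need at least 10 genes, got {n}")
    k = math.ceil(tail_fraction * n)
    if k < 2:
        raise InsufficientDataError(
            f"tail of {k} gene(s) from N={n} is too small (need ≥ 2 per tail)"
        )
    ranked = sorted(gene_rows, key=lambda row: (row[2], row[0]))
    boundary_enc = {ranked[k - 1][2], ranked[-k][2]}
    inner = [r[2] for r in ranked[k:-k]]
    if any(e in boundary_enc for e in inner):
        logger.info("ENc tie spans a tail boundary; resolved by (ENc, gene id) order")
    return ranked[:k], ranked[-k:]


# ---------------------------------------------------------------------------
# High-frequency and optimal codons


def high_frequency_codons(
    rscu: RscuTable,
    mode: str = "default",
    code: GeneticCode = STANDARD_CODE,
) -> list[str]:
    """Codons used at high frequency within their synonymous family.

    ``default``: RFSC > 0.6 or RSCU >= 1.5 (usage at least 1.5× the family
    mean).  ``literal``: RFSC > 0.5 × the family-mean RFSC, i.e.
    RFSC > 0.5 / n_i — a much weaker rule.  Met, Trp and stop codons are
    never flagged.
    """
    if mode not in ("default", "literal"):
        raise ValueError("mode must be 'default' or 'literal'")
    out = []
    for codon in code.synonymous_sense_codons:
        row = rscu.table.loc[codon]
        if math.isnan(row["rscu"]):
            continue
        if mode == "default":
            hit = row["rfsc"] > 0.6 or row["rscu"] >= 1.5
        else:
            hit = row["rfsc"] > 0.5 / row["family_size"]
        if hit:
            out.append(codon)
    return out


@dataclass
class OptimalCodonResult:
    codon: str
    aa: str
    rscu_high: float
    rscu_low: float
    is_optimal: bool

    @property
    def delta_rscu(self) -> float:
        return self.rscu_high - self.rscu_low


def optimal_codons_between(
    high_counts: CodonCountVector,
    low_counts: CodonCountVector,
    delta_threshold: float = 0.08,
    code: GeneticCode = STANDARD_CODE,
) -> list[OptimalCodonResult]:
    """ΔRSCU decision between two pooled expression libraries.

    A codon is optimal iff its high-library RSCU > 1 and
    ΔRSCU = RSCU_high − RSCU_low > ``delta_threshold`` (both strict).
    Codons of a family absent from either library carry NaN and are never
    optimal.
    """
    high = compute_rscu(high_counts, code)
    low = compute_rscu(low_counts, code)
    results = []
    for codon in code.sense_codons:
        rh = high.rscu(codon)
        rl = low.rscu(codon)
        if math.isnan(rh) or math.isnan(rl):
            opt = False
        else:
            opt = rh > 1.0 and (rh - rl) > delta_threshold
        results.append(
            OptimalCodonResult(
                codon=codon,
                aa=code.codon_to_aa[codon],
                rscu_high=rh,
                rscu_low=rl,
                is_optimal=opt,
            )
        )
    return results


def optimal_codons(
    gene_rows: Sequence[tuple[str, CodonCountVector, float]],
    tail_fraction: float = 0.10,
    delta_threshold: float = 0.08,
    code: GeneticCode = STANDARD_CODE,
) -> list[OptimalCodonResult]:
    """Optimal codons via ENc-tail expression libraries (see module docs)."""
    high, low = expression_libraries(gene_rows, tail_fraction)
    pooled_high = CodonCountVector(
        scope="high_expression", counts=np.sum([c.counts for _, c, _ in high], axis=0)
    )
    pooled_low = CodonCountVector(
        scope="low_expression", counts=np.sum([c.counts for _, c, _ in low], axis=0)
    )
    return optimal_codons_between(pooled_high, pooled_low, delta_threshold, code)


def shared_optimal_codons(per_species: Sequence[Iterable[str]]) -> set[str]:
    """Exact intersection of per-species optimal-codon sets."""
    if len(per_species) < 2:
        raise InsufficientDataError("need at least 2 species sets to intersect")
    sets = [set(s) for s in per_species]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


# ---------------------------------------------------------------------------
# Per-gene index table


def gene_index_table(
    gene_counts: Sequence[CodonCountVector],
    code: GeneticCode = STANDARD_CODE,
    cai_weights: Mapping[str, float] | None = None,
    pr2_codon_set: str = "fourfold",
) -> pd.DataFrame:
    """One row of scalar indices per gene.

    Columns: laa (amino-acid count = codons minus stops), enc, cai (NaN if no
    weights given), gc1, gc2, gc3, gc_mean, gc12, gc3s, a3, t3, g3, c3.
    Genes with undefined ENc get NaN and a log entry; they are excluded from
    ENc-based plots downstream.
    """
    rows = []
    for cv in gene_counts:
        comp = positional_composition(cv, code, pr2_codon_set)
        stops = sum(cv[c] for c in code.stop_codons)
        try:
            enc = compute_enc(cv, code)
        except UndefinedMetricError as exc:
            logger.info("%s", exc)
            enc = math.nan
        cai = (
            compute_cai(cv, cai_weights, code) if cai_weights is not None else math.nan
        )
        rows.append(
            {
                "gene": cv.scope,
                "laa": cv.total - stops,
                "enc": enc,
                "cai": cai,
                "gc1": comp.gc1,
                "gc2": comp.gc2,
                "gc3": comp.gc3,
                "gc_mean": comp.gc_mean,
                "gc12": comp.gc12,
                "gc3s": comp.gc3s,
                "a3": comp.a3,
                "t3": comp.t3,
                "g3": comp.g3,
                "c3": comp.c3,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
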