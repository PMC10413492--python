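"""Sources of codon-usage variation: ENc-plot, PR2-plot, neutrality
regression, correspondence analysis, and index–axis correlations.

The ENc-plot compares each gene's observed ENc with the value expected from
its GC3s under mutation pressure alone; genes far below the curve point to
selection.  The PR2-plot examines third-position strand parity,
A3/(A3+T3) against G3/(G3+C3), where (0.5, 0.5) is the no-bias point.  The
neutrality plot regresses GC12 on GC3: a slope near 1 means mutation
pressure dominates, near 0 means selection; the slope is reported as the
mutation fraction.  Correspondence analysis decomposes the genes × 59-codon
RSCU matrix (Met, Trp and stops excluded) into orthogonal axes ordered by
explained inertia.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codons import PositionalComposition
from .errors import DegenerateFitError, InsufficientDataError
from .genetic_code import GeneticCode, STANDARD_CODE
from .metrics import enc_expected

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ENc-plot


@dataclass
class EncPlotPoint:
    gene: str
    gc3s: float
    enc_observed: float
    enc_expected: float
    on_curve: bool

    @property
    def ratio_deviation(self) -> float:
        """(expected − observed) / expected; positive below the curve."""
        return (self.enc_expected - self.enc_observed) / self.enc_expected


def enc_plot(
    points: Sequence[tuple[str, float, float]],
    tolerance: float = 0.05,
) -> tuple[list[EncPlotPoint], dict[str, int]]:
    """Classify genes against the mutation-only expected ENc curve.

    ``points`` are (gene, gc3s, enc_observed) triples; genes with undefined
    (NaN) ENc are skipped with a log entry.  Returns the per-gene points and
    a summary {"on": .., "below": .., "above": ..} at the given relative
    tolerance.
    """
    out: list[EncPlotPoint] = []
    summary = {"on": 0, "below": 0, "above": 0}
    for gene, gc3s, enc_obs in points:
        if math.isnan(enc_obs) or math.isnan(gc3s):
            logger.info("gene %s skipped in ENc-plot (undefined ENc or GC3s)", gene)
            continue
        exp = enc_expected(gc3s)
        dev = (exp - enc_obs) / exp
        on = abs(dev) <= tolerance
        out.append(
            EncPlotPoint(
                gene=gene, gc3s=gc3s, enc_observed=enc_obs, enc_expected=exp, on_curve=on
            )
        )
        summary["on" if on else ("below" if dev > 0 else "above")] += 1
    return out, summary


# ---------------------------------------------------------------------------
# PR2-plot


@dataclass
class Pr2Point:
    gene: str
    x: float  # G3 / (G3 + C3)
    y: float  # A3 / (A3 + T3)


def pr2_plot(
    per_gene: Sequence[tuple[str, PositionalComposition]]
) -> list[Pr2Point]:
    """Parity-rule-2 coordinates, one point per gene with defined denominators."""
    out = []
    for gene, comp in per_gene:
        gc = comp.g3 + comp.c3
        at = comp.a3 + comp.t3
        if not gc or not at or math.isnan(gc) or math.isnan(at):
            logger.info("gene %s excluded from PR2-plot (zero denominator)", gene)
            continue
        out.append(Pr2Point(gene=gene, x=comp.g3 / gc, y=comp.a3 / at))
    return out


# ---------------------------------------------------------------------------
# Neutrality plot


@dataclass
class NeutralityFit:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n_genes: int

    @property
    def mutation_fraction(self) -> float:
        """Share of the GC12 variation attributed to mutation pressure."""
        return self.slope

    @property
    def selection_fraction(self) -> float:
        return 1.0 - self.slope


def neutrality_fit(per_gene: Sequence[tuple[float, float]]) -> NeutralityFit:
    """Ordinary least squares of GC12 on GC3 with Pearson correlation.

    ``per_gene`` holds (gc12, gc3) pairs.  OLS (not reduced major axis) is
    the near-universal convention for this regression.
    """
    if len(per_gene) < 3:
        raise InsufficientDataError("neutrality fit needs at least 3 genes")
    gc12 = np.array([p[0] for p in per_gene], dtype=float)
    gc3 = np.array([p[1] for p in per_gene], dtype=float)
    if np.ptp(gc3) == 0:
        raise DegenerateFitError("GC3 has zero variance; regression undefined")
    if np.ptp(gc12) == 0:
        # flat response: slope 0 exactly, correlation undefined -> 0 by convention
        return NeutralityFit(
            slope=0.0,
            intercept=float(gc12[0]),
            pearson_r=0.0,
            p_value=1.0,
            n_genes=len(per_gene),
        )
    res = stats.linregress(gc3, gc12)
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_genes=len(per_gene),
    )


# ---------------------------------------------------------------------------
# Correspondence analysis


@dataclass
class CoaResult:
    """Classical correspondence analysis of a genes × codons table.

    ``inertia`` holds the fraction of total inertia per axis (descending);
    ``gene_coords`` and ``codon_coords`` are principal coordinates on every
    non-trivial axis (columns ``axis1``, ``axis2``, ...).  ``degenerate`` is
    set when the table carries (numerically) no inertia at all, in which
    case the fractions are NaN.
    """

    inertia: np.ndarray
    gene_coords: pd.DataFrame
    codon_coords: pd.DataFrame
    degenerate: bool = False

    @property
    def n_axes(self) -> int:
        return len(self.inertia)


def correspondence_analysis(
    matrix: pd.DataFrame,
    equalize_rows: bool = True,
) -> CoaResult:
    """Classical CA of a non-negative genes × codons matrix.

    Intended input is the per-gene RSCU matrix over the 59 synonymous sense
    codons, NaN (absent family) imputed to 0; with ``equalize_rows`` each row
    is rescaled to unit sum so every gene carries equal mass (the usual
    CA-on-RSCU construction).  A raw-counts matrix can be passed instead
    with ``equalize_rows=False`` for sensitivity analysis.

    The table is treated as a contingency-style table: with ``P`` the matrix
    normalised to sum 1, row masses ``r`` and column masses ``c``, the
    standardized residuals ``S = D_r^{-1/2} (P − r cᵀ) D_c^{-1/2}`` are
    decomposed by SVD; axis k's inertia fraction is σ_k²/Σσ², and principal
    coordinates are ``D_r^{-1/2} U Σ`` (rows) and ``D_c^{-1/2} V Σ``
    (columns).  Axis signs are fixed so the codon with the largest absolute
    loading on each axis is positive.
    """
    if matrix.shape[0] < 3:
        raise InsufficientDataError("correspondence analysis needs at least 3 rows")
    m = matrix.to_numpy(dtype=float)
    if np.isnan(m).any():
        m = np.nan_to_num(m, nan=0.0)
    if (m < 0).any():
        raise ValueError("CA input must be non-negative")

    # drop all-zero columns (codon never observed) but remember them
    col_keep = m.sum(axis=0) > 0
    dropped = list(matrix.columns[~col_keep])
    if dropped:
        logger.info("CA: %d all-zero codon column(s) dropped: %s", len(dropped), dropped)
    m = m[:, col_keep]
    cols = list(matrix.columns[col_keep])
    if (m.sum(axis=1) == 0).any():
        raise ValueError("CA input has an all-zero row")

    if equalize_rows:
        m = m / m.sum(axis=1, keepdims=True)

    P = m / m.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)

    max_axes = min(P.shape) - 1
    sig = sig[:max_axes]
    U = U[:, :max_axes]
    V = Vt.T[:, :max_axes]

    total = float(np.square(sig).sum())
    degenerate = total < 1e-12
    if degenerate:
        logger.warning("CA: total inertia ~ 0 (all rows proportional); degenerate result")
        inertia = np.full(max_axes, np.nan)
        gene = np.zeros((P.shape[0], max_axes))
        codon = np.zeros((P.shape[1], max_axes))
    else:
        inertia = np.square(sig) / total
        gene = (U * sig) / np.sqrt(r)[:, None]
        codon = (V * sig) / np.sqrt(c)[:, None]
        # deterministic axis orientation
        for k in range(max_axes):
            if sig[k] < 1e-12:
                continue
            j = int(np.argmax(np.abs(codon[:, k])))
            if codon[j, k] < 0:
                codon[:, k] *= -1
                gene[:, k] *= -1

    axes = [f"axis{k + 1}" for k in range(max_axes)]
    return CoaResult(
        inertia=inertia,
        gene_coords=pd.DataFrame(gene, index=matrix.index, columns=axes),
        codon_coords=pd.DataFrame(codon, index=cols, columns=axes),
        degenerate=degenerate,
    )


def rscu_matrix(
    per_gene_rscu: Mapping[str, "pd.Series | pd.DataFrame"],
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Assemble the genes × 59 synonymous-sense-codon RSCU matrix for CA.

    Accepts a mapping gene -> RSCU series (indexed by codon); absent-family
    NaNs are imputed to 0 only here, at the multivariate boundary.
    """
    cols = list(code.synonymous_sense_codons)
    rows = {}
    for gene, series in per_gene_rscu.items():
        s = series["rscu"] if isinstance(series, pd.DataFrame) else series
        rows[gene] = s.reindex(cols).to_numpy(dtype=float)
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).fillna(0.0)


# ---------------------------------------------------------------------------
# GC classing and correlations


def classify_gc(gc: float) -> str:
    """Bucket a gene's mean GC: ``lt45`` (< 0.45), ``45to60`` (0.45–0.60
    inclusive), ``gt60`` (> 0.60)."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must lie in [0, 1], got {gc}")
    if gc < 0.45:
        return "lt45"
    if gc <= 0.60:
        return "45to60"
    return "gt60"


def _stars(p: float) -> str:
    if math.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlate_indices_with_axes(
    index_table: pd.DataFrame,
    coa: CoaResult,
    method: str = "pearson",
    indices: Sequence[str] = ("gc3s", "enc", "cai", "laa"),
    n_axes: int = 2,
) -> pd.DataFrame:
    """Correlate per-gene indices with the first CA axes and one another.

    Rows are aligned on gene id.  Returns a long-form table with columns
    (var1, var2, r, p_value, significance); stars mark p < 0.05 (*) and
    p < 0.01 (**).  Constant columns yield NaN with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    axes = [f"axis{k + 1}" for k in range(min(n_axes, coa.n_axes))]
    joined = index_table.join(coa.gene_coords[axes], how="inner")
    cols = [c for c in indices if c in joined.columns] + axes
    pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1 :]]
    rows = []
    for a, b in pairs:
        sub = joined[[a, b]].dropna()
        x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if len(sub) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("correlation %s~%s undefined (constant or too few values)", a, b)
            r = p = math.nan
        else:
            r, p = map(float, corr(x, y))
        rows.append(
            {"var1": a, "var2": b, "r": r, "p_value": p, "significance": _stars(p)}
        )
    return pd.DataFrame(rows)
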