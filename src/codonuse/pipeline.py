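"""One-command orchestration: per-species analysis plus a cross-species
comparison, written as TSV artifacts and a machine-readable summary.json.

Species are processed independently and joined only at the end (common
preferred codons, shared optimal codons); every number in summary.json is
recomputable from the stage TSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .codons import CodonCountVector, aggregate_counts, count_codons, positional_composition
from .errors import CodonUsageError, ConfigError
from .genetic_code import STANDARD_CODE
from .hosts import (
    HostUsageTable,
    coffee_usage_per_1000,
    compare_usage,
    load_bundled_host,
    load_host_dir,
    BUNDLED_HOSTS,
)
from .metrics import (
    build_reference_weights,
    compute_enc,
    compute_rscu,
    gene_index_table,
    high_frequency_codons,
    optimal_codons,
    shared_optimal_codons,
)
from .seqio import (
    apply_qc_filters,
    read_fasta_cds,
    read_genbank_cds,
    write_filter_report,
    write_filtered_fasta,
)
from .variation import (
    classify_gc,
    correlate_indices_with_axes,
    correspondence_analysis,
    enc_plot,
    neutrality_fit,
    pr2_plot,
    rscu_matrix,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.4f"


def _round(x: float, nd: int = 4) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return round(float(x), nd)


@dataclass
class RunConfig:
    """Configuration for :func:`run_pipeline`; echoed verbatim into the
    output directory."""

    inputs: list[tuple[str, str]]  # (path, species label)
    out_dir: str
    hosts_dir: str | None = None  # None -> bundled synthetic snapshots
    min_len_bp: int = 300
    tail_fraction: float = 0.10
    delta_threshold: float = 0.08
    hf_mode: str = "default"  # default | literal
    pr2_codon_set: str = "fourfold"  # fourfold | all
    on_curve_tolerance: float = 0.05
    corr_method: str = "pearson"  # pearson | spearman
    dedup: str = "sequence"
    seed: int = 0

    def validate(self) -> None:
        if not self.inputs:
            raise ConfigError("at least one input file is required")
        if not 0.0 < self.tail_fraction <= 0.5:
            raise ConfigError("tail_fraction must lie in (0, 0.5]")
        if self.delta_threshold < 0:
            raise ConfigError("delta_threshold must be non-negative")
        if self.hf_mode not in ("default", "literal"):
            raise ConfigError("hf_mode must be 'default' or 'literal'")
        if self.pr2_codon_set not in ("fourfold", "all"):
            raise ConfigError("pr2_codon_set must be 'fourfold' or 'all'")
        if self.corr_method not in ("pearson", "spearman"):
            raise ConfigError("corr_method must be 'pearson' or 'spearman'")
        if not 0.0 < self.on_curve_tolerance < 1.0:
            raise ConfigError("on_curve_tolerance must lie in (0, 1)")
        if self.min_len_bp < 0:
            raise ConfigError("min_len_bp must be non-negative")


def _read_records(path: str, species: str):
    p = Path(path)
    if p.suffix.lower() in (".gb", ".gbk", ".genbank"):
        return read_genbank_cds(p, species=species)
    return read_fasta_cds(p, species=species)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def analyse_species(
    records,
    species: str,
    config: RunConfig,
    hosts: dict[str, HostUsageTable],
    out_dir: Path | None = None,
) -> dict:
    """Full single-species analysis; optionally writes the stage TSVs.

    Returns the species' summary dict (every headline statistic)."""
    code = STANDARD_CODE
    kept, reports = apply_qc_filters(records, config.min_len_bp, config.dedup)
    if out_dir:
        write_filter_report(reports, out_dir / "filter_report.tsv")
        write_filtered_fasta(kept, out_dir / "filtered_cds.fasta")
    if len(kept) < 10:
        raise CodonUsageError(
            f"{species}: only {len(kept)} CDS pass quality control; need >= 10"
        )

    per_gene = [count_codons(r.sequence, scope=r.id) for r in kept]
    pooled = aggregate_counts(per_gene)
    pooled_comp = positional_composition(pooled, code, config.pr2_codon_set)

    # per-gene ENc, CAI reference from the low-ENc tail, index table
    gene_rows = []
    for cv in per_gene:
        try:
            enc = compute_enc(cv, code)
        except CodonUsageError:
            enc = math.nan
        gene_rows.append((cv.scope, cv, enc))
    usable = [r for r in gene_rows if not math.isnan(r[2])]
    weights = build_reference_weights(usable, config.tail_fraction, code)
    indices = gene_index_table(per_gene, code, weights, config.pr2_codon_set)
    if out_dir:
        _write_tsv(indices, out_dir / "gene_indices.tsv")

    # genome-scope RSCU / RFSC, high-frequency codons
    rscu = compute_rscu(pooled, code)
    hf = high_frequency_codons(rscu, config.hf_mode, code)
    rscu_out = rscu.table.copy()
    rscu_out.insert(0, "scope", species)
    rscu_out["high_frequency"] = [c in hf for c in rscu_out.index]
    if out_dir:
        _write_tsv(rscu_out, out_dir / "rscu.tsv")

    # optimal codons
    opt = optimal_codons(usable, config.tail_fraction, config.delta_threshold, code)
    opt_df = pd.DataFrame(
        [
            {
                "codon": o.codon,
                "aa": o.aa,
                "rscu_high": o.rscu_high,
                "rscu_low": o.rscu_low,
                "delta_rscu": o.delta_rscu,
                "is_optimal": o.is_optimal,
            }
            for o in opt
        ]
    ).set_index("codon")
    optimal_set = sorted(o.codon for o in opt if o.is_optimal)
    if out_dir:
        _write_tsv(opt_df, out_dir / "optimal_codons.tsv")

    # ENc-plot
    enc_points, enc_summary = enc_plot(
        [(g, indices.loc[g, "gc3s"], indices.loc[g, "enc"]) for g in indices.index],
        config.on_curve_tolerance,
    )
    enc_df = pd.DataFrame(
        [
            {
                "gene": p.gene,
                "gc3s": p.gc3s,
                "enc_observed": p.enc_observed,
                "enc_expected": p.enc_expected,
                "ratio_deviation": p.ratio_deviation,
                "on_curve": p.on_curve,
            }
            for p in enc_points
        ]
    )
    if out_dir:
        _write_tsv(enc_df, out_dir / "enc_plot.tsv", index=False)

    # PR2-plot
    comps = [
        (r.id, positional_composition(cv, code, config.pr2_codon_set))
        for r, cv in zip(kept, per_gene)
    ]
    pr2_points = pr2_plot(comps)
    pr2_df = pd.DataFrame([{"gene": p.gene, "x": p.x, "y": p.y} for p in pr2_points])
    if out_dir:
        _write_tsv(pr2_df, out_dir / "pr2.tsv", index=False)

    # neutrality plot
    fit = neutrality_fit(
        [(indices.loc[g, "gc12"], indices.loc[g, "gc3"]) for g in indices.index]
    )
    if out_dir:
        neut = indices[["gc12", "gc3"]].copy()
        neut["fitted"] = fit.intercept + fit.slope * neut["gc3"]
        _write_tsv(neut, out_dir / "neutrality.tsv")

    # correspondence analysis on per-gene RSCU (59 codons)
    per_gene_rscu = {cv.scope: compute_rscu(cv, code).table for cv in per_gene}
    ca_matrix = rscu_matrix(per_gene_rscu, code)
    coa = correspondence_analysis(ca_matrix)
    gc_classes = {g: classify_gc(indices.loc[g, "gc_mean"]) for g in indices.index}
    if out_dir:
        inertia_df = pd.DataFrame(
            {
                "axis": [f"axis{k + 1}" for k in range(coa.n_axes)],
                "inertia_fraction": coa.inertia,
            }
        )
        _write_tsv(inertia_df, out_dir / "coa_inertia.tsv", index=False)
        genes_out = coa.gene_coords.iloc[:, :4].copy()
        genes_out["gc_class"] = [gc_classes[g] for g in genes_out.index]
        _write_tsv(genes_out, out_dir / "coa_genes.tsv")
        _write_tsv(coa.codon_coords.iloc[:, :4], out_dir / "coa_codons.tsv")

    # index ~ axis correlations
    corr = correlate_indices_with_axes(indices, coa, config.corr_method)
    if out_dir:
        _write_tsv(corr, out_dir / "correlations.tsv", index=False)

    # host comparison
    per1000 = coffee_usage_per_1000(pooled)
    host_summaries = {}
    host_rows = []
    for name, table in hosts.items():
        ratios, n_large = compare_usage(per1000, table)
        host_summaries[name] = {
            "large_difference": n_large,
            "large_difference_pct": _round(100.0 * n_large / 64, 4),
        }
        for rr in ratios:
            host_rows.append(
                {
                    "organism": name,
                    "codon": rr.codon,
                    "coffee_per_1000": rr.coffee_freq,
                    "host_per_1000": rr.host_freq,
                    "ratio": rr.ratio,
                    "category": rr.category,
                }
            )
    if out_dir and host_rows:
        _write_tsv(pd.DataFrame(host_rows), out_dir / "host_comparison.tsv", index=False)

    gc_counts = pd.Series(list(gc_classes.values())).value_counts().to_dict()
    rscu_vals = rscu.table["rscu"].dropna()
    return {
        "species": species,
        "n_raw_cds": len(records),
        "n_filtered_cds": len(kept),
        "gc1_pct": _round(100 * pooled_comp.gc1),
        "gc2_pct": _round(100 * pooled_comp.gc2),
        "gc3_pct": _round(100 * pooled_comp.gc3),
        "gc_mean_pct": _round(100 * pooled_comp.gc_mean),
        "gc3s_pct": _round(100 * pooled_comp.gc3s),
        "rscu_min": _round(rscu_vals.min()),
        "rscu_max": _round(rscu_vals.max()),
        "rscu_max_codon": str(rscu_vals.idxmax()),
        "preferred_codons": rscu.preferred_codons(),
        "n_preferred": len(rscu.preferred_codons()),
        "high_frequency_codons": hf,
        "n_high_frequency": len(hf),
        "optimal_codons": optimal_set,
        "n_optimal": len(optimal_set),
        "enc_plot": enc_summary,
        "enc_on_curve_pct": _round(
            100.0 * enc_summary["on"] / max(1, sum(enc_summary.values()))
        ),
        "neutrality": {
            "slope": _round(fit.slope),
            "intercept": _round(fit.intercept),
            "pearson_r": _round(fit.pearson_r),
            "p_value": _round(fit.p_value, 6),
            "mutation_fraction_pct": _round(100 * fit.mutation_fraction),
            "selection_fraction_pct": _round(100 * fit.selection_fraction),
            "n_genes": fit.n_genes,
        },
        "coa": {
            "axis1_inertia_pct": _round(100 * coa.inertia[0]) if coa.n_axes else None,
            "axis2_inertia_pct": _round(100 * coa.inertia[1]) if coa.n_axes > 1 else None,
            "degenerate": coa.degenerate,
        },
        "gc_classes": {k: int(gc_counts.get(k, 0)) for k in ("lt45", "45to60", "gt60")},
        "hosts": host_summaries,
    }


def common_preferred_codons(per_species_rscu: Sequence) -> set[str]:
    """Intersection of {codon : RSCU > 1} across genome-scope tables."""
    if not per_species_rscu:
        return set()
    sets = [set(t.preferred_codons()) for t in per_species_rscu]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the summary dict (also written as
    summary.json).  Partial outputs are retained with a MANIFEST of the
    stages completed."""
    config.validate()
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    cfg_text = json.dumps(asdict(config), indent=2, sort_keys=True)
    (out_root / "config.json").write_text(cfg_text + "\n")
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]

    log_path = out_root / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("codonuse")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info("codonuse %s, config hash %s", __version__, cfg_hash)

    manifest: list[str] = []

    def _done(stage: str) -> None:
        manifest.append(stage)
        (out_root / "MANIFEST").write_text("\n".join(manifest) + "\n")

    try:
        if config.hosts_dir:
            hosts = load_host_dir(config.hosts_dir)
        else:
            hosts = {name: load_bundled_host(name) for name in BUNDLED_HOSTS}
        _done("hosts")

        species_summaries = []
        for path, species in config.inputs:
            records = _read_records(path, species)
            sp_dir = out_root / species
            sp_dir.mkdir(exist_ok=True)
            summary = analyse_species(records, species, config, hosts, sp_dir)
            species_summaries.append(summary)
            _done(f"species:{species}")

        common = sorted(
            set.intersection(*(set(s["preferred_codons"]) for s in species_summaries))
        )
        at_ending = [c for c in common if c[2] in "AT"]
        cross = {
            "common_preferred_codons": common,
            "n_common_preferred": len(common),
            "n_common_preferred_at_ending": len(at_ending),
            "common_preferred_at_ending_pct": _round(
                100.0 * len(at_ending) / len(common) if common else 0.0
            ),
        }
        if len(species_summaries) >= 2:
            shared = sorted(
                shared_optimal_codons([s["optimal_codons"] for s in species_summaries])
            )
            cross["shared_optimal_codons"] = shared
            cross["n_shared_optimal"] = len(shared)
        _done("cross_species")

        summary = {
            "tool": f"codonuse {__version__}",
            "config_hash": cfg_hash,
            "seed": config.seed,
            "species": species_summaries,
            "cross_species": cross,
        }
        (out_root / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        _done("summary")
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()
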