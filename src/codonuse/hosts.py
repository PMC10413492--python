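"""Host codon-usage tables and frequency-ratio comparison.

A candidate heterologous-expression host is judged by the per-codon ratio of
the chloroplast genome's usage (per 1000 codons) to the host's: a ratio at
or below 0.5, or at or above 2, marks a codon whose usage differs enough to
hinder expression ("large difference"); anything strictly between is
"similar".  The denominator for summary percentages is all 64 codons.

Host tables use the Kazusa codon-usage-table text layout: a 4 × 16 grid of
``codon  frequency-per-1000 (count)`` entries in the RNA alphabet.  The
tables shipped under :mod:`codonuse.data` are hand-constructed synthetic
snapshots emulating each organism's qualitative preferences (see the file
headers); point comparisons against them characterise those snapshots, not
the live database.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

from .codons import CodonCountVector
from .errors import FormatError, UndefinedMetricError
from .genetic_code import CODONS

logger = logging.getLogger(__name__)

_ENTRY = re.compile(r"([ACGUT]{3})\s+(\d+(?:\.\d+)?)\s*\(\s*(\d+(?:\.\d+)?)\s*\)")

#: Hosts with a snapshot shipped in codonuse/data.
BUNDLED_HOSTS = {
    "A_thaliana": "a_thaliana.synthetic.cut.txt",
    "N_tabacum": "n_tabacum.synthetic.cut.txt",
    "E_coli": "e_coli.synthetic.cut.txt",
    "S_cerevisiae": "s_cerevisiae.synthetic.cut.txt",
}


@dataclass
class HostUsageTable:
    """Per-codon usage frequency (per 1000 codons) for one organism."""

    organism: str
    freq_per_1000: dict[str, float]  # keyed by DNA codon, all 64 present
    source: str = ""

    def __post_init__(self) -> None:
        missing = set(CODONS) - set(self.freq_per_1000)
        if missing:
            raise FormatError(f"host table missing {len(missing)} codon(s): {sorted(missing)[:4]}...")
        total = sum(self.freq_per_1000.values())
        if abs(total - 1000.0) > 10.0:
            raise FormatError(
                f"per-1000 frequencies sum to {total:.1f}, expected ~1000 (±1%)"
            )


def parse_kazusa_table(text: str, organism: str = "", source: str = "") -> HostUsageTable:
    """Parse a Kazusa-layout codon usage table.

    Lines starting with ``#`` are treated as metadata; ``organism:`` and
    ``source:`` keys there fill the corresponding fields when not passed
    explicitly.  U is converted to T.  All 64 codons must be present exactly
    once.
    """
    freq: dict[str, float] = {}
    meta: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("#"):
            m = re.match(r"#\s*(\w+)\s*:\s*(.+)", stripped)
            if m:
                meta[m.group(1).lower()] = m.group(2).strip()
            continue
        if not stripped:
            continue
        hits = _ENTRY.findall(line)
        if not hits and stripped:
            raise FormatError(f"line {lineno}: no codon entries in {stripped!r}")
        for rna_codon, f, _count in hits:
            codon = rna_codon.replace("U", "T")
            if codon in freq:
                raise FormatError(f"line {lineno}: codon {rna_codon} repeated")
            freq[codon] = float(f)
    if len(freq) != 64:
        raise FormatError(f"expected 64 codons, parsed {len(freq)}")
    return HostUsageTable(
        organism=organism or meta.get("organism", "unknown"),
        freq_per_1000=freq,
        source=source or meta.get("source", ""),
    )


def load_bundled_host(name: str) -> HostUsageTable:
    """Load one of the shipped synthetic host snapshots by key
    (see :data:`BUNDLED_HOSTS`)."""
    fname = BUNDLED_HOSTS[name]
    text = resources.files("codonuse.data").joinpath(fname).read_text()
    return parse_kazusa_table(text, organism=name)


def load_host_dir(path: str | Path) -> dict[str, HostUsageTable]:
    """Parse every ``*.txt`` table in a directory, keyed by organism label."""
    out = {}
    for p in sorted(Path(path).glob("*.txt")):
        table = parse_kazusa_table(p.read_text(), source=str(p))
        out[table.organism] = table
    return out


def coffee_usage_per_1000(counts: CodonCountVector) -> dict[str, float]:
    """Genome codon usage on the Kazusa scale: 1000 · X_c / ΣX."""
    total = counts.total
    if total == 0:
        raise UndefinedMetricError("per-1000 usage undefined for zero counts")
    return {c: 1000.0 * counts[c] / total for c in CODONS}


@dataclass
class RatioRecord:
    codon: str
    coffee_freq: float
    host_freq: float
    category: str  # similar | large_difference | undefined

    @property
    def ratio(self) -> float:
        return self.coffee_freq / self.host_freq if self.host_freq else float("nan")


def categorize_ratio(ratio: float) -> str:
    """``large_difference`` iff ratio ≤ 0.5 or ratio ≥ 2 (inclusive bounds)."""
    return "large_difference" if (ratio <= 0.5 or ratio >= 2.0) else "similar"


def compare_usage(
    coffee: Mapping[str, float], host: HostUsageTable
) -> tuple[list[RatioRecord], int]:
    """Per-codon frequency ratios against one host over all 64 codons.

    Returns the records and the number of large-difference codons.  Codons
    the host never uses give an undefined ratio; they are excluded from the
    summary count with a log entry.
    """
    records = []
    n_large = 0
    for codon in CODONS:
        cf = float(coffee[codon])
        hf = float(host.freq_per_1000[codon])
        if hf == 0.0:
            logger.info(
                "codon %s has zero frequency in %s; ratio undefined", codon, host.organism
            )
            cat = "undefined"
        else:
            cat = categorize_ratio(cf / hf)
            if cat == "large_difference":
                n_large += 1
        records.append(
            RatioRecord(codon=codon, coffee_freq=cf, host_freq=hf, category=cat)
        )
    return records, n_large
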