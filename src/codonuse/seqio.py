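"""GenBank/FASTA CDS input, quality-control filtering, and FASTA output.

The four acceptance rules applied to every extracted CDS:

1. length a multiple of three;
2. starts with ATG, ends with a stop (TAA/TAG/TGA), no internal stop;
3. longer than 300 bp (strict: 301+, in practice 303 given rule 1);
4. not a repeat of a sequence already accepted (chloroplast inverted repeats
   double-annotate genes verbatim; the first occurrence is kept).

Records carrying ambiguity codes (N etc.) are additionally rejected, since
every downstream index requires a clean A/C/G/T alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import EmptyInputError, FormatError

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")
STOP_CODONS = ("TAA", "TAG", "TGA")

#: Failure categories, in reporting order.
FAILURES = (
    "not_multiple_of_3",
    "bad_start",
    "bad_stop",
    "internal_stop",
    "too_short",
    "duplicate",
    "ambiguous_base",
)


@dataclass
class CdsRecord:
    """One coding sequence on its coding strand, 5'→3'."""

    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class FilterReport:
    """Outcome of quality control for one record."""

    record_id: str
    passed: bool
    failures: list[str] = field(default_factory=list)


def read_genbank_cds(path: str | Path, species: str | None = None) -> list[CdsRecord]:
    """Extract every CDS feature from a GenBank flat file.

    join()/complement() locations are spliced and reverse-complemented so the
    returned sequence reads 5'→3' on the coding strand.  Feature order is
    preserved.  A CDS whose coordinates run outside the record is skipped
    with a warning.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subtypes
        raise FormatError(f"{path}: not parseable as GenBank: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no GenBank records found")

    out: list[CdsRecord] = []
    for rec in records:
        label = species or rec.annotations.get("organism", rec.id)
        n_seen = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n_seen += 1
            gene = feat.qualifiers.get(
                "gene", feat.qualifiers.get("locus_tag", [f"cds{n_seen}"])
            )[0]
            try:
                seq = str(feat.location.extract(rec.seq))
            except Exception as exc:
                logger.warning(
                    "%s: CDS %s has an unresolvable location (%s); skipped",
                    path,
                    gene,
                    exc,
                )
                continue
            start = int(feat.location.start)
            end = int(feat.location.end)
            if end > len(rec.seq):
                logger.warning(
                    "%s: CDS %s coordinates %d..%d exceed record length; skipped",
                    path,
                    gene,
                    start + 1,
                    end,
                )
                continue
            out.append(
                CdsRecord(id=f"{gene}_{start + 1}_{end}", species=label, sequence=seq)
            )
    return out


def read_fasta_cds(path: str | Path, species: str | None = None) -> list[CdsRecord]:
    """Read one CDS per FASTA record; the first header token becomes the id."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records")
    return [
        CdsRecord(id=r.id, species=species or path.stem, sequence=str(r.seq))
        for r in records
    ]


def _rule_failures(seq: str, min_len_bp: int) -> list[str]:
    fails: list[str] = []
    if len(seq) % 3:
        fails.append("not_multiple_of_3")
    if not seq.startswith("ATG"):
        fails.append("bad_start")
    if len(seq) % 3 == 0 and len(seq) >= 3:
        if seq[-3:] not in STOP_CODONS:
            fails.append("bad_stop")
        internal = any(
            seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq) - 3, 3)
        )
        if internal:
            fails.append("internal_stop")
    if len(seq) <= min_len_bp:
        fails.append("too_short")
    if not _VALID.issuperset(seq):
        fails.append("ambiguous_base")
    return fails


def apply_qc_filters(
    records: Sequence[CdsRecord],
    min_len_bp: int = 300,
    dedup: str = "sequence",
) -> tuple[list[CdsRecord], list[FilterReport]]:
    """Apply the four CDS acceptance rules; report every record's outcome.

    Parameters
    ----------
    min_len_bp
        Length threshold; the comparison is strict, a CDS of exactly
        ``min_len_bp`` fails.
    dedup
        ``"sequence"`` (default) fails any record whose sequence is identical
        to an earlier kept record; ``"gene"`` deduplicates on the gene-name
        part of the id (text before the first underscore); ``"none"``
        disables the repeat rule.

    All rules are evaluated for every record (no short-circuit), so a report
    lists every violated rule.
    """
    if not records:
        raise EmptyInputError("apply_qc_filters received no records")
    if dedup not in ("sequence", "gene", "none"):
        raise ValueError("dedup must be 'sequence', 'gene' or 'none'")

    kept: list[CdsRecord] = []
    reports: list[FilterReport] = []
    seen_seq: set[str] = set()
    seen_gene: set[str] = set()
    for rec in records:
        fails = _rule_failures(rec.sequence, min_len_bp)
        if dedup == "sequence" and rec.sequence in seen_seq:
            fails.append("duplicate")
        elif dedup == "gene":
            gene = rec.id.split("_", 1)[0]
            if gene in seen_gene:
                fails.append("duplicate")
        passed = not fails
        reports.append(FilterReport(record_id=rec.id, passed=passed, failures=fails))
        if passed:
            kept.append(rec)
            seen_seq.add(rec.sequence)
            seen_gene.add(rec.id.split("_", 1)[0])
    return kept, reports


def write_filtered_fasta(records: Sequence[CdsRecord], path: str | Path) -> None:
    """Write records as standard FASTA, 60-column wrapped."""
    path = Path(path)
    if not records:
        logger.warning("writing empty FASTA to %s (no records)", path)
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def write_filter_report(reports: Sequence[FilterReport], path: str | Path) -> None:
    """TSV report: id, passed, semicolon-joined failures."""
    with open(path, "w") as fh:
        fh.write("record_id\tpassed\tfailures\n")
        for r in reports:
            fh.write(f"{r.record_id}\t{str(r.passed).lower()}\t{';'.join(r.failures)}\n")
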