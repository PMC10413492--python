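"""Shared fixtures: a small synthetic GenBank chloroplast fragment and
codon-count helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from codonuse.codons import CodonCountVector
from codonuse.genetic_code import CODON_INDEX


def make_counts(d: dict[str, int], scope: str = "test") -> CodonCountVector:
    arr = np.zeros(64, dtype=np.int64)
    for codon, n in d.items():
        arr[CODON_INDEX[codon.upper()]] = n
    return CodonCountVector(scope=scope, counts=arr)


@pytest.fixture
def counts_factory():
    return make_counts


def _revcomp(s: str) -> str:
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


# 33 bp synthetic genome fragment:
#   1..9              forward CDS  "fwd"     -> ATGAAATAA
#   complement(10..18) reverse CDS "rev"     -> ATGCCCTAA
#   join(22..27,31..33) spliced CDS "spliced" -> ATGTTTTAA
GENOME = "ATGAAATAA" + _revcomp("ATGCCCTAA") + "GGG" + "ATGTTT" + "CCC" + "TAA"


def _origin_lines(seq: str) -> str:
    out = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60].lower()
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        out.append(f"{i + 1:>9} {groups}")
    return "\n".join(out)


GENBANK_TEXT = f"""LOCUS       TESTCP01                  {len(GENOME)} bp    DNA     linear   PLN 01-JAN-2024
DEFINITION  synthetic chloroplast fragment for unit tests.
ACCESSION   TESTCP01
VERSION     TESTCP01.1
SOURCE      synthetic construct
  ORGANISM  synthetic construct
            .
FEATURES             Location/Qualifiers
     source          1..{len(GENOME)}
     CDS             1..9
                     /gene="fwd"
     CDS             complement(10..18)
                     /gene="rev"
     CDS             join(22..27,31..33)
                     /gene="spliced"
ORIGIN
{_origin_lines(GENOME)}
//
"""


@pytest.fixture
def genbank_file(tmp_path):
    path = tmp_path / "fixture.gb"
    path.write_text(GENBANK_TEXT)
    return path
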