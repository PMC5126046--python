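"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_genbank(tmp_path):
    """Single-contig GenBank record with a plus- and a minus-strand CDS."""
    seq = "ATGAAATTTGGGTAACCCATGCCCGGGAAATAG" + "ACGT" * 5
    # gene1: 1..15 on + (ATG AAA TTT GGG TAA); gene2: 19..33 on - strand
    gb = textwrap.dedent(
        f"""\
        LOCUS       contig1                   53 bp    DNA     linear   BCT 01-JAN-2000
        DEFINITION  synthetic toy genome.
        ACCESSION   contig1
        VERSION     contig1
        FEATURES             Location/Qualifiers
             CDS             1..15
                             /locus_tag="gene1"
                             /product="protein one"
             CDS             complement(19..33)
                             /locus_tag="gene2"
                             /product="protein two"
        ORIGIN
        """
    )
    body = ""
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60].lower()
        grouped = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        body += f"{i+1:>9} {grouped}\n"
    path = tmp_path / "toy.gb"
    path.write_text(gb + body + "//\n")
    return path, seq
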