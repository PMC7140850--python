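"""Thin wrappers around Biopython for FASTA/FASTQ input."""

from __future__ import annotations

from typing import Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_fastq_sequences(path) -> Iterator[str]:
    """Sequences only, in file order (fast tuple-based parser)."""
    with open(path) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq
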