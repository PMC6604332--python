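"""Sequence records and FASTA/FASTQ input/output.

Thin layer over Biopython's parsers that normalises everything to a small
:class:`SeqRecord` dataclass (id, sequence, optional Phred+33 qualities).
Lowercase letters are meaningful: they mark masked (low-complexity) bases
and survive round-trips.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional

from Bio import SeqIO as _BioSeqIO

__all__ = [
    "SeqRecord",
    "ParseError",
    "load_sequences",
    "iter_sequences",
    "write_sequences",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_DNA_CHARS = set("ACGTNacgtn")


class ParseError(ValueError):
    """Raised when a sequence file does not parse under the named format."""


@dataclass
class SeqRecord:
    """One named nucleotide or amino-acid sequence.

    Parameters
    ----------
    id : str
        Identifier (first whitespace-delimited token of the header).
    seq : str
        The sequence. For DNA, characters from ``ACGTN`` in either case;
        lowercase means masked.
    qual : str, optional
        Per-base quality string (Phred+33), same length as ``seq``.
    alphabet : {"dna", "protein"}
    description : str
        Remainder of the header line after the id.
    """

    id: str
    seq: str
    qual: Optional[str] = None
    alphabet: str = "dna"
    description: str = ""

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ParseError(
                f"record {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        if self.alphabet != "dna":
            raise ValueError("reverse complement is only defined for DNA")
        return SeqRecord(
            id=self.id,
            seq=revcomp(self.seq),
            qual=self.qual[::-1] if self.qual else None,
            alphabet="dna",
            description=self.description,
        )


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _guess_alphabet(seq: str) -> str:
    return "dna" if not seq or set(seq) <= _DNA_CHARS else "protein"


def iter_sequences(path: os.PathLike | str, fmt: str = "fasta") -> Iterator[SeqRecord]:
    """Stream records from a FASTA or FASTQ file without loading them all."""
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format: {fmt!r}")
    try:
        for rec in _BioSeqIO.parse(os.fspath(path), fmt):
            seq = str(rec.seq)
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            yield SeqRecord(
                id=rec.id,
                seq=seq,
                qual=qual,
                alphabet=_guess_alphabet(seq),
                description=desc,
            )
    except ValueError as exc:  # Biopython signals malformed records this way
        raise ParseError(f"{path}: {exc}") from exc


def load_sequences(path: os.PathLike | str, fmt: str = "fasta") -> List[SeqRecord]:
    """Load all records from *path*; empty file yields an empty list."""
    return list(iter_sequences(path, fmt))


def write_sequences(
    records: Iterable[SeqRecord],
    path: os.PathLike | str,
    fmt: str = "fasta",
    width: int = 80,
) -> None:
    """Write records as FASTA with *width*-column line wrapping.

    Case is preserved so that lowercase masking survives serialization.
    """
    if fmt != "fasta":
        raise ValueError(f"unsupported output format: {fmt!r}")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
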