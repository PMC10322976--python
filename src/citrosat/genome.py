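"""Genome container and FASTA round-trip.

A :class:`Genome` is an ordered mapping of chromosome id to an upper-case
sequence string. Only A/C/G/T/N are meaningful to the rest of the package;
validation happens in the consumers that care (the miner rejects characters
other than ACGTN, e-PCR treats N as unmatchable).
"""

from __future__ import annotations

import gzip
from collections.abc import Iterator, Mapping
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class Genome(Mapping[str, str]):
    """Ordered chromosome-id -> sequence mapping with FASTA I/O."""

    def __init__(self, sequences: Mapping[str, str], genome_id: str = "genome"):
        self.genome_id = genome_id
        self._seqs: dict[str, str] = {str(k): str(v).upper() for k, v in sequences.items()}

    def __getitem__(self, key: str) -> str:
        return self._seqs[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def total_length(self) -> int:
        """Summed sequence length in bp."""
        return sum(len(s) for s in self._seqs.values())

    @classmethod
    def from_fasta(cls, path: str | Path, genome_id: str | None = None) -> "Genome":
        """Read a (possibly gzipped) FASTA file."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        name = genome_id if genome_id is not None else path.name.split(".")[0]
        return cls(seqs, genome_id=name)

    def to_fasta(self, path: str | Path) -> Path:
        """Write FASTA wrapped at 60 columns."""
        path = Path(path)
        records = [
            SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in self._seqs.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
        return path

    def reverse_complement(self) -> "Genome":
        return Genome(
            {c: str(Seq(s).reverse_complement()) for c, s in self._seqs.items()},
            genome_id=self.genome_id + "_rc",
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Genome({self.genome_id!r}, {len(self)} sequences, {self.total_length} bp)"


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return str(Seq(seq).reverse_complement())
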