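"""Core sequence record types shared across the pipeline.

``SeqRead`` is deliberately lighter than Biopython's ``SeqRecord``: the
pipeline shuffles millions of short reads through pure-python filters, and a
frozen dataclass with a plain string and an integer tuple is both faster and
easier to reason about.  File I/O converts to/from Biopython at the boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

PHRED_OFFSET = 33

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRead:
    """One sequence record: id, bases, optional per-base Phred qualities."""

    read_id: str
    bases: str
    quality: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, stop: Optional[int] = None) -> "SeqRead":
        q = self.quality[start:stop] if self.quality is not None else None
        return SeqRead(self.read_id, self.bases[start:stop], q)

    def reverse_complement(self) -> "SeqRead":
        q = self.quality[::-1] if self.quality is not None else None
        return SeqRead(self.read_id, reverse_complement(self.bases), q)


@dataclass(frozen=True)
class ReadPair:
    """A forward/reverse mate pair; the reverse mate is stored as sequenced."""

    forward: SeqRead
    reverse: SeqRead
    truncated: bool = False


@dataclass(frozen=True)
class Tag:
    """Merged read pair.  ``support`` marks each base's source: f, r or b."""

    tag_id: str
    bases: str
    quality: Optional[tuple[int, ...]] = None
    support: Optional[str] = None


@dataclass(frozen=True)
class Contig:
    """Assembled sequence with a mean fold-coverage."""

    contig_id: str
    bases: str
    coverage: float

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError(f"contig {self.contig_id!r} is empty")
        if not (self.coverage >= 0 and self.coverage == self.coverage):
            raise ValueError(f"contig {self.contig_id!r}: bad coverage")

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass
class SampleBatch:
    """Ordered reads of one demultiplexed sample (file order preserved)."""

    sample_id: str
    reads: list[SeqRead] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# FASTA / FASTQ boundaries (Biopython-backed)

def _handle(path_or_handle: Union[str, Path, TextIO], mode: str):
    if isinstance(path_or_handle, (str, Path)):
        return open(path_or_handle, mode), True
    return path_or_handle, False


def read_fastq(source: Union[str, Path, TextIO]) -> Iterator[SeqRead]:
    from Bio import SeqIO

    handle, close = _handle(source, "r")
    try:
        for rec in SeqIO.parse(handle, "fastq"):
            yield SeqRead(rec.id, str(rec.seq).upper(),
                          tuple(rec.letter_annotations["phred_quality"]))
    finally:
        if close:
            handle.close()


def read_fasta(source: Union[str, Path, TextIO]) -> Iterator[SeqRead]:
    from Bio import SeqIO

    handle, close = _handle(source, "r")
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            yield SeqRead(rec.id, str(rec.seq).upper())
    finally:
        if close:
            handle.close()


def write_fastq(reads: Iterable[SeqRead],
                dest: Union[str, Path, TextIO]) -> int:
    handle, close = _handle(dest, "w")
    n = 0
    try:
        for r in reads:
            if r.quality is None:
                raise ValueError(f"read {r.read_id!r} has no quality")
            qual = "".join(chr(q + PHRED_OFFSET) for q in r.quality)
            handle.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")
            n += 1
    finally:
        if close:
            handle.close()
    return n


def write_fasta(reads: Iterable[SeqRead],
                dest: Union[str, Path, TextIO],
                width: int = 80) -> int:
    handle, close = _handle(dest, "w")
    n = 0
    try:
        for r in reads:
            handle.write(f">{r.read_id}\n")
            for i in range(0, len(r.bases), width):
                handle.write(r.bases[i:i + width] + "\n")
            n += 1
    finally:
        if close:
            handle.close()
    return n


def contigs_to_fasta(contigs: Sequence[Contig],
                     dest: Union[str, Path, TextIO]) -> int:
    """Write contigs with the coverage embedded as a ``_cov_<float>`` suffix."""
    reads = (SeqRead(f"{c.contig_id}_cov_{c.coverage:.4f}", c.bases)
             for c in contigs)
    return write_fasta(reads, dest)


def contigs_from_fasta(source: Union[str, Path, TextIO]) -> list[Contig]:
    """Read contigs whose headers carry a ``_cov_<float>`` suffix."""
    out = []
    for r in read_fasta(source):
        name, _, cov = r.read_id.rpartition("_cov_")
        if not name:
            raise ValueError(f"contig header {r.read_id!r} lacks _cov_ suffix")
        out.append(Contig(name, r.bases, float(cov)))
    return out


def reads_to_string(reads: Iterable[SeqRead], fmt: str = "fastq") -> str:
    buf = io.StringIO()
    if fmt == "fastq":
        write_fastq(reads, buf)
    else:
        write_fasta(reads, buf)
    return buf.getvalue()
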