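"""Read quality control.

Raw shotgun reads are filtered with the preprocessing rules used throughout
the analysis: reads with mean quality below 25 are removed, runs of
positions with quality below 15 are trimmed from the read ends, and reads
shorter than 90 nt after trimming are removed.  A generic decoy-removal
step (exact shared k-mer with a decoy sequence on either strand) stands in
for mapping-based removal of host and spike-in reads.

The fixed order of operations is: (1) trim low-quality runs from the 3'
end, then the 5' end; (2) drop reads shorter than ``min_len``; (3) drop
reads whose post-trim mean quality is below ``mean_q_min``.  Mean quality
after trimming is the meaningful retention statistic, which is why the
length/mean tests follow trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp

__all__ = [
    "Read",
    "FastqRecordError",
    "read_fastq",
    "read_fastq_tolerant",
    "write_fastq",
    "quality_filter",
    "remove_decoy_reads",
    "qc_summary",
]


@dataclass(frozen=True)
class Read:
    """A single read: identifier, bases, and per-base Phred scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FastqRecordError:
    """A malformed FASTQ record: byte offset of the record start and reason."""

    offset: int
    message: str


def read_fastq(path) -> list[Read]:
    """Read a FASTQ file (Phred+33) into a list of :class:`Read`."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            Read(rec.id, str(rec.seq).upper(), tuple(rec.letter_annotations["phred_quality"]))
        )
    return out


def read_fastq_tolerant(path) -> tuple[list[Read], list[FastqRecordError]]:
    """Read FASTQ, skipping malformed records instead of aborting.

    Returns the well-formed reads plus one :class:`FastqRecordError` per bad
    record, carrying the byte offset of the record's first line.  Use this
    only when the input may be truncated or corrupted; :func:`read_fastq`
    is the normal entry point.
    """
    reads: list[Read] = []
    errors: list[FastqRecordError] = []
    with open(path, "rb") as fh:
        while True:
            offset = fh.tell()
            lines = [fh.readline() for _ in range(4)]
            if not lines[0]:
                break
            if not lines[3]:
                errors.append(FastqRecordError(offset, "truncated record"))
                break
            header, seq, plus, qual = (ln.rstrip(b"\r\n") for ln in lines)
            if not header.startswith(b"@"):
                errors.append(FastqRecordError(offset, "header does not start with '@'"))
                continue
            if not plus.startswith(b"+"):
                errors.append(FastqRecordError(offset, "separator line does not start with '+'"))
                continue
            if len(seq) != len(qual):
                errors.append(
                    FastqRecordError(offset, "sequence and quality lengths differ")
                )
                continue
            quals = tuple(q - 33 for q in qual)
            if any(q < 0 for q in quals):
                errors.append(FastqRecordError(offset, "quality character below '!'"))
                continue
            reads.append(Read(header[1:].split()[0].decode(), seq.decode().upper(), quals))
    return reads, errors


def write_fastq(reads: Iterable[Read], path) -> None:
    """Write reads to FASTQ (Phred+33)."""
    records = (
        SeqRecord(
            Seq(r.sequence),
            id=r.id,
            description="",
            letter_annotations={"phred_quality": list(r.qualities)},
        )
        for r in reads
    )
    SeqIO.write(records, str(path), "fastq")


def quality_filter(
    reads: Sequence[Read],
    mean_q_min: float = 25.0,
    trim_q: int = 15,
    min_len: int = 90,
) -> list[Read]:
    """Apply the quality-control rules; returns retained reads in input order.

    Per read: trim the maximal run of positions with quality < ``trim_q``
    from the 3' end, then from the 5' end; drop the read if shorter than
    ``min_len`` after trimming; drop it if its post-trim mean quality is
    below ``mean_q_min``.  Retained reads are unmodified except for the
    end-trimming, so the filter is idempotent.
    """
    out: list[Read] = []
    for r in reads:
        q = r.qualities
        end = len(q)
        while end > 0 and q[end - 1] < trim_q:
            end -= 1
        start = 0
        while start < end and q[start] < trim_q:
            start += 1
        if end - start < min_len:
            continue
        kept = q[start:end]
        if sum(kept) / len(kept) < mean_q_min:
            continue
        if start == 0 and end == len(q):
            out.append(r)
        else:
            out.append(Read(r.id, r.sequence[start:end], kept))
    return out


def remove_decoy_reads(
    reads: Sequence[Read], decoys: Sequence[str], k: int = 31
) -> list[Read]:
    """Remove reads sharing at least one exact k-mer (either strand) with a decoy.

    Reads shorter than ``k`` are trivially retained; output preserves input
    order.  This is a desk-scale stand-in for mapping reads against host or
    spike-in genomes.
    """
    if not decoys:
        raise ValueError("decoy sequence set must be nonempty")
    kmers: set[str] = set()
    for d in decoys:
        for s in (d.upper(), revcomp(d.upper())):
            for i in range(len(s) - k + 1):
                kmers.add(s[i : i + k])
    out = []
    for r in reads:
        seq = r.sequence
        if not any(seq[i : i + k] in kmers for i in range(len(seq) - k + 1)):
            out.append(r)
    return out


def qc_summary(reads_in: Sequence[Read], reads_out: Sequence[Read]) -> dict:
    """Per-file QC summary: read and base counts before/after filtering."""
    bases_in = sum(len(r) for r in reads_in)
    bases_out = sum(len(r) for r in reads_out)
    return {
        "reads_in": len(reads_in),
        "reads_out": len(reads_out),
        "bases_in": bases_in,
        "bases_out": bases_out,
        "bases_trimmed_or_dropped": bases_in - bases_out,
    }
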