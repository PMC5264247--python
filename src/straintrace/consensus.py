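"""Read mapping to markers, pileups, and dominant-strain consensus calling.

The dominant strain of a species in a sample is the most abundant strain;
its sequence is what per-position majority voting over a read pileup
recovers.  The mapper here is a deliberately simple seed-and-extend,
*gapless* aligner over the marker database: an exact ``seed_len``-mer
match (either strand) anchors a full-length ungapped extension, and a read
is assigned to its single best placement.  Substitution-only data keep all
reads co-linear with the marker coordinate frame, so gapless placement is
exact; alignments from an external aligner can be imported from SAM
instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import BASES, N_CODE, as_codes, decode, encode, revcomp
from .markers import MarkerDB
from .readprep import Read

__all__ = [
    "ReadAlignment",
    "Pileup",
    "ConsensusSequence",
    "MarkerIndex",
    "map_reads",
    "alignments_from_sam",
    "alignments_to_sam",
    "build_pileup",
    "pileup_from_alignments",
    "call_consensus",
    "select_markers",
]


@dataclass(frozen=True)
class ReadAlignment:
    """Gapless placement of a read on a marker.

    ``aligned_bases`` are stored in marker orientation (reverse-strand reads
    are reverse-complemented), so downstream pileup code never needs the
    original read again.  ``start`` is a 0-based offset on the marker.
    """

    read_id: str
    marker_id: str
    start: int
    strand: str
    aligned_bases: str
    mismatches: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.mismatches > len(self.aligned_bases):
            raise ValueError("mismatches exceed aligned length")

    @property
    def end(self) -> int:
        return self.start + len(self.aligned_bases)

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / len(self.aligned_bases)


@dataclass
class Pileup:
    """Per-position A/C/G/T counts over one marker; depth is their sum."""

    marker_id: str
    counts: np.ndarray  # shape (4, marker_length), dtype uint32

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class ConsensusSequence:
    """Dominant-strain consensus for one marker in one sample.

    Positions that cannot be called (insufficient depth, plurality tie, or
    majority fraction not exceeded) are masked with ``N``.
    """

    sample: str
    species: str
    marker_id: str
    sequence: str
    unmasked_fraction: float


class MarkerIndex:
    """Exact k-mer index over a marker database for seed-and-extend mapping.

    Building the index once and calling :meth:`map_read` per read is what
    :func:`map_reads` does; keep an index around when mapping many samples
    against the same database.
    """

    def __init__(self, db: MarkerDB, seed_len: int = 21):
        if seed_len < 1:
            raise ValueError("seed_len must be >= 1")
        self.db = db
        self.seed_len = seed_len
        self._arrays = {mid: encode(seq) for mid, seq in db.sequences.items()}
        index: dict[str, list[tuple[str, int]]] = {}
        for mid in sorted(db.sequences):
            seq = db.sequences[mid]
            for pos in range(len(seq) - seed_len + 1):
                index.setdefault(seq[pos : pos + seed_len], []).append((mid, pos))
        self._index = index

    def _candidates(self, seq: str) -> set[tuple[str, int]]:
        k = self.seed_len
        L = len(seq)
        cands: set[tuple[str, int]] = set()
        if L < k:
            return cands
        offsets = list(range(0, L - k + 1, k))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        for off in offsets:
            for mid, pos in self._index.get(seq[off : off + k], ()):
                start = pos - off
                if start >= 0 and start + L <= len(self._arrays[mid]):
                    cands.add((mid, start))
        return cands

    def map_read(self, read: Read, min_identity: float = 0.90) -> ReadAlignment | None:
        """Best gapless placement of one read, or None if unmapped.

        Ties on identity are broken deterministically: lowest marker id,
        then lowest offset, then forward strand.
        """
        L = len(read.sequence)
        if L == 0:
            return None
        best: tuple | None = None
        for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
            arr = encode(seq)
            for mid, start in self._candidates(seq):
                mism = int(
                    np.count_nonzero(self._arrays[mid][start : start + L] != arr)
                )
                ident = 1.0 - mism / L
                if ident < min_identity:
                    continue
                key = (-ident, mid, start, strand)
                if best is None or key < best[0]:
                    best = (key, mid, start, strand, seq, mism)
        if best is None:
            return None
        _, mid, start, strand, seq, mism = best
        return ReadAlignment(read.id, mid, start, strand, seq, mism)


def map_reads(
    reads: Sequence[Read],
    db: MarkerDB,
    seed_len: int = 21,
    min_identity: float = 0.90,
    index: MarkerIndex | None = None,
) -> list[ReadAlignment]:
    """Map reads against the marker database; unmapped reads are absent."""
    if index is None:
        index = MarkerIndex(db, seed_len)
    out = []
    for r in reads:
        aln = index.map_read(r, min_identity)
        if aln is not None:
            out.append(aln)
    return out


def alignments_from_sam(path, db: MarkerDB) -> list[ReadAlignment]:
    """Import gapless alignments from a SAM file produced by an external mapper.

    Only records whose CIGAR is a single full-length match (``M``/``=``/``X``)
    against a marker present in the database are accepted; others are skipped.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name not in db.sequences:
                continue
            cig = rec.cigartuples
            if cig is None or any(op not in (0, 7, 8) for op, _ in cig):
                continue
            seq = rec.query_sequence  # already in reference orientation
            if seq is None:
                continue
            ref = db.sequences[rec.reference_name]
            start = rec.reference_start
            if start + len(seq) > len(ref):
                continue
            mism = sum(1 for a, b in zip(seq.upper(), ref[start : start + len(seq)]) if a != b)
            out.append(
                ReadAlignment(
                    rec.query_name,
                    rec.reference_name,
                    start,
                    "-" if rec.is_reverse else "+",
                    seq.upper(),
                    mism,
                )
            )
    return out


def alignments_to_sam(alignments: Iterable[ReadAlignment], db: MarkerDB, path) -> None:
    """Export alignments to a plain-text SAM file in marker coordinates."""
    import pysam

    mids = db.marker_ids
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": mid, "LN": db.marker_length(mid)} for mid in mids],
    }
    tid = {mid: i for i, mid in enumerate(mids)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for a in alignments:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = a.read_id
            rec.reference_id = tid[a.marker_id]
            rec.reference_start = a.start
            rec.query_sequence = a.aligned_bases
            rec.cigartuples = [(0, len(a.aligned_bases))]
            rec.flag = 16 if a.strand == "-" else 0
            rec.mapping_quality = 255
            rec.set_tag("NM", a.mismatches)
            sam.write(rec)


def pileup_from_alignments(
    alignments: Iterable[ReadAlignment], marker_id: str, length: int
) -> Pileup:
    """Accumulate base counts for one marker (or any single reference)."""
    counts = np.zeros((4, length), dtype=np.uint32)
    for a in alignments:
        if a.marker_id != marker_id:
            continue
        if a.start < 0 or a.end > length:
            raise ValueError(
                f"alignment of {a.read_id!r} exceeds bounds of {marker_id!r}"
            )
        arr = encode(a.aligned_bases)
        pos = np.arange(a.start, a.end)
        valid = arr < N_CODE
        np.add.at(counts, (arr[valid], pos[valid]), 1)
    return Pileup(marker_id, counts)


def build_pileup(
    alignments: Iterable[ReadAlignment], db: MarkerDB
) -> dict[str, Pileup]:
    """One pileup per marker with at least one alignment.

    Reverse-strand reads already carry reverse-complemented bases in their
    alignment records, so counts are accumulated directly in marker
    coordinates.
    """
    by_marker: dict[str, list[ReadAlignment]] = {}
    for a in alignments:
        if a.marker_id not in db.sequences:
            raise ValueError(f"alignment references unknown marker {a.marker_id!r}")
        by_marker.setdefault(a.marker_id, []).append(a)
    return {
        mid: pileup_from_alignments(alns, mid, db.marker_length(mid))
        for mid, alns in by_marker.items()
    }


def call_consensus(
    pileup: Pileup,
    min_depth: int = 3,
    majority_frac: float = 0.5,
    sample: str = "",
    species: str = "",
) -> ConsensusSequence:
    """Per-position majority call of the dominant strain.

    A position is called with the base holding a strict plurality whose
    frequency exceeds ``majority_frac``, provided depth >= ``min_depth``;
    otherwise it is masked with ``N`` (this includes plurality ties).
    """
    counts = pileup.counts
    depth = counts.sum(axis=0)
    top = counts.max(axis=0)
    tie = (counts == top[None, :]).sum(axis=0) > 1
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
    called = (depth >= min_depth) & ~tie & (frac > majority_frac)
    codes = np.where(called, counts.argmax(axis=0), N_CODE).astype(np.uint8)
    seq = decode(codes)
    return ConsensusSequence(
        sample=sample,
        species=species,
        marker_id=pileup.marker_id,
        sequence=seq,
        unmasked_fraction=float(called.mean()) if len(seq) else 0.0,
    )


def select_markers(
    consensuses: Sequence[ConsensusSequence],
    db: MarkerDB,
    min_unmasked: float = 0.8,
    min_markers_frac: float = 0.5,
) -> dict[str, list[ConsensusSequence]]:
    """Detection gate: which species of one sample enter strain comparison.

    A marker is retained iff its unmasked fraction is >= ``min_unmasked``; a
    species is retained iff its retained markers are at least
    ``min_markers_frac`` of its database markers.  Returns retained species
    -> retained consensuses (sorted by marker id).
    """
    by_species: dict[str, list[ConsensusSequence]] = {}
    for c in consensuses:
        if c.unmasked_fraction >= min_unmasked:
            sp = c.species or db.species_of(c.marker_id)
            by_species.setdefault(sp, []).append(c)
    out = {}
    for sp, kept in by_species.items():
        total = len(db.species_markers[sp])
        if len(kept) >= min_markers_frac * total:
            out[sp] = sorted(kept, key=lambda c: c.marker_id)
    return out
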