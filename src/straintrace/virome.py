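"""Viral genome tracking: coverage, consensus SNVs, windows, polymorphism.

Viral genomes recovered from metagenomes/metatranscriptomes are profiled
by breadth of coverage (fraction of reference positions covered by at
least one read) and average depth (mean per-position depth over the whole
reference, uncovered positions included).  Consensus reconstruction reuses
the dominant-strain caller; SNVs are unmasked consensus positions that
differ from the reference.  Mother/infant variant sets are compared in
fixed-width windows (160 bp by default), and intra-sample polymorphic
sites — evidence of coexisting haplotypes in one host — are positions
whose second most frequent base is well supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._seq import BASES, N_CODE, as_codes
from .consensus import Pileup, ReadAlignment, call_consensus, pileup_from_alignments

__all__ = [
    "ViralAlignmentSummary",
    "ViralSNV",
    "ViralConsensus",
    "WindowComparison",
    "PolymorphicSite",
    "viral_coverage",
    "viral_consensus_snvs",
    "shared_variant_windows",
    "polymorphic_sites",
]


@dataclass
class ViralAlignmentSummary:
    """Breadth/depth summary of one viral genome in one sample."""

    sample: str
    genome: str
    breadth: float
    avg_depth: float
    mapped_reads: int
    depth_vector: np.ndarray

    def __post_init__(self):
        if not 0.0 <= self.breadth <= 1.0:
            raise ValueError("breadth must be in [0, 1]")


@dataclass(frozen=True)
class ViralSNV:
    """Consensus difference against the viral reference (1-based position)."""

    genome: str
    position: int
    ref_base: str
    consensus_base: str
    consensus_frequency: float
    depth: int

    def __post_init__(self):
        if self.consensus_base == self.ref_base:
            raise ValueError("an SNV must differ from the reference base")
        if not 0.0 < self.consensus_frequency <= 1.0:
            raise ValueError("consensus frequency must be in (0, 1]")


@dataclass
class ViralConsensus:
    genome: str
    sequence: str  # N-masked consensus
    reconstructed_fraction: float
    snvs: list[ViralSNV]


@dataclass(frozen=True)
class WindowComparison:
    """Mother/infant variant agreement within one reference window
    (1-based inclusive coordinates)."""

    start: int
    end: int
    shared: int
    mother_only: int
    infant_only: int


@dataclass(frozen=True)
class PolymorphicSite:
    position: int  # 1-based
    major_base: str
    minor_base: str
    minor_frequency: float
    depth: int


def viral_coverage(
    alignments: Iterable[ReadAlignment], genome: str, genome_id: str = "", sample: str = ""
) -> ViralAlignmentSummary:
    """Breadth and average depth of one viral genome.

    breadth = positions with depth >= 1 / genome length; avg_depth = total
    aligned bases / genome length.  The per-position depth vector is
    retained for consensus and polymorphism calls.
    """
    alns = [a for a in alignments if not genome_id or a.marker_id == genome_id]
    gid = genome_id or (alns[0].marker_id if alns else "")
    pile = pileup_from_alignments(alns, gid, len(genome))
    depth = pile.depth.astype(np.int64)
    return ViralAlignmentSummary(
        sample=sample,
        genome=gid,
        breadth=float((depth >= 1).mean()) if len(genome) else 0.0,
        avg_depth=float(depth.sum() / len(genome)) if len(genome) else 0.0,
        mapped_reads=len(alns),
        depth_vector=depth,
    )


def viral_consensus_snvs(
    pileup: Pileup, reference: str, min_depth: int = 3
) -> ViralConsensus:
    """Consensus against a viral reference, its reconstructed fraction, and SNVs.

    Consensus rules are those of the dominant-strain caller;
    reconstructed_fraction is the non-N fraction of the consensus, and each
    unmasked position differing from the reference is reported as a SNV
    with its supporting frequency and depth.
    """
    cons = call_consensus(pileup, min_depth=min_depth)
    ref = as_codes(reference)
    called = as_codes(cons.sequence)
    if len(ref) != len(called):
        raise ValueError("pileup and reference lengths differ")
    depth = pileup.depth
    snvs = []
    for pos in np.nonzero((called != N_CODE) & (called != ref))[0]:
        d = int(depth[pos])
        count = int(pileup.counts[called[pos], pos])
        snvs.append(
            ViralSNV(
                genome=pileup.marker_id,
                position=int(pos) + 1,
                ref_base=BASES[ref[pos]] if ref[pos] < N_CODE else "N",
                consensus_base=BASES[called[pos]],
                consensus_frequency=count / d,
                depth=d,
            )
        )
    return ViralConsensus(pileup.marker_id, cons.sequence, cons.unmasked_fraction, snvs)


def shared_variant_windows(
    snvs_mother: Sequence[ViralSNV],
    snvs_infant: Sequence[ViralSNV],
    genome_length: int,
    window: int = 160,
) -> list[WindowComparison]:
    """Tile the genome into fixed windows and count variant agreement.

    A variant at the same position with the same alternate base in both
    samples is shared; a position match with different alternate bases
    counts as one mother-only plus one infant-only.  The terminal window
    may be shorter than ``window``.
    """
    if window < 1:
        raise ValueError("window width must be >= 1")
    mom = {s.position: s.consensus_base for s in snvs_mother}
    inf = {s.position: s.consensus_base for s in snvs_infant}
    out = []
    for start in range(1, genome_length + 1, window):
        end = min(start + window - 1, genome_length)
        shared = mother_only = infant_only = 0
        for pos in range(start, end + 1):
            mb, ib = mom.get(pos), inf.get(pos)
            if mb is None and ib is None:
                continue
            if mb is not None and ib is not None:
                if mb == ib:
                    shared += 1
                else:
                    mother_only += 1
                    infant_only += 1
            elif mb is not None:
                mother_only += 1
            else:
                infant_only += 1
        out.append(WindowComparison(start, end, shared, mother_only, infant_only))
    return out


def polymorphic_sites(
    pileup: Pileup, min_minor_freq: float = 0.2, min_depth: int = 10
) -> list[PolymorphicSite]:
    """Sites whose second most frequent base is well supported.

    Reported when depth >= ``min_depth`` and the minor (second) base
    frequency is >= ``min_minor_freq`` — the signature of more than one
    haplotype coexisting in the same host.
    """
    counts = pileup.counts
    depth = counts.sum(axis=0)
    order = np.argsort(counts, axis=0, kind="stable")
    major = order[-1]
    minor = order[-2]
    minor_count = np.take_along_axis(counts, minor[None, :], axis=0)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        minor_freq = np.where(depth > 0, minor_count / np.maximum(depth, 1), 0.0)
    hits = np.nonzero((depth >= min_depth) & (minor_freq >= min_minor_freq))[0]
    return [
        PolymorphicSite(
            position=int(p) + 1,
            major_base=BASES[major[p]],
            minor_base=BASES[minor[p]],
            minor_frequency=float(minor_freq[p]),
            depth=int(depth[p]),
        )
        for p in hits
    ]
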