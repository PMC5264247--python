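"""Species-specific marker database.

A :class:`MarkerDB` holds, per species, a set of marker genes: genes
present in (nearly) all genomes of the species and absent elsewhere.
Marker sequences provide the fixed coordinate frame for all consensus
reconstruction and SNV comparison, and an optional gene-family partition
per species supports the pangenome presence/absence track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["MarkerDB"]

_VALID = set("ACGT")


@dataclass
class MarkerDB:
    """Marker catalog: species -> marker ids, marker id -> sequence.

    Parameters
    ----------
    species_markers
        Mapping species label -> list of marker identifiers (globally unique).
    sequences
        Mapping marker identifier -> uppercase {A,C,G,T} sequence.
    families
        Optional mapping marker identifier -> gene-family label, partitioning
        each species' markers into gene families.
    """

    species_markers: dict[str, list[str]]
    sequences: dict[str, str]
    families: dict[str, str] | None = None

    def __post_init__(self):
        seen: set[str] = set()
        for sp, mids in self.species_markers.items():
            for mid in mids:
                if mid in seen:
                    raise ValueError(f"marker id {mid!r} is not globally unique")
                seen.add(mid)
                if mid not in self.sequences:
                    raise ValueError(f"marker {mid!r} of species {sp!r} has no sequence")
        for mid, seq in self.sequences.items():
            if not seq or not set(seq) <= _VALID:
                raise ValueError(
                    f"marker {mid!r}: sequence must be non-empty uppercase A/C/G/T"
                )
        self._species_of = {
            mid: sp for sp, mids in self.species_markers.items() for mid in mids
        }

    @property
    def species(self) -> list[str]:
        return sorted(self.species_markers)

    @property
    def marker_ids(self) -> list[str]:
        return sorted(self.sequences)

    def species_of(self, marker_id: str) -> str:
        return self._species_of[marker_id]

    def marker_length(self, marker_id: str) -> int:
        return len(self.sequences[marker_id])

    def families_of(self, species: str) -> dict[str, list[str]]:
        """Gene-family partition of one species: family label -> member markers."""
        if self.families is None:
            raise ValueError("marker database has no gene-family partition")
        out: dict[str, list[str]] = {}
        for mid in self.species_markers[species]:
            out.setdefault(self.families[mid], []).append(mid)
        return {fam: sorted(mids) for fam, mids in sorted(out.items())}

    def to_fasta(self, path) -> None:
        records = []
        for sp in sorted(self.species_markers):
            for mid in self.species_markers[sp]:
                desc = f"species={sp}"
                if self.families is not None:
                    desc += f" family={self.families[mid]}"
                records.append(SeqRecord(Seq(self.sequences[mid]), id=mid, description=desc))
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "MarkerDB":
        """Load a marker FASTA whose headers carry ``species=`` (and optionally
        ``family=``) key-value annotations."""
        species_markers: dict[str, list[str]] = {}
        sequences: dict[str, str] = {}
        families: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            attrs = dict(
                tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok
            )
            sp = attrs.get("species")
            if sp is None:
                raise ValueError(f"marker {rec.id!r}: header lacks 'species=' annotation")
            species_markers.setdefault(sp, []).append(rec.id)
            sequences[rec.id] = str(rec.seq).upper()
            if "family" in attrs:
                families[rec.id] = attrs["family"]
        return cls(species_markers, sequences, families or None)
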