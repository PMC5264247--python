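"""Synthetic mother-infant cohort generator.

Generates the inputs the analysis assumes, with known ground truth: a
species-specific marker database, per-subject dominant strains that
diverge 0.6-2.6% between unrelated subjects and (by default) 0% within
transmitted mother-infant pairs, substitution-only sequencing reads at
configurable depth and error rate, Dirichlet-distributed species
abundances, and optional paired RNA read sets with per-species expression
multipliers.  Every draw is governed by a single integer seed, and a fixed
configuration reproduces byte-identical output files.

The model is substitution-only (no indels), which keeps every simulated
strain in the marker reference coordinate frame — exactly the assumption
the consensus/SNV machinery relies on.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._seq import decode, encode, random_sequence
from .markers import MarkerDB
from .readprep import Read, write_fastq

__all__ = [
    "CohortConfig",
    "PairSpeciesTruth",
    "CohortTruth",
    "make_marker_db",
    "mutate_strain",
    "simulate_pair",
    "simulate_reads",
    "simulate_cohort",
]


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the observed cohort structure: strains of unrelated
    subjects differ at 0.6-2.6% of nucleotides, transmitted strains are
    identical up to sequencing error, and 14% of shared species are
    transmitted.  Sizes (3 markers x 1000 bp per species, 100 bp reads at
    20x) are desk-scale choices that keep every species comfortably above
    the 1000-column overlap needed for strain testing.
    """

    n_pairs: int = 5
    species_per_pair: int = 10
    markers_per_species: int = 3
    marker_len: int = 1000
    gene_families_per_species: int = 3
    transmission_prob: float = 0.14
    inter_subject_divergence_range: tuple[float, float] = (0.006, 0.026)
    transmitted_divergence: float = 0.0
    read_len: int = 100
    dna_depth: float = 20.0
    rna_expression_multipliers: dict[str, float] | None = None
    error_rate: float = 0.005
    abundance_dirichlet_alpha: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_pairs", "species_per_pair", "markers_per_species",
                     "marker_len", "gene_families_per_species", "read_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("transmission_prob", "transmitted_divergence", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.inter_subject_divergence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("inter_subject_divergence_range must satisfy 0 <= low <= high <= 1")
        if self.marker_len < self.read_len:
            raise ValueError("marker_len must be >= read_len")
        if self.dna_depth <= 0 or self.abundance_dirichlet_alpha <= 0:
            raise ValueError("dna_depth and abundance_dirichlet_alpha must be positive")
        if self.rna_expression_multipliers is not None:
            if any(v < 0 for v in self.rna_expression_multipliers.values()):
                raise ValueError("rna_expression_multipliers must be nonnegative")

    @property
    def species_names(self) -> list[str]:
        return [f"s{i + 1:02d}" for i in range(self.species_per_pair)]


@dataclass
class PairSpeciesTruth:
    """Ground truth for one (pair, species): who carries which strain."""

    pair: str
    species: str
    transmitted: bool
    mother_divergence: float
    infant_divergence: float
    mother_strain: dict[str, str]  # marker id -> sequence
    infant_strain: dict[str, str]


@dataclass
class CohortTruth:
    """Full generative ground truth of a simulated cohort.

    Sufficient to decide every downstream question: transmission verdicts,
    abundance profiles, and expected read counts per sample and species.
    """

    records: list[PairSpeciesTruth]
    abundances: dict[str, dict[str, float]]  # sample -> species -> fraction
    read_counts: dict[str, dict[str, int]]  # sample -> species -> DNA reads

    def transmitted(self, pair: str, species: str) -> bool:
        for rec in self.records:
            if rec.pair == pair and rec.species == species:
                return rec.transmitted
        raise KeyError((pair, species))

    def to_json(self, path) -> None:
        payload = {
            "records": [asdict(r) for r in self.records],
            "abundances": self.abundances,
            "read_counts": self.read_counts,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "CohortTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            records=[PairSpeciesTruth(**r) for r in payload["records"]],
            abundances=payload["abundances"],
            read_counts=payload["read_counts"],
        )

    def to_tsv(self, path) -> None:
        """Flat per (pair, species) table (sequences live in the JSON)."""
        lines = ["pair\tspecies\ttransmitted\tmother_divergence\tinfant_divergence"]
        for r in self.records:
            lines.append(
                f"{r.pair}\t{r.species}\t{int(r.transmitted)}"
                f"\t{r.mother_divergence:.6f}\t{r.infant_divergence:.6f}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_marker_db(
    n_species: int,
    markers_per_species: int,
    marker_len: int,
    seed: int,
    gene_families_per_species: int = 0,
) -> MarkerDB:
    """Random marker catalog: uniform {A,C,G,T} sequences, unique ids.

    When ``gene_families_per_species`` > 0, markers are partitioned
    round-robin into that many gene families per species.
    """
    if n_species < 1 or markers_per_species < 1 or marker_len < 1:
        raise ValueError("n_species, markers_per_species and marker_len must be >= 1")
    rng = _as_rng(seed)
    species_markers: dict[str, list[str]] = {}
    sequences: dict[str, str] = {}
    families: dict[str, str] = {}
    for i in range(n_species):
        sp = f"s{i + 1:02d}"
        mids = []
        for j in range(markers_per_species):
            mid = f"{sp}__M{j + 1:02d}"
            mids.append(mid)
            sequences[mid] = random_sequence(marker_len, rng)
            if gene_families_per_species > 0:
                families[mid] = f"{sp}__F{j % gene_families_per_species + 1:02d}"
        species_markers[sp] = mids
    return MarkerDB(species_markers, sequences, families or None)


def mutate_strain(reference: str, divergence: float, seed) -> str:
    """Derive a strain from a reference by random substitutions.

    The number of substituted positions is Binomial(L, divergence), sites
    are chosen without replacement, and each substituted base differs from
    the reference base.  divergence 0 returns the reference unchanged;
    divergence 1 changes every position.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence must be in [0, 1], got {divergence}")
    rng = _as_rng(seed)
    L = len(reference)
    n_sub = int(rng.binomial(L, divergence)) if 0.0 < divergence < 1.0 else int(round(divergence * L))
    if n_sub == 0:
        return reference
    positions = rng.choice(L, size=n_sub, replace=False)
    codes = encode(reference).copy()
    shifts = rng.integers(1, 4, size=n_sub).astype(np.uint8)
    codes[positions] = (codes[positions] + shifts) % 4
    return decode(codes)


def simulate_pair(
    config: CohortConfig,
    pair_id: str,
    db: MarkerDB,
    seed,
) -> tuple[dict[str, dict[str, str]], dict[str, dict[str, str]], list[PairSpeciesTruth]]:
    """Draw mother and infant strains for every species of one pair.

    Per species: the mother's strain diverges from the species reference by
    a uniform draw from ``inter_subject_divergence_range``; with
    probability ``transmission_prob`` the infant inherits the mother's
    strain (further mutated by ``transmitted_divergence``, 0 by default),
    otherwise the infant's strain is an independent draw from the
    reference at its own divergence.
    """
    rng = _as_rng(seed)
    lo, hi = config.inter_subject_divergence_range
    mother: dict[str, dict[str, str]] = {}
    infant: dict[str, dict[str, str]] = {}
    truth: list[PairSpeciesTruth] = []
    for sp in config.species_names:
        mids = db.species_markers[sp]
        m_div = float(rng.uniform(lo, hi))
        m_strain = {mid: mutate_strain(db.sequences[mid], m_div, rng) for mid in mids}
        transmitted = bool(rng.random() < config.transmission_prob)
        if transmitted:
            i_div = config.transmitted_divergence
            i_strain = {mid: mutate_strain(m_strain[mid], i_div, rng) for mid in mids}
        else:
            i_div = float(rng.uniform(lo, hi))
            i_strain = {mid: mutate_strain(db.sequences[mid], i_div, rng) for mid in mids}
        mother[sp] = m_strain
        infant[sp] = i_strain
        truth.append(
            PairSpeciesTruth(pair_id, sp, transmitted, m_div, i_div, m_strain, i_strain)
        )
    return mother, infant, truth


def simulate_reads(
    genome: str,
    depth: float,
    read_len: int,
    error_rate: float,
    seed,
    id_prefix: str = "r",
    base_quality: int = 37,
    degraded_quality: bool = False,
) -> list[Read]:
    """Substitution-only shotgun reads from one sequence.

    ceil(depth x L / read_len) reads, uniform start positions, per-base
    substitution errors at ``error_rate`` (error base always differs from
    the true base).  Qualities are a constant high Phred score by default;
    ``degraded_quality`` draws low-quality profiles (mean below 25, read
    ends below 15) to exercise the QC stage.
    """
    L = len(genome)
    if read_len > L:
        raise ValueError(f"read_len {read_len} exceeds genome length {L}")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    rng = _as_rng(seed)
    n_reads = math.ceil(depth * L / read_len)
    if n_reads == 0:
        return []
    codes = encode(genome)
    starts = rng.integers(0, L - read_len + 1, size=n_reads)
    block = codes[starts[:, None] + np.arange(read_len)[None, :]].copy()
    if error_rate > 0:
        err = rng.random(block.shape) < error_rate
        shifts = rng.integers(1, 4, size=block.shape).astype(np.uint8)
        block[err] = (block[err] + shifts[err]) % 4
    reads = []
    if degraded_quality:
        core = rng.integers(18, 30, size=(n_reads, read_len))
        tail = min(8, read_len // 2)
        core[:, :tail] = rng.integers(5, 15, size=(n_reads, tail))
        core[:, read_len - tail :] = rng.integers(5, 15, size=(n_reads, tail))
        quals = [tuple(int(q) for q in core[i]) for i in range(n_reads)]
    else:
        const = (base_quality,) * read_len
        quals = [const] * n_reads
    for i in range(n_reads):
        reads.append(Read(f"{id_prefix}{i:06d}", decode(block[i]), quals[i]))
    return reads


def _sample_name(pair_id: str, role: str) -> str:
    return f"{pair_id}_{'M' if role == 'mother' else 'I'}"


def simulate_cohort(
    config: CohortConfig, outdir
) -> tuple[dict, CohortTruth]:
    """Generate a full cohort: marker FASTA, per-sample FASTQ, truth table.

    Per sample, species abundances are a symmetric Dirichlet draw and the
    expected marker depth of species s is ``abundance_s x n_species x
    dna_depth`` (a uniform profile gives every species the configured
    fold-coverage).  RNA read sets are generated when expression
    multipliers are configured, with per-species depth additionally scaled
    by the multiplier.  Returns (manifest, truth); the manifest maps each
    sample to its role, pair, timepoint and file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    db = make_marker_db(
        config.species_per_pair,
        config.markers_per_species,
        config.marker_len,
        seed=rng,
        gene_families_per_species=config.gene_families_per_species,
    )
    db.to_fasta(outdir / "markers.fasta")

    species = config.species_names
    n_species = len(species)
    records: list[PairSpeciesTruth] = []
    abundances: dict[str, dict[str, float]] = {}
    read_counts: dict[str, dict[str, int]] = {}
    manifest: dict[str, dict] = {}
    mult = config.rna_expression_multipliers

    for p in range(config.n_pairs):
        pair_id = f"p{p + 1:02d}"
        mother, infant, truth = simulate_pair(config, pair_id, db, rng)
        records.extend(truth)
        for role, strains in (("mother", mother), ("infant", infant)):
            sample = _sample_name(pair_id, role)
            abund = rng.dirichlet([config.abundance_dirichlet_alpha] * n_species)
            abundances[sample] = {sp: float(a) for sp, a in zip(species, abund)}
            counts: dict[str, int] = {}
            dna_reads: list[Read] = []
            rna_reads: list[Read] = []
            for sp, a in zip(species, abund):
                depth = float(a) * n_species * config.dna_depth
                sp_reads: list[Read] = []
                for mid in db.species_markers[sp]:
                    sp_reads.extend(
                        simulate_reads(
                            strains[sp][mid],
                            depth,
                            config.read_len,
                            config.error_rate,
                            rng,
                            id_prefix=f"{sample}_{mid}_",
                        )
                    )
                counts[sp] = len(sp_reads)
                dna_reads.extend(sp_reads)
                if mult is not None:
                    rna_depth = depth * mult.get(sp, 1.0)
                    for mid in db.species_markers[sp]:
                        rna_reads.extend(
                            simulate_reads(
                                strains[sp][mid],
                                rna_depth,
                                config.read_len,
                                config.error_rate,
                                rng,
                                id_prefix=f"{sample}_rna_{mid}_",
                            )
                        )
            read_counts[sample] = counts
            dna_path = outdir / f"{sample}.dna.fastq"
            write_fastq(dna_reads, dna_path)
            entry = {
                "sample": sample,
                "role": role,
                "pair": pair_id,
                "timepoint": "t1",
                "dna": str(dna_path),
                "rna": None,
            }
            if mult is not None:
                rna_path = outdir / f"{sample}.rna.fastq"
                write_fastq(rna_reads, rna_path)
                entry["rna"] = str(rna_path)
            manifest[sample] = entry

    truth_obj = CohortTruth(records, abundances, read_counts)
    truth_obj.to_json(outdir / "truth.json")
    truth_obj.to_tsv(outdir / "truth.tsv")
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("sample\trole\tpair\ttimepoint\tdna\trna\n")
        for sample in sorted(manifest):
            e = manifest[sample]
            # paths relative to the output directory keep the file
            # byte-identical across runs in different locations
            rna = Path(e["rna"]).name if e["rna"] else "-"
            fh.write(
                f"{e['sample']}\t{e['role']}\t{e['pair']}\t{e['timepoint']}"
                f"\t{Path(e['dna']).name}\t{rna}\n"
            )
    return manifest, truth_obj
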