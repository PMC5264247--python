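"""End-to-end pipeline: QC -> mapping -> consensus -> strain comparison ->
transmission verdicts, with optional pangenome, transcription-activity and
virome stages.

A run is fully described by a :class:`RunConfig` (sample manifest, marker
database, parameter blocks with the documented defaults, seed); rerunning
the same configuration reproduces byte-identical outputs, and every output
is stamped with the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import consensus as cns
from . import pangenome as pan
from . import phylo
from . import readprep
from . import transcription as rnaseq
from . import transmission as tx
from . import virome as vir
from .markers import MarkerDB

__all__ = ["SampleSpec", "RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name, sample and cause."""

    def __init__(self, stage: str, sample: str | None, cause: Exception):
        super().__init__(f"stage {stage!r}" + (f" (sample {sample})" if sample else "")
                         + f" failed: {cause}")
        self.stage = stage
        self.sample = sample
        self.cause = cause


@dataclass
class SampleSpec:
    sample: str
    role: str  # mother | infant
    pair: str
    timepoint: str
    dna: str
    rna: str | None = None

    def __post_init__(self):
        if self.role not in ("mother", "infant"):
            raise ValueError(f"role must be 'mother' or 'infant', got {self.role!r}")


def _default(name, **kw):
    return field(default_factory=lambda: dict(kw))


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults are the documented values."""

    manifest: list[SampleSpec]
    marker_db: str
    outdir: str
    seed: int = 0
    viral_refs: str | None = None
    qc: dict = _default("qc", enabled=True, mean_q_min=25.0, trim_q=15, min_len=90)
    mapping: dict = _default("mapping", seed_len=21, min_identity=0.90)
    consensus: dict = _default("consensus", min_depth=3, majority_frac=0.5)
    selection: dict = _default("selection", min_unmasked=0.8, min_markers_frac=0.5)
    strain: dict = _default("strain", min_columns=1000)
    transmission: dict = _default("transmission", alpha=0.05, min_abundance=0.1)
    pangenome: dict = _default(
        "pangenome", min_coverage=1.0, left_max=1.70, right_min=0.30
    )
    nta: dict = _default("nta", rna_norm_percentile=90.0, rna_max_zeros=90.0)
    virome: dict = _default(
        "virome", min_depth=3, window=160, min_minor_freq=0.2, polymorphism_min_depth=10
    )

    def __post_init__(self):
        if not self.manifest:
            raise ValueError("manifest must not be empty")
        self.manifest = [
            SampleSpec(**s) if isinstance(s, dict) else s for s in self.manifest
        ]
        mothers = {(s.pair, s.timepoint) for s in self.manifest if s.role == "mother"}
        for s in self.manifest:
            if s.role == "infant" and (s.pair, s.timepoint) not in mothers:
                raise ValueError(
                    f"infant {s.sample!r} has no mother for pair {s.pair} at {s.timepoint}"
                )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)

    @classmethod
    def from_manifest_tsv(cls, manifest_path, marker_db: str, outdir: str, **kw) -> "RunConfig":
        df = pd.read_csv(manifest_path, sep="\t")
        specs = [
            SampleSpec(
                sample=row["sample"], role=row["role"], pair=row["pair"],
                timepoint=str(row["timepoint"]), dna=row["dna"],
                rna=None if row.get("rna") in (None, "-", "") or pd.isna(row.get("rna"))
                else row["rna"],
            )
            for row in df.to_dict("records")
        ]
        return cls(manifest=specs, marker_db=marker_db, outdir=outdir, **kw)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the run directory; returns the summary.

    Stage order: QC -> mapping -> consensus -> strain comparison ->
    transmission -> pangenome -> NTA (samples with RNA) -> virome (when
    viral references are configured).  Any stage failure raises
    :class:`PipelineError` naming the stage and sample; outputs written so
    far are preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "consensus").mkdir(exist_ok=True)
    (outdir / "trees").mkdir(exist_ok=True)
    log: list[str] = []
    chash = config.config_hash()
    log.append(f"config_hash={chash} seed={config.seed}")

    db = MarkerDB.from_fasta(config.marker_db)
    index = cns.MarkerIndex(db, config.mapping["seed_len"])

    # ------------------------------------------------------ per-sample stages
    per_sample: dict[str, dict] = {}
    counts_log: dict[str, dict] = {}
    for spec in config.manifest:
        try:
            reads = readprep.read_fastq(spec.dna)
            n_raw = len(reads)
            if config.qc["enabled"]:
                reads = readprep.quality_filter(
                    reads,
                    mean_q_min=config.qc["mean_q_min"],
                    trim_q=config.qc["trim_q"],
                    min_len=config.qc["min_len"],
                )
        except PipelineError:
            raise
        except Exception as e:  # pragma: no cover - defensive
            raise PipelineError("qc", spec.sample, e)
        try:
            alns = cns.map_reads(
                reads, db, min_identity=config.mapping["min_identity"], index=index
            )
            pileups = cns.build_pileup(alns, db)
        except Exception as e:
            raise PipelineError("mapping", spec.sample, e)
        try:
            consensuses = [
                cns.call_consensus(
                    pileups[mid],
                    min_depth=config.consensus["min_depth"],
                    majority_frac=config.consensus["majority_frac"],
                    sample=spec.sample,
                    species=db.species_of(mid),
                )
                for mid in sorted(pileups)
            ]
            retained = cns.select_markers(
                consensuses,
                db,
                min_unmasked=config.selection["min_unmasked"],
                min_markers_frac=config.selection["min_markers_frac"],
            )
            mean_depths = {}
            for sp in db.species:
                vals = [
                    pileups[mid].depth.mean() if mid in pileups else 0.0
                    for mid in db.species_markers[sp]
                ]
                mean_depths[sp] = float(np.mean(vals))
            profile = tx.estimate_abundance(mean_depths, spec.sample)
        except Exception as e:
            raise PipelineError("consensus", spec.sample, e)
        with open(outdir / "consensus" / f"{spec.sample}.fasta", "w") as fh:
            for sp in sorted(retained):
                for c in retained[sp]:
                    fh.write(f">{c.marker_id} sample={spec.sample} species={sp} "
                             f"unmasked={c.unmasked_fraction:.4f}\n{c.sequence}\n")
        keep_reads = spec.rna is not None or config.viral_refs is not None
        per_sample[spec.sample] = {
            "spec": spec,
            "reads": reads if keep_reads else None,
            "n_qc_reads": len(reads),
            "pileups": pileups,
            "retained": retained,
            "profile": profile,
        }
        counts_log[spec.sample] = {
            "raw_reads": n_raw,
            "qc_reads": len(reads),
            "aligned_reads": len(alns),
            "retained_species": len(retained),
        }
        log.append(
            f"sample={spec.sample} raw={n_raw} qc={len(reads)} aligned={len(alns)} "
            f"species_retained={len(retained)}"
        )

    # -------------------------------------------------------------- abundance
    ab_rows = [
        {"sample": s, "species": sp, "abundance_percent": a}
        for s, d in per_sample.items()
        for sp, a in sorted(d["profile"].abundances.items())
    ]
    _write_tsv(pd.DataFrame(ab_rows, columns=["sample", "species", "abundance_percent"]),
               outdir / "abundance.tsv")

    # ---------------------------------------------------------- shared species
    by_pair_tp: dict[tuple[str, str], dict[str, str]] = {}
    for s, d in per_sample.items():
        spec = d["spec"]
        by_pair_tp.setdefault((spec.pair, spec.timepoint), {})[spec.role] = s
    shared_by_pt: dict[tuple[str, str], list[str]] = {}
    for (pair, tp), roles in sorted(by_pair_tp.items()):
        if "mother" in roles and "infant" in roles:
            shared_by_pt[(pair, tp)] = tx.shared_species(
                per_sample[roles["mother"]]["profile"],
                per_sample[roles["infant"]]["profile"],
                min_abundance=config.transmission["min_abundance"],
            )
    _write_tsv(
        pd.DataFrame(
            [
                {"pair": pair, "timepoint": tp, "species": sp}
                for (pair, tp), sps in shared_by_pt.items()
                for sp in sps
            ],
            columns=["pair", "timepoint", "species"],
        ),
        outdir / "shared_species.tsv",
    )

    # --------------------------------------------- strain matrices & distances
    min_cols = config.strain["min_columns"]
    dists: dict[str, phylo.DistanceMatrix] = {}
    for sp in db.species:
        cons_by_sample = {
            s: d["retained"][sp] for s, d in per_sample.items() if sp in d["retained"]
        }
        if len(cons_by_sample) < 2:
            continue
        try:
            matrix = phylo.project_and_concatenate(cons_by_sample, sp)
            dm = phylo.distance_matrix(matrix, min_columns=min_cols)
        except ValueError:
            continue
        dists[sp] = dm
        dm.to_tsv(outdir / "trees" / f"{sp}.distances.tsv")
        if len(dm.labels) >= 3 and not np.isnan(dm.values).any():
            tree = phylo.nj_tree(dm)
            (outdir / "trees" / f"{sp}.nwk").write_text(str(tree))
    log.append(f"species_with_distances={len(dists)}")

    # ------------------------------------------------------------ transmission
    sample_pair = {s: d["spec"].pair for s, d in per_sample.items()}
    candidates = []
    for (pair, tp), sps in shared_by_pt.items():
        roles = by_pair_tp[(pair, tp)]
        mom, inf = roles["mother"], roles["infant"]
        for sp in sps:
            if sp not in dists:
                continue
            dm = dists[sp]
            if mom not in dm.labels or inf not in dm.labels:
                continue
            i, j = dm.labels.index(mom), dm.labels.index(inf)
            rate = dm.values[i, j]
            ncols = int(dm.n_columns[i, j])
            background = [
                float(dm.values[a, b])
                for a in range(len(dm.labels))
                for b in range(a + 1, len(dm.labels))
                if sample_pair[dm.labels[a]] != sample_pair[dm.labels[b]]
                and not np.isnan(dm.values[a, b])
            ]
            candidates.append((pair, tp, sp, rate, ncols, background))
    n_tests = sum(
        1 for (_, _, _, rate, _, bg) in candidates if not np.isnan(rate) and bg
    )
    results: list[tx.TransmissionResult] = []
    for pair, tp, sp, rate, ncols, background in candidates:
        if np.isnan(rate) or not background:
            p_value, verdict = None, tx.INSUFFICIENT
        else:
            p_value, verdict = tx.transmission_test(
                rate, ncols, background,
                alpha=config.transmission["alpha"],
                n_tests=max(n_tests, 1),
            )
        results.append(
            tx.TransmissionResult(
                pair, sp, tp, float(rate), tuple(background), ncols, p_value, verdict
            )
        )
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "pair": r.pair, "species": r.species, "timepoint": r.timepoint,
                    "pair_snv_rate": r.pair_snv_rate,
                    "min_background_rate": min(r.background_rates) if r.background_rates else float("nan"),
                    "n_background": len(r.background_rates),
                    "n_columns": r.n_columns,
                    "p_value": r.p_value if r.p_value is not None else float("nan"),
                    "verdict": r.verdict,
                }
                for r in results
            ],
            columns=["pair", "species", "timepoint", "pair_snv_rate",
                     "min_background_rate", "n_background", "n_columns",
                     "p_value", "verdict"],
        ),
        outdir / "transmission.tsv",
    )
    shared_by_pair: dict[str, list[str]] = {}
    for (pair, _), sps in shared_by_pt.items():
        shared_by_pair.setdefault(pair, [])
        shared_by_pair[pair] = sorted(set(shared_by_pair[pair]) | set(sps))
    summary = tx.cohort_summary(results, shared_by_pair)
    log.append(f"transmission_tests={n_tests} "
               f"transmitted={sum(1 for r in results if r.verdict == tx.TRANSMITTED)}")

    # --------------------------------------------------------------- pangenome
    plateau_rows = []
    profiles_by_species: dict[str, dict[str, dict[str, bool]]] = {}
    if db.families is not None:
        for s, d in per_sample.items():
            for sp in db.species:
                if len(db.families_of(sp)) < 2:
                    continue
                cov = pan.family_coverage_from_pileups(d["pileups"], db, s, sp)
                call = pan.detect_strain_plateau(
                    cov,
                    min_coverage=config.pangenome["min_coverage"],
                    left_max=config.pangenome["left_max"],
                    right_min=config.pangenome["right_min"],
                )
                plateau_rows.append(
                    {
                        "sample": s, "species": sp, "evaluable": call.evaluable,
                        "present": call.present, "plateau_median": call.plateau_median,
                        "genes_present": sum(call.gene_presence.values()),
                    }
                )
                if call.evaluable and call.present:
                    profiles_by_species.setdefault(sp, {})[s] = call.gene_presence
        _write_tsv(
            pd.DataFrame(plateau_rows, columns=["sample", "species", "evaluable",
                                                "present", "plateau_median",
                                                "genes_present"]),
            outdir / "pangenome.tsv",
        )
        for sp, profs in sorted(profiles_by_species.items()):
            if len(profs) >= 2:
                res = pan.hier_cluster_profiles(profs)
                (outdir / "trees" / f"{sp}.pangenome.nwk").write_text(res.to_newick() + "\n")

    # --------------------------------------------------------------------- NTA
    nta_rows = []
    activity_rows = []
    for s, d in per_sample.items():
        spec = d["spec"]
        if spec.rna is None:
            continue
        try:
            rna_reads = readprep.read_fastq(spec.rna)
            if config.qc["enabled"]:
                rna_reads = readprep.quality_filter(
                    rna_reads,
                    mean_q_min=config.qc["mean_q_min"],
                    trim_q=config.qc["trim_q"],
                    min_len=config.qc["min_len"],
                )
            rna_alns = cns.map_reads(
                rna_reads, db, min_identity=config.mapping["min_identity"], index=index
            )
            rna_pileups = cns.build_pileup(rna_alns, db)
        except Exception as e:
            raise PipelineError("nta", s, e)
        def depths_of(pileups):
            out: dict[str, dict[str, float]] = {}
            for sp in db.species:
                out[sp] = {
                    mid: float(pileups[mid].depth.mean()) if mid in pileups else 0.0
                    for mid in db.species_markers[sp]
                }
            return out
        profile = rnaseq.build_nta_profile(
            depths_of(d["pileups"]), depths_of(rna_pileups),
            total_dna_reads=d["n_qc_reads"], total_rna_reads=len(rna_reads),
            dna_sample=s, rna_sample=f"{s}_rna",
        )
        for sp, regions in profile.regions.items():
            for r in regions:
                nta_rows.append(
                    {"sample": s, "species": sp, "region": r.region,
                     "rna_depth": r.rna_depth, "dna_depth": r.dna_depth,
                     "nta": r.value if r.value is not None else float("nan")}
                )
            summ = rnaseq.species_activity_summary(
                profile, sp,
                rna_norm_percentile=config.nta["rna_norm_percentile"],
                rna_max_zeros=config.nta["rna_max_zeros"],
            )
            activity_rows.append(
                {"sample": s, "species": sp,
                 "evaluable": summ is not None,
                 "mean_nta": summ.mean if summ else float("nan"),
                 "sd_nta": summ.sd if summ else float("nan"),
                 "n_regions": summ.n_regions if summ else 0}
            )
    if nta_rows:
        _write_tsv(pd.DataFrame(nta_rows), outdir / "nta_regions.tsv")
        _write_tsv(pd.DataFrame(activity_rows), outdir / "nta_species.tsv")
        log.append(f"nta_samples={len({r['sample'] for r in nta_rows})}")

    # ------------------------------------------------------------------ virome
    if config.viral_refs is not None:
        genomes = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(config.viral_refs, "fasta")
        }
        vdb = MarkerDB({gid: [gid] for gid in genomes}, dict(genomes))
        vindex = cns.MarkerIndex(vdb, config.mapping["seed_len"])
        vrows, snv_rows, poly_rows = [], [], []
        snvs_by: dict[tuple[str, str], list[vir.ViralSNV]] = {}
        for s, d in per_sample.items():
            valns = cns.map_reads(
                d["reads"], vdb, min_identity=config.mapping["min_identity"],
                index=vindex,
            )
            for gid, genome in sorted(genomes.items()):
                summ = vir.viral_coverage(valns, genome, genome_id=gid, sample=s)
                vrows.append(
                    {"sample": s, "genome": gid, "breadth": summ.breadth,
                     "avg_depth": summ.avg_depth, "mapped_reads": summ.mapped_reads}
                )
                pile = cns.pileup_from_alignments(
                    [a for a in valns if a.marker_id == gid], gid, len(genome)
                )
                vcons = vir.viral_consensus_snvs(
                    pile, genome, min_depth=config.virome["min_depth"]
                )
                snvs_by[(s, gid)] = vcons.snvs
                for snv in vcons.snvs:
                    snv_rows.append(
                        {"sample": s, "genome": gid, "position": snv.position,
                         "ref": snv.ref_base, "alt": snv.consensus_base,
                         "frequency": snv.consensus_frequency, "depth": snv.depth}
                    )
                for site in vir.polymorphic_sites(
                    pile,
                    min_minor_freq=config.virome["min_minor_freq"],
                    min_depth=config.virome["polymorphism_min_depth"],
                ):
                    poly_rows.append(
                        {"sample": s, "genome": gid, "position": site.position,
                         "major": site.major_base, "minor": site.minor_base,
                         "minor_frequency": site.minor_frequency, "depth": site.depth}
                    )
        _write_tsv(pd.DataFrame(vrows, columns=["sample", "genome", "breadth",
                                                "avg_depth", "mapped_reads"]),
                   outdir / "virome.tsv")
        _write_tsv(pd.DataFrame(snv_rows, columns=["sample", "genome", "position",
                                                   "ref", "alt", "frequency", "depth"]),
                   outdir / "virome_snvs.tsv")
        _write_tsv(pd.DataFrame(poly_rows, columns=["sample", "genome", "position",
                                                    "major", "minor",
                                                    "minor_frequency", "depth"]),
                   outdir / "virome_polymorphic.tsv")
        win_rows = []
        for (pair, tp), roles in sorted(by_pair_tp.items()):
            if "mother" not in roles or "infant" not in roles:
                continue
            for gid, genome in sorted(genomes.items()):
                wins = vir.shared_variant_windows(
                    snvs_by.get((roles["mother"], gid), []),
                    snvs_by.get((roles["infant"], gid), []),
                    len(genome),
                    window=config.virome["window"],
                )
                for w in wins:
                    if w.shared or w.mother_only or w.infant_only:
                        win_rows.append(
                            {"pair": pair, "timepoint": tp, "genome": gid,
                             "start": w.start, "end": w.end, "shared": w.shared,
                             "mother_only": w.mother_only, "infant_only": w.infant_only}
                        )
        _write_tsv(pd.DataFrame(win_rows, columns=["pair", "timepoint", "genome",
                                                   "start", "end", "shared",
                                                   "mother_only", "infant_only"]),
                   outdir / "virome_windows.tsv")
        log.append(f"virome_genomes={len(genomes)}")

    # ----------------------------------------------------------------- summary
    summary_payload = {
        "config_hash": chash,
        "seed": config.seed,
        "n_samples": len(per_sample),
        "sample_counts": counts_log,
        "n_transmission_tests": n_tests,
        "verdicts": {
            f"{r.pair}:{r.species}:{r.timepoint}": r.verdict for r in results
        },
        "per_pair": summary.per_pair,
        "cohort_mean_transmitted_fraction": summary.cohort_mean_fraction,
        "replacements": summary.replacements,
        "indeterminate": summary.indeterminate,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary_payload, indent=1, sort_keys=True)
    )
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return summary_payload
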