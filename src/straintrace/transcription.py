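"""Normalized transcript abundance (NTA) from paired DNA/RNA samples.

NTA of a genomic region is the region's average metatranscriptome coverage
over the total RNA read count, divided by its average metagenome coverage
over the total DNA read count:

    nta = (depth_RNA / N_RNA) / (depth_DNA / N_DNA)

which makes it invariant to sequencing effort in either sample.  Regions
with zero DNA-normalized depth have undefined NTA and are excluded (and
counted) rather than smoothed with pseudocounts.  Species-level summaries
normalize region NTAs by the species' 90th-percentile NTA, and a species
with more than 90% zero-RNA regions is not evaluable — mirroring the
rna_norm_percentile 90 / rna_max_zeros 90 profiling parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RegionNTA",
    "NTAProfile",
    "ActivitySummary",
    "ActivityComparison",
    "nta",
    "build_nta_profile",
    "species_activity_summary",
    "compare_activity",
]


def nta(
    region_depth_rna: float,
    total_rna_reads: int,
    region_depth_dna: float,
    total_dna_reads: int,
) -> float:
    """Normalized transcript abundance of one region (see module docstring)."""
    if total_rna_reads <= 0 or total_dna_reads <= 0:
        raise ValueError("total read counts must be positive")
    if region_depth_dna <= 0:
        raise ValueError("NTA undefined for zero DNA depth; exclude the region")
    if region_depth_rna < 0:
        raise ValueError("RNA depth must be nonnegative")
    return (region_depth_rna / total_rna_reads) / (region_depth_dna / total_dna_reads)


@dataclass(frozen=True)
class RegionNTA:
    """NTA of one region (gene family or marker); ``value`` None if undefined."""

    region: str
    rna_depth: float
    dna_depth: float
    value: float | None


@dataclass
class NTAProfile:
    """Region-level NTA for one DNA/RNA sample pair, grouped by species."""

    dna_sample: str
    rna_sample: str
    total_dna_reads: int
    total_rna_reads: int
    regions: dict[str, list[RegionNTA]]  # species -> regions
    excluded_zero_dna: dict[str, int]  # species -> regions dropped (undefined NTA)

    def values(self, species: str) -> np.ndarray:
        """Defined region NTA values of one species."""
        return np.array(
            [r.value for r in self.regions[species] if r.value is not None]
        )


@dataclass(frozen=True)
class ActivitySummary:
    mean: float
    sd: float
    n_regions: int


@dataclass(frozen=True)
class ActivityComparison:
    species_a: str
    species_b: str
    fold_change: float
    p_value: float
    n_regions_a: int
    n_regions_b: int


def build_nta_profile(
    dna_depths: Mapping[str, Mapping[str, float]],
    rna_depths: Mapping[str, Mapping[str, float]],
    total_dna_reads: int,
    total_rna_reads: int,
    dna_sample: str = "dna",
    rna_sample: str = "rna",
) -> NTAProfile:
    """Assemble an NTA profile from per-species, per-region mean depths.

    Regions present in the DNA map define the universe; missing RNA depth
    counts as 0.  Zero-DNA regions are excluded and tallied.
    """
    regions: dict[str, list[RegionNTA]] = {}
    excluded: dict[str, int] = {}
    for sp in sorted(dna_depths):
        lst = []
        dropped = 0
        rna_sp = rna_depths.get(sp, {})
        for region in sorted(dna_depths[sp]):
            d_dna = float(dna_depths[sp][region])
            d_rna = float(rna_sp.get(region, 0.0))
            if d_dna <= 0:
                dropped += 1
                lst.append(RegionNTA(region, d_rna, d_dna, None))
                continue
            lst.append(
                RegionNTA(
                    region, d_rna, d_dna,
                    nta(d_rna, total_rna_reads, d_dna, total_dna_reads),
                )
            )
        regions[sp] = lst
        excluded[sp] = dropped
    return NTAProfile(
        dna_sample, rna_sample, total_dna_reads, total_rna_reads, regions, excluded
    )


def species_activity_summary(
    profile: NTAProfile,
    species: str,
    rna_norm_percentile: float = 90.0,
    rna_max_zeros: float = 90.0,
) -> ActivitySummary | None:
    """Mean/SD of percentile-normalized region NTAs, or None if not evaluable.

    Region NTAs are divided by the species' ``rna_norm_percentile``-th
    percentile NTA before summarizing; a species where more than
    ``rna_max_zeros`` percent of regions have zero RNA depth (or whose
    normalizing percentile is zero) is not evaluable.  SD uses the n-1
    (sample) convention; a single region has SD 0.
    """
    region_list = profile.regions.get(species, [])
    if not region_list:
        return None
    zero_rna = sum(1 for r in region_list if r.rna_depth == 0)
    if 100.0 * zero_rna / len(region_list) > rna_max_zeros:
        return None
    vals = profile.values(species)
    if len(vals) == 0:
        return None
    norm = float(np.percentile(vals, rna_norm_percentile))
    if norm <= 0:
        return None
    x = vals / norm
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return ActivitySummary(float(np.mean(x)), sd, len(x))


def compare_activity(
    profile: NTAProfile,
    species_a: str,
    species_b: str,
    rna_norm_percentile: float = 90.0,
    rna_max_zeros: float = 90.0,
) -> ActivityComparison:
    """Compare transcriptional activity of two species.

    fold_change is the ratio of mean raw region NTAs (A over B); the
    p-value is a two-sided Wilcoxon rank-sum (Mann-Whitney U) test on the
    two region-level NTA samples, exact for small tie-free samples.
    Raises if either species is not evaluable under the summary rules.
    """
    for sp in (species_a, species_b):
        if species_activity_summary(profile, sp, rna_norm_percentile, rna_max_zeros) is None:
            raise ValueError(f"species {sp!r} is not evaluable for activity comparison")
    x = profile.values(species_a)
    y = profile.values(species_b)
    mean_b = float(np.mean(y))
    if mean_b <= 0:
        raise ValueError(f"species {species_b!r} has zero mean NTA; fold change undefined")
    fold = float(np.mean(x)) / mean_b
    if species_a == species_b:
        return ActivityComparison(species_a, species_b, 1.0, 1.0, len(x), len(y))
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return ActivityComparison(
        species_a, species_b, fold, float(res.pvalue), len(x), len(y)
    )
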