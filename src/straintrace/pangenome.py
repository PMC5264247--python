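"""Pangenome track: gene-family coverage, plateau-based presence, clustering.

A strain of a species is declared present in a sample when the sorted
(descending) gene-family coverage curve shows a plateau: the median
coverage m must reach ``min_coverage``, the curve near the left edge (10th
percentile position) must not exceed ``left_max * m``, and near the right
edge (90th percentile position) must not fall below ``right_min * m``.
Thresholds follow the printed profiling parameters (min_coverage 1,
left_max 1.70, right_min 0.30); the exact edge positions are this
package's convention.  Gene presence within a present strain uses the same
``right_min * m`` cutoff, and presence/absence profiles are compared by
hierarchical clustering under Euclidean distance (average linkage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy

from .consensus import ReadAlignment, build_pileup
from .markers import MarkerDB

__all__ = [
    "GeneFamilyCoverage",
    "PlateauCall",
    "ClusterResult",
    "gene_family_coverage",
    "family_coverage_from_pileups",
    "detect_strain_plateau",
    "hier_cluster_profiles",
]


@dataclass
class GeneFamilyCoverage:
    """Mean fold-coverage per gene family of one species in one sample."""

    sample: str
    species: str
    depths: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.depths.values()):
            raise ValueError("family depths must be nonnegative")


@dataclass
class PlateauCall:
    """Strain presence/absence verdict and per-family gene presence."""

    sample: str
    species: str
    evaluable: bool
    present: bool
    plateau_median: float
    gene_presence: dict[str, bool]


@dataclass
class ClusterResult:
    """Hierarchical clustering of presence/absence profiles."""

    labels: list[str]  # sorted input labels, row order of linkage input
    families: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: list[str]

    def to_newick(self) -> str:
        """Dendrogram as a Newick string (merge heights as branch lengths)."""
        root = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return rec(root, root.dist).rsplit(":", 1)[0] + ";"


def family_coverage_from_pileups(
    pileups: Mapping[str, "object"],
    db: MarkerDB,
    sample: str,
    species: str,
) -> GeneFamilyCoverage:
    """Family coverage from already-built marker pileups (see
    :func:`gene_family_coverage`)."""
    families = db.families_of(species)
    depths: dict[str, float] = {}
    for fam, members in families.items():
        total_depth = 0.0
        total_len = 0
        for mid in members:
            total_len += db.marker_length(mid)
            if mid in pileups:
                total_depth += float(pileups[mid].depth.sum())
        depths[fam] = total_depth / total_len if total_len else 0.0
    return GeneFamilyCoverage(sample, species, depths)


def gene_family_coverage(
    alignments: Iterable[ReadAlignment],
    db: MarkerDB,
    sample: str,
    species: str,
) -> GeneFamilyCoverage:
    """Mean depth per gene family: summed per-position depth of the member
    genes divided by their summed length."""
    pileups = build_pileup(
        [a for a in alignments if db.species_of(a.marker_id) == species], db
    )
    return family_coverage_from_pileups(pileups, db, sample, species)


def detect_strain_plateau(
    cov: GeneFamilyCoverage,
    min_coverage: float = 1.0,
    left_max: float = 1.70,
    right_min: float = 0.30,
) -> PlateauCall:
    """Plateau-based strain presence call on one coverage profile.

    With the G family depths sorted descending into c(1..G) and m their
    median: present iff m >= ``min_coverage`` and c(ceil(0.10 G)) <=
    ``left_max`` * m and c(floor(0.90 G)) >= ``right_min`` * m.  Fewer than
    10 families cannot be evaluated.  Gene presence (only for present
    strains): depth >= ``right_min`` * m.
    """
    fams = sorted(cov.depths)
    G = len(fams)
    if G < 10:
        return PlateauCall(cov.sample, cov.species, False, False, float("nan"),
                           {f: False for f in fams})
    depths = np.array([cov.depths[f] for f in fams])
    c = np.sort(depths)[::-1]
    m = float(np.median(c))
    left = c[math.ceil(0.10 * G) - 1]   # 1-based curve position
    right = c[math.floor(0.90 * G) - 1]
    present = (m >= min_coverage) and (left <= left_max * m) and (right >= right_min * m)
    if present:
        presence = {f: bool(cov.depths[f] >= right_min * m) for f in fams}
    else:
        presence = {f: False for f in fams}
    return PlateauCall(cov.sample, cov.species, True, present, m, presence)


def hier_cluster_profiles(
    profiles: Mapping[str, Mapping[str, bool]],
) -> ClusterResult:
    """Cluster gene presence/absence profiles (Euclidean distance, average
    linkage).  All profiles must share the same family set; labels are
    processed in sorted order so the result is deterministic."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    labels = sorted(profiles)
    families = sorted(profiles[labels[0]])
    for lab in labels:
        if sorted(profiles[lab]) != families:
            raise ValueError(f"profile {lab!r} has a mismatched gene-family set")
    X = np.array([[float(bool(profiles[lab][f])) for f in families] for lab in labels])
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    leaves = hierarchy.dendrogram(Z, no_plot=True)["leaves"]
    return ClusterResult(labels, families, Z, [labels[i] for i in leaves])
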