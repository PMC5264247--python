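"""Strain comparison: SNV rates, distance matrices, neighbor-joining trees.

Reconstructed consensus marker sequences are concatenated in reference
coordinates (marker ids in lexicographic order, positions ascending), so
every sample's strain is a row of an aligned matrix with ``N`` marking
unknown positions.  The pairwise SNV rate between two strains is the
mismatch count over jointly unmasked columns, expressed per 100 columns —
so a printed SNV rate of 0.04 corresponds to 99.96% sequence identity.

Because substitution-only consensus rows are already co-linear, reference
projection replaces de novo multiple alignment, and neighbor-joining over
the SNV-rate matrix replaces likelihood-based tree inference; both are
deliberate, documented divergences from pipelines built on external
aligners and ML tree builders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._seq import N_CODE, as_codes, decode
from .consensus import ConsensusSequence

__all__ = [
    "StrainMatrix",
    "SnvRateResult",
    "DistanceMatrix",
    "project_and_concatenate",
    "snv_rate",
    "distance_matrix",
    "neighbor_joining",
    "nj_tree",
]


@dataclass
class StrainMatrix:
    """Aligned strain rows for one species across samples.

    ``codes`` is (n_rows, n_columns) uint8 with A,C,G,T -> 0..3 and N -> 4;
    columns are ordered by (marker id lexicographic, position ascending).
    """

    species: str
    samples: list[str]
    marker_ids: list[str]
    codes: np.ndarray

    def __post_init__(self):
        if self.codes.shape[0] != len(self.samples):
            raise ValueError("row count does not match sample labels")

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]

    def row(self, sample: str) -> np.ndarray:
        return self.codes[self.samples.index(sample)]

    def row_sequence(self, sample: str) -> str:
        return decode(self.row(sample))


@dataclass(frozen=True)
class SnvRateResult:
    """SNV rate (percent) between two strain rows over jointly unmasked columns."""

    rate: float
    n_columns: int
    sufficient: bool


@dataclass
class DistanceMatrix:
    """Pairwise SNV rates, percent scale; NaN marks insufficient overlap."""

    labels: list[str]
    values: np.ndarray  # (n, n) float, symmetric, zero diagonal
    n_columns: np.ndarray  # (n, n) int, jointly unmasked columns per pair

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def project_and_concatenate(
    consensuses_by_sample: Mapping[str, Sequence[ConsensusSequence]],
    species: str,
    reference_strains: Mapping[str, Mapping[str, str]] | None = None,
) -> StrainMatrix:
    """Concatenate each sample's retained marker consensuses at fixed coordinates.

    ``consensuses_by_sample`` maps sample label -> consensuses retained for
    this species in that sample.  Markers missing from a sample are filled
    with ``N`` in its row only.  Optional ``reference_strains`` (label ->
    marker id -> sequence) are appended as additional rows, e.g. available
    reference genomes projected onto the marker set.
    """
    per_sample: dict[str, dict[str, ConsensusSequence]] = {}
    marker_len: dict[str, int] = {}
    for sample, cons in consensuses_by_sample.items():
        rows = {}
        for c in cons:
            if c.species and c.species != species:
                continue
            rows[c.marker_id] = c
            prev = marker_len.setdefault(c.marker_id, len(c.sequence))
            if prev != len(c.sequence):
                raise ValueError(f"inconsistent lengths for marker {c.marker_id!r}")
        if rows:
            per_sample[sample] = rows
    if not per_sample:
        raise ValueError(f"species {species!r} absent from all samples")
    if len(per_sample) < 2 and not reference_strains:
        raise ValueError(f"species {species!r} retained in fewer than 2 samples")

    if reference_strains:
        for label, seqs in reference_strains.items():
            for mid, seq in seqs.items():
                prev = marker_len.setdefault(mid, len(seq))
                if prev != len(seq):
                    raise ValueError(f"inconsistent lengths for marker {mid!r}")

    marker_ids = sorted(marker_len)
    n_cols = sum(marker_len[m] for m in marker_ids)
    offsets = {}
    off = 0
    for mid in marker_ids:
        offsets[mid] = off
        off += marker_len[mid]

    samples = list(per_sample)
    ref_labels = list(reference_strains) if reference_strains else []
    codes = np.full((len(samples) + len(ref_labels), n_cols), N_CODE, dtype=np.uint8)
    for i, sample in enumerate(samples):
        for mid, c in per_sample[sample].items():
            o = offsets[mid]
            codes[i, o : o + marker_len[mid]] = as_codes(c.sequence)
    for j, label in enumerate(ref_labels):
        for mid, seq in reference_strains[label].items():
            o = offsets[mid]
            codes[len(samples) + j, o : o + marker_len[mid]] = as_codes(seq)
    return StrainMatrix(species, samples + ref_labels, marker_ids, codes)


def snv_rate(row_a, row_b, min_columns: int = 1000) -> SnvRateResult:
    """SNV rate between two aligned strain rows.

    rate = 100 x (mismatching jointly unmasked columns) / (jointly unmasked
    columns).  Pairs with fewer than ``min_columns`` jointly unmasked
    columns are flagged insufficient and must be excluded from identity
    testing (``sufficient`` False, rate NaN).
    """
    a = as_codes(row_a)
    b = as_codes(row_b)
    if a.shape != b.shape:
        raise ValueError("strain rows have different lengths")
    joint = (a != N_CODE) & (b != N_CODE)
    n = int(joint.sum())
    if n == 0 or n < min_columns:
        rate = float("nan") if n == 0 else 100.0 * int(((a != b) & joint).sum()) / n
        return SnvRateResult(rate, n, False)
    mism = int(((a != b) & joint).sum())
    return SnvRateResult(100.0 * mism / n, n, True)


def distance_matrix(matrix: StrainMatrix, min_columns: int = 1000) -> DistanceMatrix:
    """All pairwise SNV rates of a strain matrix.

    Insufficient-overlap pairs are NaN.  Raises if no pair at all has
    sufficient overlap.
    """
    n = len(matrix.samples)
    if n < 2:
        raise ValueError("need at least 2 rows")
    values = np.zeros((n, n))
    ncols = np.zeros((n, n), dtype=int)
    any_ok = False
    for i in range(n):
        ncols[i, i] = int((matrix.codes[i] != N_CODE).sum())
        for j in range(i + 1, n):
            r = snv_rate(matrix.codes[i], matrix.codes[j], min_columns)
            values[i, j] = values[j, i] = r.rate if r.sufficient else float("nan")
            ncols[i, j] = ncols[j, i] = r.n_columns
            any_ok = any_ok or r.sufficient
    if not any_ok:
        raise ValueError("all pairs have insufficient jointly unmasked overlap")
    return DistanceMatrix(list(matrix.samples), values, ncols)


def neighbor_joining(d: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Neighbor-joining on a distance matrix, deterministic under ties.

    Standard agglomeration (Saitou-Nei with the usual Q criterion); ties in
    Q are broken by lexicographic order of the joined clusters' labels,
    where an internal cluster carries the smallest leaf label beneath it.
    Negative estimated branch lengths are clamped to 0.  Two labels yield a
    cherry with half-distance branches.  Branch lengths are in the units of
    ``d``; the tree is returned as an skbio ``TreeNode`` (use
    ``str(tree)``/``tree.write`` for Newick).
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if n < 2:
        raise ValueError("need at least 2 labels")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains undefined (NaN) entries")
    if n == 2:
        half = d[0, 1] / 2.0
        root = TreeNode()
        root.extend([TreeNode(name=labels[0], length=half),
                     TreeNode(name=labels[1], length=half)])
        return root

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    keys: list[str] = list(labels)  # tie-break key: min leaf label of cluster
    D = d.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                pair_key = tuple(sorted((keys[idx[ai]], keys[idx[aj]])))
                cand = (q, pair_key, ai, aj)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, ai, aj = best
        i, j = idx[ai], idx[aj]
        dij = D[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        # new cluster reuses slot i
        for k in active:
            if k not in (i, j):
                D[i, k] = D[k, i] = (D[i, k] + D[j, k] - dij) / 2.0
        nodes[i] = parent
        keys[i] = min(keys[i], keys[j])
        active.remove(j)

    i, j = active
    # root at an internal node if possible; attach the other with the full
    # remaining distance so leaf-to-leaf path lengths are preserved
    if len(nodes[i].children) > 0:
        root, other = nodes[i], nodes[j]
    else:
        root, other = nodes[j], nodes[i]
    other.length = max(D[i, j], 0.0)
    root.append(other)
    return root


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Strain tree from an SNV-rate matrix.

    Branch lengths are the percent rates divided by 100 (substitutions per
    jointly unmasked site).
    """
    return neighbor_joining(dm.values / 100.0, dm.labels)
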