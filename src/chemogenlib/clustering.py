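"""Scaffold clustering on bioactivity profiles.

Each surviving scaffold is described by the binary vector of protein
entries its molecules hit.  Scaffolds are clustered by hierarchical
agglomeration on Jaccard distances between these profiles (average
linkage by default) and the dendrogram is cut into a fixed number of
clusters.  One representative scaffold is then picked per cluster by a
deterministic tie-break cascade: cluster medoid first, then most targets,
then most molecules, then smallest canonical SMILES.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .config import ConfigError, PipelineConfig
from .filtering import BioactivePair
from .records import DataIntegrityError


class UndefinedDistanceError(ValueError):
    """Jaccard distance is undefined when both vectors are all-zero."""


@dataclass
class ScaffoldTargetMatrix:
    """Binary scaffold x protein-entry bioactivity matrix.

    Row/column orders are fixed (sorted ids) and recorded so that runs
    are reproducible and sidecar files can name every axis entry.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray  # shape (rows, cols), dtype bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise DataIntegrityError("matrix shape does not match id lists")
        if self.values.size and not self.values.any(axis=1).all():
            raise DataIntegrityError("all-zero scaffold rows are not allowed")


@dataclass
class ClusterAssignment:
    """Cluster label (1..k) and representative flag per scaffold."""

    labels: dict[str, int]
    representatives: dict[int, str]

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def build_matrix(
    pairs: Iterable[BioactivePair],
    molecule_scaffolds: Mapping[str, str],
    surviving_scaffolds: set[str] | None = None,
) -> ScaffoldTargetMatrix:
    """Assemble the binary scaffold-by-protein matrix from retained pairs.

    A cell is 1 iff some retained molecule carrying that scaffold is
    bioactive on that protein entry.  Rows are restricted to
    ``surviving_scaffolds`` when given (promiscuity-pruned set).
    """
    hits: dict[str, set[str]] = {}
    for p in pairs:
        scaffold = molecule_scaffolds.get(p.molecule_id)
        if scaffold is None:
            continue
        if surviving_scaffolds is not None and scaffold not in surviving_scaffolds:
            continue
        hits.setdefault(scaffold, set()).add(p.ui_id)
    if not hits:
        raise DataIntegrityError("no scaffolds survive; cannot build matrix")
    row_ids = sorted(hits)
    col_ids = sorted(set().union(*hits.values()))
    col_index = {u: j for j, u in enumerate(col_ids)}
    values = np.zeros((len(row_ids), len(col_ids)), dtype=bool)
    for i, s in enumerate(row_ids):
        for u in hits[s]:
            values[i, col_index[u]] = True
    return ScaffoldTargetMatrix(row_ids=row_ids, col_ids=col_ids, values=values)


def jaccard_distance(x: Sequence[int], y: Sequence[int]) -> float:
    """Jaccard distance between two binary profiles.

    d = (b + c) / (a + b + c) where a counts shared 1s and b, c the
    mismatches; positions where both are 0 are ignored (the "binary"
    distance of classic statistical software, equal to 1 - Tanimoto).
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    union = np.logical_or(x, y).sum()
    if union == 0:
        raise UndefinedDistanceError("both vectors are all-zero")
    both = np.logical_and(x, y).sum()
    return float((union - both) / union)


def pairwise_jaccard(values: np.ndarray) -> np.ndarray:
    """Condensed pairwise Jaccard distance matrix for binary rows."""
    return pdist(np.asarray(values, dtype=bool), metric="jaccard")


def hcluster(
    matrix: ScaffoldTargetMatrix,
    k: int,
    cfg: PipelineConfig,
    molecule_counts: Mapping[str, int] | None = None,
) -> ClusterAssignment:
    """Agglomerative clustering of scaffold profiles, cut into k clusters.

    Deterministic for a fixed matrix (row order is fixed by construction).
    Cluster labels are relabelled to be contiguous 1..k in order of first
    appearance along the row order.  ``molecule_counts`` (scaffold id ->
    number of molecules carrying it) feeds tie-break 3 of the
    representative cascade; when omitted that tie-break is inert.
    """
    n = len(matrix.row_ids)
    if k > n:
        raise ConfigError(f"k={k} exceeds the number of scaffolds ({n})")
    if n == 1:
        raw = np.array([1])
        dist = np.zeros((1, 1))
    else:
        condensed = pairwise_jaccard(matrix.values)
        link = hierarchy.linkage(condensed, method=cfg.linkage)
        raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
        # maxclust can merge below k when heights tie; force exact k by
        # undoing merges explicitly
        if len(set(raw)) != k:
            raw = _cut_exact(link, n, k)
        dist = squareform(condensed)
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for sid, lab in zip(matrix.row_ids, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[sid] = relabel[lab]
    target_counts = matrix.values.sum(axis=1)
    molecule_counts = molecule_counts or {}
    stats = {
        sid: (int(target_counts[i]), int(molecule_counts.get(sid, 0)))
        for i, sid in enumerate(matrix.row_ids)
    }
    index = {sid: i for i, sid in enumerate(matrix.row_ids)}
    representatives = {}
    for lab in sorted(set(labels.values())):
        members = [sid for sid in matrix.row_ids if labels[sid] == lab]
        representatives[lab] = pick_representative(members, dist, index, stats)
    return ClusterAssignment(labels=labels, representatives=representatives)


def _cut_exact(link: np.ndarray, n: int, k: int) -> np.ndarray:
    # cut the dendrogram by undoing the last k-1 merges explicitly
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for m in range(n - k):
        a, b = int(link[m, 0]), int(link[m, 1])
        parent[find(a)] = n + m
        parent[find(b)] = n + m
    roots = {}
    out = np.empty(n, dtype=int)
    for i in range(n):
        r = find(i)
        roots.setdefault(r, len(roots) + 1)
        out[i] = roots[r]
    return out


def pick_representative(
    members: Sequence[str],
    dist: np.ndarray,
    index: Mapping[str, int],
    stats: Mapping[str, tuple[int, int]],
) -> str:
    """One scaffold per cluster via the deterministic tie-break cascade.

    1. medoid: minimal summed Jaccard distance to the other members;
    2. among ties, the scaffold hitting the most protein entries;
    3. then the scaffold carried by the most molecules;
    4. then the lexicographically smallest canonical SMILES.

    ``stats`` maps scaffold id to (n_targets, n_molecules).
    """
    if not members:
        raise ValueError("cluster has no members")

    def key(sid: str):
        i = index[sid]
        total = float(sum(dist[i, index[m]] for m in members if m != sid))
        n_targets, n_molecules = stats[sid]
        return (total, -n_targets, -n_molecules, sid)

    return min(members, key=key)
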