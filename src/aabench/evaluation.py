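"""Metrics and embedding-space analysis.

AUC is the rank-based Mann-Whitney estimator (midranks for ties), which
equals the trapezoidal ROC area.  The embedding-space analysis computes
pairwise Euclidean distances over all 21 token vectors (padding symbol
included), an average-linkage clustering for heat-map ordering, and a
permutation test of physicochemical group cohesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .encodings import ALPHABET, EncodingMatrix


class UndefinedAUCError(ValueError):
    """AUC requested with only one class present."""


@dataclass(frozen=True)
class MetricSummary:
    metric: str
    values: tuple[float, ...]
    mean: float
    sd: float

    @property
    def n_repetitions(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DistanceMatrix:
    values: np.ndarray  # (21, 21)
    labels: tuple[str, ...]
    scheme: str

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix / label size mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")


def compute_auc(scores, binary_labels) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binary_labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_accuracy(scores, binary_labels, threshold: float = 0.5) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binary_labels, dtype=int)
    return float(np.mean((scores >= threshold).astype(int) == labels))


def aggregate_repetitions(values, metric: str = "metric") -> MetricSummary:
    """Mean and sample (n-1) standard deviation over repetitions."""
    vals = tuple(float(v) for v in values)
    if not vals:
        raise ValueError("no repetition values given")
    arr = np.asarray(vals)
    sd = float(arr.std(ddof=1)) if len(vals) > 1 else 0.0
    return MetricSummary(metric, vals, float(arr.mean()), sd)


def pairwise_distance_matrix(matrix: EncodingMatrix) -> DistanceMatrix:
    """Euclidean distances between all 21 token vectors (pad row included)."""
    d = squareform(pdist(np.asarray(matrix.values), metric="euclidean"))
    return DistanceMatrix(d, ALPHABET.tokens, matrix.scheme)


def hierarchical_cluster_order(
    dm: DistanceMatrix, linkage: str = "average"
) -> tuple[list[int], np.ndarray]:
    """Agglomerative clustering of the distance matrix.

    Returns (leaf order for heat-map rendering, scipy linkage matrix).
    """
    z = hierarchy.linkage(squareform(dm.values, checks=False), method=linkage)
    return list(hierarchy.leaves_list(z)), z


def linkage_to_newick(z: np.ndarray, labels) -> str:
    """Serialize a scipy merge tree as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def group_cohesion_test(
    dm: DistanceMatrix,
    groups: dict[str, str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test of group cohesion in an embedding space.

    statistic = mean between-group distance - mean within-group distance
    over the amino acids named in ``groups`` (the pad symbol carries no
    group and is excluded).  The one-sided p-value is the +1-smoothed
    fraction of random label permutations with a statistic at least as
    large as observed.
    """
    members = [a for a in dm.labels if a in groups]
    counts: dict[str, int] = {}
    for a in members:
        counts[groups[a]] = counts.get(groups[a], 0) + 1
    if any(c < 2 for c in counts.values()) or len(counts) < 2:
        raise ValueError("every group must contain at least 2 amino acids")
    idx = [dm.labels.index(a) for a in members]
    sub = dm.values[np.ix_(idx, idx)]
    labels = np.array([groups[a] for a in members])

    iu = np.triu_indices(len(members), k=1)
    dists = sub[iu]

    def statistic(lab: np.ndarray) -> float:
        same = lab[iu[0]] == lab[iu[1]]
        return float(dists[~same].mean() - dists[same].mean())

    observed = statistic(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if statistic(rng.permutation(labels)) >= observed:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return observed, p


def distance_matrix_to_tsv(dm: DistanceMatrix) -> str:
    lines = ["\t" + "\t".join(dm.labels)]
    for label, row in zip(dm.labels, dm.values):
        lines.append(label + "\t" + "\t".join(f"{v:.12g}" for v in row))
    return "\n".join(lines) + "\n"
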