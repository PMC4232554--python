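"""Genomic relationships, principal components, and line clustering.

The kinship estimator is the VanRaden genomic relationship matrix
K = Z Z' / (2 sum_j p_j (1 - p_j)), with Z the dosage matrix centered by
twice the minor-allele frequency.  Optionally only a random fraction of
markers enters the estimate (the emulated pipeline's SNP.fraction setting).
Hierarchical clustering of lines uses complete linkage on the monotone
distance d_ij = max(K) - K_ij; cutting the tree yields the groups for
kinship compression in the compressed mixed linear model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .genotype_io import GenotypeMatrix


@dataclass
class KinshipMatrix:
    values: np.ndarray  # line x line, symmetric
    line_ids: list
    marker_fraction_used: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or n != len(self.line_ids):
            raise ValueError("kinship must be square over line_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    def stabilized(self) -> np.ndarray:
        """PSD-clamped copy: eigenvalues below -1e-8 * max are set to 0.

        Marker-subsampled kinship can be (slightly) indefinite; mixed-model
        code requires PSD.
        """
        w, v = np.linalg.eigh(self.values)
        if w.min() >= 0:
            return self.values
        w = np.clip(w, 0.0, None)
        return (v * w) @ v.T


@dataclass
class PCScores:
    scores: np.ndarray             # line x component
    explained_variance_ratio: np.ndarray
    line_ids: list

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores,
                          columns=[f"PC{i+1}" for i in
                                   range(self.scores.shape[1])])
        df.insert(0, "line_id", self.line_ids)
        return df


@dataclass
class LineDendrogram:
    linkage: np.ndarray  # scipy linkage matrix
    line_ids: list

    @property
    def leaf_order(self) -> np.ndarray:
        return np.asarray(hierarchy.leaves_list(self.linkage))

    def cut(self, n_groups: int) -> np.ndarray:
        """0-based group labels from cutting the tree into n_groups."""
        labels = hierarchy.fcluster(self.linkage, t=n_groups,
                                    criterion="maxclust")
        # relabel to 0..k-1 in order of first appearance for determinism
        _, inv = np.unique(labels, return_inverse=True)
        return inv

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)
        ids = self.line_ids

        def rec(node):
            if node.is_leaf():
                return f"{ids[node.id]}:0"
            left, right = node.get_left(), node.get_right()
            lb = node.dist - left.dist if not left.is_leaf() else node.dist
            rb = node.dist - right.dist if not right.is_leaf() else node.dist
            return (f"({rec(left).rsplit(':', 1)[0]}:{lb:g},"
                    f"{rec(right).rsplit(':', 1)[0]}:{rb:g})")

        return rec(tree) + ";"


def kinship(g: GenotypeMatrix, marker_fraction: float = 1.0,
            seed: int = 0) -> KinshipMatrix:
    """VanRaden genomic relationship matrix on a random marker subsample."""
    if not (0.0 < marker_fraction <= 1.0):
        raise ValueError("marker_fraction must lie in (0, 1]")
    if g.has_missing():
        raise ValueError("impute missing dosages before kinship")
    idx = np.arange(g.n_markers)
    if marker_fraction < 1.0:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=max(1, int(round(
            marker_fraction * g.n_markers))), replace=False))
    d = g.dosages[idx].astype(np.float64)
    p = d.mean(axis=1) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom == 0:
        raise ValueError("all subsampled markers are monomorphic")
    z = (d - 2.0 * p[:, None]).T  # lines x markers
    k = (z @ z.T) / denom
    k = 0.5 * (k + k.T)
    return KinshipMatrix(k, g.line_ids, marker_fraction, seed)


def write_kinship(k: KinshipMatrix, path) -> None:
    pd.DataFrame(k.values, index=k.line_ids, columns=k.line_ids) \
        .to_csv(path, sep="\t", index_label="line_id")


def read_kinship(path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix(df.to_numpy(dtype=float), list(df.columns))


def pca(g: GenotypeMatrix, n_components: int = 3) -> PCScores:
    """Principal-component scores of lines from the centered dosage matrix.

    Scores come from the singular decomposition of the line x marker matrix
    column-centered per marker; signs are fixed so each component's
    largest-magnitude marker loading is positive.
    """
    if g.has_missing():
        raise ValueError("impute missing dosages before PCA")
    if n_components >= min(g.n_lines, g.n_markers):
        raise ValueError("n_components must be < min(lines, markers)")
    x = g.dosages.T.astype(np.float64)
    x -= x.mean(axis=0)
    total_var = float((x ** 2).sum())
    if total_var <= 1e-12:
        raise ValueError("zero-variance genotype matrix")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    for i in range(n_components):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    return PCScores(scores=u * s, explained_variance_ratio=s ** 2 / total_var,
                    line_ids=g.line_ids)


def cluster_lines(k: KinshipMatrix, method: str = "complete",
                  distance: str = "gramian") -> LineDendrogram:
    """Complete-linkage hierarchical clustering of lines on a kinship-derived
    distance.

    The default distance is the one the kinship itself induces,
    d_ij = K_ii + K_jj - 2 K_ij (zero exactly for genomically identical
    lines, non-negative for PSD K).  The simpler monotone shift
    d_ij = max(K) - K_ij is available as ``distance="max_shift"``; it ranks
    pairs identically per row but gives identical lines a nonzero height
    whenever another line has a larger diagonal.  ``method="average"`` is
    available behind the flag.
    """
    if distance == "gramian":
        diag = np.diag(k.values)
        dist = diag[:, None] + diag[None, :] - 2.0 * k.values
    elif distance == "max_shift":
        dist = k.values.max() - k.values
    else:
        raise ValueError(f"unknown distance policy {distance!r}")
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = dist[np.triu_indices(k.n_lines, 1)]
    linkage = hierarchy.linkage(condensed, method=method)
    return LineDendrogram(linkage, list(k.line_ids))


def compress_kinship(k: KinshipMatrix, n_groups: int,
                     tree: LineDendrogram | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Group lines by cutting the cluster tree; average K within blocks.

    Returns (assignment, compressed) where ``assignment[i]`` is line i's
    group and ``compressed[a, b]`` is the mean of all pairwise kinship
    entries between groups a and b (diagonal blocks, including the
    line-level diagonal, averaged onto the compressed diagonal).
    """
    if not (1 <= n_groups <= k.n_lines):
        raise ValueError(f"n_groups must be in [1, {k.n_lines}]")
    if tree is None:
        tree = cluster_lines(k)
    assignment = tree.cut(n_groups)
    n_eff = assignment.max() + 1
    # incidence matrix group sums
    z = np.zeros((k.n_lines, n_eff))
    z[np.arange(k.n_lines), assignment] = 1.0
    sizes = z.sum(axis=0)
    block_sum = z.T @ k.values @ z
    compressed = block_sum / np.outer(sizes, sizes)
    compressed = 0.5 * (compressed + compressed.T)
    return assignment, compressed


def expand_compressed(assignment: np.ndarray, compressed: np.ndarray
                      ) -> np.ndarray:
    """Line-level covariance implied by a group-level kinship."""
    return compressed[np.ix_(assignment, assignment)]
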