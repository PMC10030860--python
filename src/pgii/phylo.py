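"""Phylogeny from inversion presence/absence.

The distance between two genomes is the normalized Hamming distance over
their presence states (pairwise-complete over missing values; a Jaccard
alternative is available), trees are built with UPGMA (arithmetic-mean
agglomeration, producing ultrametric trees), and concordance with an
external distance matrix (e.g. SNP distances) is assessed with a Mantel
permutation test.
"""

from __future__ import annotations

from itertools import permutations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform


def inversion_distance(matrix: pd.DataFrame, metric: str = "hamming") -> pd.DataFrame:
    """Genome x genome distance from the clusters x genomes presence matrix.

    hamming: share of jointly observed clusters where presence states
    differ. jaccard: 1 - |intersection| / |union| of carrier sets over
    jointly observed clusters.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two genomes")
    X = matrix.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    n = X.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[:, i] & obs[:, j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no jointly observed clusters for pair "
                    f"({matrix.columns[i]}, {matrix.columns[j]})"
                )
            xi, xj = X[both, i], X[both, j]
            if metric == "hamming":
                d[i, j] = d[j, i] = float((xi != xj).mean())
            elif metric == "jaccard":
                union = float(((xi > 0) | (xj > 0)).sum())
                inter = float(((xi > 0) & (xj > 0)).sum())
                d[i, j] = d[j, i] = 0.0 if union == 0 else 1.0 - inter / union
            else:
                raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def _validate_square(d: pd.DataFrame) -> np.ndarray:
    a = d.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("distance matrix is not square")
    if not np.allclose(a, a.T):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(a), 0):
        raise ValueError("distance matrix has nonzero diagonal")
    return a


def upgma(d: pd.DataFrame) -> str:
    """UPGMA tree in Newick format from a labelled distance matrix.

    Built on SciPy's arithmetic-mean (average) hierarchical clustering, so
    the merge heights are the mean pairwise distances; branch lengths place
    every leaf at identical depth (ultrametric). Labels are canonicalized
    to input-column order before clustering so that ties break
    deterministically.
    """
    labels = list(d.columns)
    a = _validate_square(d)
    if len(labels) == 1:
        return f"{labels[0]};"
    z = average(squareform(a, checks=False))
    n = len(labels)
    # node id -> (newick string without trailing length, height)
    nodes: List[Tuple[str, float]] = [(lab, 0.0) for lab in labels]
    for row in z:
        i, j, dist = int(row[0]), int(row[1]), float(row[2])
        height = dist / 2.0
        left, lh = nodes[i]
        right, rh = nodes[j]
        newick = f"({left}:{height - lh:.10g},{right}:{height - rh:.10g})"
        nodes.append((newick, height))
    return nodes[-1][0] + ";"


def _upper(a: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(a, k=1)
    return a[iu]


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> Tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the off-diagonal upper triangles; the
    p-value permutes the labels of ``d2`` and uses the add-one estimator.
    With ``exact=True`` (feasible for <= 8 labels) all label permutations
    are enumerated instead and the exact permutation p-value is returned.
    """
    if list(d1.columns) != list(d2.columns):
        raise ValueError("distance matrices must share labels and order")
    a = _validate_square(d1)
    b = _validate_square(d2)
    va = _upper(a)

    def corr(mat: np.ndarray) -> float:
        vb = _upper(mat)
        if va.std() == 0 or vb.std() == 0:
            return 0.0
        return float(np.corrcoef(va, vb)[0, 1])

    r_obs = corr(b)
    n = a.shape[0]
    if exact:
        count = 0
        total = 0
        for perm in permutations(range(n)):
            perm = np.array(perm)
            total += 1
            if corr(b[np.ix_(perm, perm)]) >= r_obs - 1e-12:
                count += 1
        return r_obs, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(b[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (n_perm + 1)


def newick_leaf_depths(newick: str) -> dict:
    """Root-to-leaf path lengths of a Newick tree (for ultrametricity checks)."""
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(newick), "newick")
    return {
        leaf.name: tree.distance(tree.root, leaf) for leaf in tree.get_terminals()
    }
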