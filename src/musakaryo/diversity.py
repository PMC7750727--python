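"""HE-masked identity-by-state distances and bootstrap trees.

Because homologous exchanges overwrite one subgenome with the other,
sites inside any accession's HE region distort between-accession
distances; diversity analysis therefore masks the union of HE
intervals over all analysed accessions before computing pairwise
identity-by-state (IBS) dissimilarity and an average-linkage tree with
site-bootstrap support.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "mask_he_regions",
    "ibs_dissimilarity",
    "cluster_with_bootstrap",
    "genotype_matrix",
]


def genotype_matrix(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Pivot a site-table (chrom, pos, ref, alt, sample columns) into an
    accessions x sites dosage matrix (NaN = missing)."""
    meta = ["chrom", "pos", "ref", "alt"]
    samples = [c for c in genotypes.columns if c not in meta]
    mat = genotypes[samples].to_numpy(dtype=float).T
    mat[mat < 0] = np.nan
    cols = pd.MultiIndex.from_frame(genotypes[["chrom", "pos"]])
    return pd.DataFrame(mat, index=samples, columns=cols)


def mask_he_regions(
    matrix: pd.DataFrame, intervals: list[tuple[str, int, int]]
) -> pd.DataFrame:
    """Drop sites inside any HE interval of any analysed accession.

    ``matrix`` is an accessions x sites dosage matrix whose columns are
    (chrom, pos) pairs; ``intervals`` are (chrom, start, end), 1-based
    inclusive. A site is retained iff it lies in none of the
    intervals. An empty interval list is the identity filter.
    """
    if not intervals:
        return matrix.copy()
    chroms = matrix.columns.get_level_values(0).to_numpy()
    pos = matrix.columns.get_level_values(1).to_numpy()
    keep = np.ones(len(pos), dtype=bool)
    for chrom, start, end in intervals:
        keep &= ~((chroms == chrom) & (pos >= start) & (pos <= end))
    return matrix.loc[:, keep]


def ibs_dissimilarity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - mean identity-by-state over shared non-missing sites.

    Per site, IBS between dosages g1, g2 in {0, 1, 2} is
    ``1 - |g1 - g2| / 2``; missing genotypes are handled by pairwise
    deletion. The result is symmetric with a zero diagonal. Pairs with
    no overlapping sites get NaN and trigger a warning.
    """
    if len(matrix) < 2:
        raise ValueError("need >=2 accessions")
    g = matrix.to_numpy(dtype=float)
    n = g.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(g[i]) & ~np.isnan(g[j])
            if not both.any():
                warnings.warn(
                    f"no overlapping sites for pair ({matrix.index[i]}, {matrix.index[j]})"
                )
                out[i, j] = out[j, i] = np.nan
                continue
            d = float(np.mean(np.abs(g[i, both] - g[j, both])) / 2.0)
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=matrix.index, columns=matrix.index)


def _linkage(dist: pd.DataFrame) -> np.ndarray:
    return hierarchy.linkage(squareform(dist.to_numpy(), checks=False), method="average")


def _clades(link: np.ndarray, labels: list[str]) -> list[frozenset[str]]:
    """Leaf-label sets of every internal node of a linkage tree."""
    n = len(labels)
    members: dict[int, frozenset[str]] = {i: frozenset([labels[i]]) for i in range(n)}
    clades = []
    for k, (a, b, _d, _c) in enumerate(link):
        m = members[int(a)] | members[int(b)]
        members[n + k] = m
        clades.append(m)
    return clades


def _to_newick(node, labels: list[str], supports: dict[frozenset[str], float]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels, supports)
    right = _to_newick(node.get_right(), labels, supports)
    leafset = frozenset(labels[i] for i in node.pre_order(lambda x: x.id))
    label = supports.get(leafset)
    label_str = "" if label is None else f"{label:.2f}"
    return f"({left},{right}){label_str}"


def cluster_with_bootstrap(
    matrix: pd.DataFrame, n_boot: int = 100, seed: int = 0
) -> tuple[str, dict[frozenset[str], float]]:
    """Average-linkage tree with site-bootstrap clade support.

    Sites (columns) are resampled with replacement ``n_boot`` times;
    the support of each internal node of the reference tree is the
    fraction of replicate trees containing the same leaf set.
    Deterministic under a fixed seed.

    Returns
    -------
    (newick, supports)
        A Newick string with supports as internal node labels, and the
        support per clade (leaf-label frozenset).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    labels = [str(x) for x in matrix.index]
    dist = ibs_dissimilarity(matrix)
    if dist.isna().any().any():
        raise ValueError("dissimilarity matrix has missing entries; cannot cluster")
    link = _linkage(dist)
    ref_clades = _clades(link, labels)

    rng = np.random.default_rng(seed)
    counts = {c: 0 for c in ref_clades}
    n_sites = matrix.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_sites, size=n_sites)
        boot = matrix.iloc[:, cols]
        bdist = ibs_dissimilarity(boot)
        bclades = set(_clades(_linkage(bdist), labels))
        for c in counts:
            if c in bclades:
                counts[c] += 1
    supports = {c: counts[c] / n_boot for c in counts}
    # the root clade (all leaves) is trivially present in every tree
    tree = hierarchy.to_tree(link)
    newick = _to_newick(tree, labels, supports) + ";"
    return newick, supports
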