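"""Comparative analyses over signature matrices.

Three outputs drive the phage-host inference: non-metric multidimensional
scaling (nMDS) ordinations of Euclidean Z-score distances, ANOSIM tests of
group separation, and bootstrapped neighbor-joining consensus cladograms
built from Pearson dissimilarities of Z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode
from sklearn.isotonic import isotonic_regression

__all__ = [
    "OrdinationResult",
    "AnosimResult",
    "Cladogram",
    "euclidean_distances",
    "pearson_dissimilarities",
    "correlation_scatter",
    "nmds",
    "anosim",
    "neighbor_joining",
    "bootstrap_consensus",
    "majority_consensus",
    "write_distance_tsv",
    "read_distance_tsv",
]


# ---------------------------------------------------------------------------
# distances


def euclidean_distances(sig: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance matrix between signature rows."""
    if sig.shape[0] < 2:
        raise ValueError("need at least 2 signature rows")
    d = squareform(pdist(sig.to_numpy(), metric="euclidean"))
    return DistanceMatrix(d, ids=[str(i) for i in sig.index])


def pearson_dissimilarities(
    sig: pd.DataFrame, convention: str = "one_minus_r"
) -> DistanceMatrix:
    """Pearson dissimilarity matrix d = 1 - r between signature rows.

    ``convention`` selects the dialect: ``"one_minus_r"`` gives d in [0, 2]
    (the default), ``"half"`` gives (1 - r)/2 in [0, 1].
    """
    if convention not in ("one_minus_r", "half"):
        raise ValueError(f"unknown convention {convention!r}")
    x = sig.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 signature rows")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = [str(sig.index[i]) for i in np.where(sd == 0)[0]]
        raise ValueError(f"zero-variance signature rows: {bad}")
    r = np.corrcoef(x)
    d = 1.0 - r
    if convention == "half":
        d = d / 2.0
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return DistanceMatrix(d, ids=[str(i) for i in sig.index])


def correlation_scatter(
    sig: pd.DataFrame,
    focal_ids: Sequence[str],
    include_focal: bool = True,
) -> pd.DataFrame:
    """Pearson r of every signature row against two focal rows.

    Returns a table indexed by sequence id with one column per focal id;
    ``include_focal=False`` drops the focal rows themselves.
    """
    if len(focal_ids) != 2:
        raise ValueError("exactly two focal ids required")
    missing = [f for f in focal_ids if f not in sig.index]
    if missing:
        raise KeyError(f"focal ids not in signature matrix: {missing}")
    x = sig.to_numpy(dtype=float)
    out = {}
    for f in focal_ids:
        fv = sig.loc[f].to_numpy(dtype=float)
        xm = x - x.mean(axis=1, keepdims=True)
        fm = fv - fv.mean()
        r = (xm @ fm) / (
            np.sqrt((xm**2).sum(axis=1)) * np.sqrt((fm**2).sum())
        )
        out[f"r_with_{f}"] = r
    df = pd.DataFrame(out, index=sig.index.copy())
    if not include_focal:
        df = df.drop(index=list(focal_ids))
    return df


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_data_frame().to_csv(path, sep="\t", float_format="%.6f")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(c) for c in df.columns])


# ---------------------------------------------------------------------------
# nMDS


@dataclass(frozen=True)
class OrdinationResult:
    """Best non-metric MDS configuration over multiple random starts."""

    coordinates: pd.DataFrame
    stress: float
    n_starts_used: int
    best_start_seed: int


def _classical_scaling(d: np.ndarray, dims: int) -> np.ndarray:
    """Classical (Torgerson) metric scaling, used as the first nMDS start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)


def _nmds_single(
    d_condensed: np.ndarray,
    order: np.ndarray,
    init: np.ndarray,
    max_iter: int,
    eps: float,
) -> tuple[np.ndarray, float]:
    """One SMACOF run of Kruskal non-metric MDS from a given configuration.

    Each iteration fits monotone (isotonic) disparities to the configuration
    distances in dissimilarity-rank order, then applies the Guttman
    transform.  Stops when stress-1 improves by less than ``eps``.
    """
    n, _ = init.shape
    x = init.copy()
    iu, ju = np.triu_indices(n, k=1)
    prev = np.inf
    stress = np.inf
    for _ in range(max_iter):
        dist = pdist(x)
        dhat = np.empty_like(dist)
        dhat[order] = isotonic_regression(dist[order])
        denom = (dist**2).sum()
        if denom == 0:
            break
        stress = np.sqrt(((dist - dhat) ** 2).sum() / denom)
        if prev - stress < eps:
            break
        prev = stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        b = np.zeros((n, n))
        b[iu, ju] = -ratio
        b[ju, iu] = -ratio
        b[np.arange(n), np.arange(n)] = -b.sum(axis=1)
        x = b @ x / n
    dist = pdist(x)
    denom = (dist**2).sum()
    if denom > 0:
        dhat = np.empty_like(dist)
        dhat[order] = isotonic_regression(dist[order])
        stress = np.sqrt(((dist - dhat) ** 2).sum() / denom)
    return x, float(stress)


def nmds(
    dm: DistanceMatrix,
    dims: int = 2,
    n_starts: int = 1000,
    seed: int = 0,
    max_iter: int = 300,
    eps: float = 1e-7,
) -> OrdinationResult:
    """Kruskal non-metric MDS with multiple starts, keeping the lowest stress.

    Start 0 is initialised from classical metric scaling of the
    dissimilarities; the remaining starts are random, each seeded
    deterministically from ``seed``.  Stress is Kruskal's stress-1 computed
    on monotone (isotonic) disparities.  Ties between starts go to the
    lowest start index, so results are reproducible and best-of-m starts is
    never worse than best-of-k for k < m.
    """
    d = np.asarray(dm.data, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains non-finite values")
    n = d.shape[0]
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} points for {dims}-D nMDS")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    d_condensed = squareform(d, checks=False)
    order = np.argsort(d_condensed, kind="stable")
    best_coords, best_stress, best_idx = None, np.inf, -1
    for i in range(n_starts):
        if i == 0:
            init = _classical_scaling(d, dims)
        else:
            rng = np.random.default_rng([int(seed), i])
            init = rng.standard_normal((n, dims))
        coords, stress = _nmds_single(d_condensed, order, init, max_iter, eps)
        if stress < best_stress:
            best_coords, best_stress, best_idx = coords, float(stress), i
    best_coords = best_coords - best_coords.mean(axis=0)
    cols = [f"nmds{j + 1}" for j in range(dims)]
    frame = pd.DataFrame(best_coords, index=list(dm.ids), columns=cols)
    frame.index.name = "sequence_id"
    return OrdinationResult(
        coordinates=frame,
        stress=best_stress,
        n_starts_used=n_starts,
        best_start_seed=best_idx,
    )


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass(frozen=True)
class AnosimResult:
    """ANOSIM R statistic with its permutation p-value."""

    R: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]


def _anosim_r(ranks: np.ndarray, between: np.ndarray) -> float:
    m = ranks.size
    rb = ranks[between].mean()
    rw = ranks[~between].mean()
    return (rb - rw) / (m / 2.0)


def anosim(
    dm: DistanceMatrix,
    groups: Mapping[str, str],
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities: rank-based test of group separation.

    R = (mean between-group rank - mean within-group rank) / (M/2) over the
    M = n(n-1)/2 pairwise distances, ranked with mid-ranks for ties.  The
    p-value permutes group labels: p = (1 + #{R_perm >= R_obs}) / (1 + n_perm).
    """
    ids = list(dm.ids)
    try:
        labels = np.array([groups[i] for i in ids])
    except KeyError as e:
        raise KeyError(f"no group label for sequence {e.args[0]!r}") from None
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if counts.min() < 2:
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"groups with fewer than 2 members: {small}")

    condensed = squareform(np.asarray(dm.data, dtype=float), checks=False)
    ranks = rankdata(condensed)  # mid-ranks for ties
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)

    between = labels[iu] != labels[ju]
    r_obs = _anosim_r(ranks, between)

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, perm[iu] != perm[ju]) >= r_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return AnosimResult(
        R=float(r_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        group_sizes={str(u): int(c) for u, c in zip(uniq, counts)},
    )


# ---------------------------------------------------------------------------
# trees


@dataclass
class Cladogram:
    """An unrooted tree with branch lengths and optional bootstrap support.

    The topology is held as a ``skbio.TreeNode`` whose root is a
    trifurcation (the standard unrooted display).  Support values, when
    present, are percentages attached to internal nodes.
    """

    tree: TreeNode

    @property
    def leaf_names(self) -> frozenset[str]:
        return frozenset(t.name for t in self.tree.tips())

    def bipartitions(self) -> dict[frozenset[str], float | None]:
        """Non-trivial bipartitions keyed by the side not holding the
        reference (lexicographically smallest) taxon; values are supports."""
        taxa = self.leaf_names
        ref = min(taxa)
        out: dict[frozenset[str], float | None] = {}
        for node in self.tree.preorder(include_self=False):
            if node.is_tip():
                continue
            side = frozenset(node.subset())
            if len(side) < 2 or len(taxa - side) < 2:
                continue
            key = side if ref not in side else taxa - side
            out[key] = getattr(node, "support", None)
        return out

    def branch_lengths(self) -> dict[frozenset[str] | str, float]:
        """Edge lengths keyed by bipartition (internal) or taxon (pendant)."""
        taxa = self.leaf_names
        ref = min(taxa)
        out: dict[frozenset[str] | str, float] = {}
        for node in self.tree.preorder(include_self=False):
            length = node.length if node.length is not None else 0.0
            if node.is_tip():
                out[node.name] = out.get(node.name, 0.0) + length
            else:
                side = frozenset(node.subset())
                if len(side) < 2 or len(taxa - side) < 2:
                    continue
                key = side if ref not in side else taxa - side
                out[key] = out.get(key, 0.0) + length
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths; integer support values become
        internal node labels."""

        def quote(name: str) -> str:
            if any(c in name for c in " _();:,'[]"):
                return "'" + name.replace("'", "''") + "'"
            return name

        def fmt(node: TreeNode, top: bool = False) -> str:
            if node.is_tip():
                label = quote(node.name or "")
            else:
                inner = ",".join(fmt(c) for c in node.children)
                sup = getattr(node, "support", None)
                label = f"({inner})"
                if sup is not None and not top:
                    label += str(int(round(sup)))
            if not top and node.length is not None:
                label += f":{node.length:g}"
            return label

        return fmt(self.tree, top=True) + ";"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def neighbor_joining(dm: DistanceMatrix) -> Cladogram:
    """Saitou-Nei neighbor joining on a distance matrix.

    Q-matrix ties are broken by the smallest (i, j) index pair.  Negative
    branch-length estimates are clamped to 0 with the deficit moved to the
    sister branch, so the pair's path length is preserved.  The result is
    unrooted (trifurcating root).
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.asarray(dm.data, dtype=float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]

    while len(nodes) > 3:
        m = d.shape[0]
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = q[iu]
        k = int(np.argmin(flat))  # first minimum in row-major order
        i, j = int(iu[0][k]), int(iu[1][k])

        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        elif lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)

        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])

        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.empty((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[x] for x in keep] + [parent]

    # final trifurcation: closed-form branch lengths
    da, db, dc = d[0, 1], d[0, 2], d[1, 2]
    ls = [
        0.5 * (da + db - dc),
        0.5 * (da + dc - db),
        0.5 * (db + dc - da),
    ]
    for node, length in zip(nodes, ls):
        node.length = float(max(length, 0.0))
    root = TreeNode(children=list(nodes))
    return Cladogram(tree=root)


def majority_consensus(trees: Sequence[Cladogram]) -> Cladogram:
    """Majority-rule (>50%) consensus of trees sharing one leaf set.

    The consensus contains exactly the bipartitions present in more than
    half of the input trees, each annotated with its occurrence percentage.
    Internal branch lengths are averaged over the trees containing the
    bipartition; pendant lengths over all trees.
    """
    if not trees:
        raise ValueError("no trees given")
    taxa = trees[0].leaf_names
    for t in trees[1:]:
        if t.leaf_names != taxa:
            raise ValueError("trees have mismatched leaf sets")
    ref = min(taxa)
    n_trees = len(trees)

    counts: dict[frozenset[str], int] = {}
    length_sums: dict[frozenset[str] | str, float] = {}
    for t in trees:
        bips = t.bipartitions()
        for key in bips:
            counts[key] = counts.get(key, 0) + 1
        for key, length in t.branch_lengths().items():
            length_sums[key] = length_sums.get(key, 0.0) + length

    kept = {k: c for k, c in counts.items() if c / n_trees > 0.5}

    # nest clades (all exclude ref, all pairwise compatible): parent of a
    # clade is the smallest kept clade strictly containing it
    ordered = sorted(kept, key=len, reverse=True)
    clade_nodes: dict[frozenset[str], TreeNode] = {}
    root = TreeNode()
    for clade in ordered:
        node = TreeNode()
        node.support = 100.0 * kept[clade] / n_trees
        node.length = length_sums.get(clade, 0.0) / kept[clade]
        parent = root
        best = None
        for other in ordered:
            if len(other) > len(clade) and clade < other:
                if best is None or len(other) < len(best):
                    best = other
        if best is not None:
            parent = clade_nodes[best]
        parent.append(node)
        clade_nodes[clade] = node
    for taxon in sorted(taxa):
        leaf = TreeNode(name=taxon)
        leaf.length = length_sums.get(taxon, 0.0) / n_trees
        parent = root
        best = None
        for clade in ordered:
            if taxon in clade and (best is None or len(clade) < len(best)):
                best = clade
        if best is not None:
            parent = clade_nodes[best]
        parent.append(leaf)
    return Cladogram(tree=root)


def bootstrap_consensus(
    sig: pd.DataFrame,
    n_boot: int = 500,
    seed: int = 0,
    convention: str = "one_minus_r",
) -> Cladogram:
    """Bootstrapped neighbor-joining consensus cladogram from a signature
    matrix.

    Each replicate resamples the 256 tetranucleotide columns with
    replacement, recomputes Pearson dissimilarities and a neighbor-joining
    tree; the majority-rule consensus carries per-edge support percentages.
    """
    if sig.shape[0] < 4:
        raise ValueError("bootstrap consensus needs at least 4 signature rows")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    ncol = sig.shape[1]
    trees = []
    for _ in range(n_boot):
        cols = rng.integers(0, ncol, size=ncol)
        boot = sig.iloc[:, cols]
        trees.append(neighbor_joining(pearson_dissimilarities(boot, convention)))
    return majority_consensus(trees)
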