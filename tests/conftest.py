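"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations (double-loop
counters, exhaustive permutation, graph-path distances) kept independent of
the package code paths they check.
"""

from __future__ import annotations

import itertools
from collections import Counter

import networkx as nx
import numpy as np
import pytest

from ecosig.signatures import reverse_complement


def naive_kmer_counts(seq: str, k: int) -> Counter:
    """Double-loop window counter over a sequence and its reverse
    complement, skipping N-containing windows."""
    counts: Counter = Counter()
    for strand in (seq.upper(), reverse_complement(seq.upper())):
        for i in range(len(strand) - k + 1):
            w = strand[i : i + k]
            if "N" not in w:
                counts[w] += 1
    return counts


def random_dna(rng: np.random.Generator, length: int, n_frac: float = 0.0) -> str:
    alphabet = "ACGTN" if n_frac > 0 else "ACGT"
    p = (
        [(1 - n_frac) / 4] * 4 + [n_frac]
        if n_frac > 0
        else [0.25] * 4
    )
    return "".join(rng.choice(list(alphabet), size=length, p=p))


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths.

    Returns (distance matrix, labels, {bipartition frozenset: length},
    {taxon: pendant length}); distances are exact path lengths, so the
    matrix is additive by construction.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    g = nx.Graph()
    active = list(range(n_taxa))
    next_id = n_taxa
    for leaf in active:
        g.add_node(leaf)
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[j], active[i]
        new = next_id
        next_id += 1
        g.add_edge(a, new, weight=float(rng.uniform(0.5, 2.0)))
        g.add_edge(b, new, weight=float(rng.uniform(0.5, 2.0)))
        active = [x for x in active if x not in (a, b)] + [new]
    center = next_id
    for a in active:
        g.add_edge(a, center, weight=float(rng.uniform(0.5, 2.0)))

    d = np.zeros((n_taxa, n_taxa))
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            d[i, j] = d[j, i] = paths[i][j]

    taxa = frozenset(labels)
    ref = min(taxa)
    internal_lengths = {}
    pendant_lengths = {}
    for u, v, data in g.edges(data=True):
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = frozenset(labels[x] for x in comp if x < n_taxa)
        other = taxa - side
        if len(side) == 1 or len(other) == 1:
            (taxon,) = side if len(side) == 1 else other
            pendant_lengths[taxon] = data["weight"]
        else:
            key = side if ref not in side else other
            internal_lengths[key] = data["weight"]
    return d, labels, internal_lengths, pendant_lengths


def exhaustive_anosim_p(d: np.ndarray, labels: list[str]) -> tuple[float, float]:
    """Exact ANOSIM R and p over all label permutations (small n only)."""
    from scipy.spatial.distance import squareform
    from scipy.stats import rankdata

    n = len(labels)
    ranks = rankdata(squareform(d, checks=False))
    iu, ju = np.triu_indices(n, k=1)
    m = ranks.size

    def r_stat(lab):
        lab = np.asarray(lab)
        between = lab[iu] != lab[ju]
        return (ranks[between].mean() - ranks[~between].mean()) / (m / 2)

    r_obs = r_stat(labels)
    count = 0
    total = 0
    for perm in itertools.permutations(labels):
        total += 1
        if r_stat(perm) >= r_obs - 1e-12:
            count += 1
    return r_obs, count / total


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_panel():
    """A compact host/phage panel reused across comparative tests."""
    from ecosig.synthetic import simulate_panel

    return simulate_panel(
        n_hosts=3,
        phages_per_host=2,
        host_length=100_000,
        phage_length=20_000,
        divergence_between_hosts=0.6,
        seed=11,
        include_migrant=True,
    )


@pytest.fixture(scope="session")
def small_signatures(small_panel):
    from ecosig.signatures import signature_matrix

    return signature_matrix(small_panel.records)
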