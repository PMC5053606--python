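"""Social-network topologies and edge-list IO.

The social network is an undirected simple graph ``G = (V, E)`` held in a
:class:`networkx.Graph`.  A neighbor ``w`` of ``v`` exerts influence weight
``1/|N(v)|`` on ``v``, so the incoming influence weights of every
non-isolated node sum to one.

Three synthetic generators are provided, mirroring the topologies commonly
used in behavior-diffusion studies:

* preferential attachment — each arriving node links to one existing node
  with probability proportional to (degree + 1), yielding a heavy-tailed
  tree of ``n - 1`` edges;
* small world — a ring lattice whose edges are independently rewired with a
  fixed probability;
* spatially clustered — nodes placed uniformly in the unit square, with the
  spatially closest pairs joined until a target mean degree is reached.

Edge lists use the SNAP dialect: whitespace-separated node pairs, ``#``
comment lines ignored.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import EdgeListParseError, InvalidParameterError

log = logging.getLogger(__name__)

__all__ = [
    "gen_preferential_attachment",
    "gen_small_world",
    "gen_spatially_clustered",
    "read_edge_list",
    "write_edge_list",
    "influence_weight",
]


def gen_preferential_attachment(n: int, rng_seed) -> nx.Graph:
    """Grow an undirected preferential-attachment tree on ``n`` nodes.

    Starting from a single edge, each arriving node adds one link to an
    existing node chosen with probability proportional to its current
    degree, giving a connected tree with ``n - 1`` edges and a heavy-tailed
    degree distribution.
    """
    if n < 2:
        raise InvalidParameterError(f"need n >= 2 nodes, got {n}")
    rng = np.random.default_rng(rng_seed)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edge(0, 1)
    # bag holds one entry per edge endpoint, so uniform draws from it
    # realize P(attach to v) proportional to deg(v)
    bag = [0, 1]
    for new in range(2, n):
        target = bag[rng.integers(len(bag))]
        G.add_edge(new, target)
        bag.extend((new, target))
    return G


def gen_small_world(
    n: int, lattice_k: int = 2, p_rewire: float = 0.2, rng_seed=None
) -> nx.Graph:
    """Watts–Strogatz small-world graph.

    Starts from a ring lattice where every node is linked to its
    ``lattice_k / 2`` nearest neighbors on each side, then rewires each
    lattice edge independently with probability ``p_rewire`` to a uniformly
    random non-duplicate, non-self target.  Edge count is preserved.
    """
    if lattice_k < 2 or lattice_k % 2 != 0:
        raise InvalidParameterError(f"lattice_k must be an even count >= 2, got {lattice_k}")
    if n <= lattice_k:
        raise InvalidParameterError(f"need n > lattice_k, got n={n}, lattice_k={lattice_k}")
    if not 0.0 <= p_rewire <= 1.0:
        raise InvalidParameterError(f"p_rewire must lie in [0, 1], got {p_rewire}")
    seed = int(np.random.default_rng(rng_seed).integers(2**31 - 1))
    return nx.watts_strogatz_graph(n, lattice_k, p_rewire, seed=seed)


def gen_spatially_clustered(n: int, avg_degree: float = 10.0, rng_seed=None) -> nx.Graph:
    """Spatially clustered random geometric graph with a target mean degree.

    Nodes are placed uniformly at random in the unit square and edges are
    inserted between the spatially nearest pairs, in increasing order of
    distance, until the mean degree first reaches ``avg_degree``.  Because
    edges connect nearby points, neighborhoods overlap and the graph shows
    the high clustering typical of spatial social networks.
    """
    if avg_degree < 1:
        raise InvalidParameterError(f"avg_degree must be >= 1, got {avg_degree}")
    if avg_degree > n - 1:
        raise InvalidParameterError(
            f"avg_degree={avg_degree} infeasible for n={n} (max mean degree is n-1)"
        )
    rng = np.random.default_rng(rng_seed)
    pts = rng.random((n, 2))
    m_edges = int(np.ceil(avg_degree * n / 2.0))

    # query progressively larger neighborhoods until enough distinct pairs
    kq = min(n - 1, max(8, int(3 * avg_degree)))
    tree = cKDTree(pts)
    while True:
        dist, idx = tree.query(pts, k=kq + 1)
        src = np.repeat(np.arange(n), kq)
        dst = idx[:, 1:].ravel()
        d = dist[:, 1:].ravel()
        lo = np.minimum(src, dst)
        hi = np.maximum(src, dst)
        pairs = np.unique(np.stack([lo, hi, d]).T, axis=0)
        # sorted by (lo, hi); re-sort by distance
        order = np.argsort(pairs[:, 2], kind="stable")
        pairs = pairs[order]
        if len(pairs) >= m_edges or kq == n - 1:
            break
        kq = min(n - 1, kq * 2)

    G = nx.Graph()
    G.add_nodes_from(range(n))
    take = pairs[:m_edges]
    G.add_edges_from(zip(take[:, 0].astype(int), take[:, 1].astype(int)))
    return G


def read_edge_list(path) -> nx.Graph:
    """Read an undirected graph from a SNAP-style edge list.

    Duplicate lines and reversed duplicates collapse to one edge; self-loops
    are dropped with a warning; node identifiers are kept verbatim as
    strings.  ``#``-prefixed lines are comments.
    """
    path = Path(path)
    G = nx.Graph()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise EdgeListParseError(path, lineno, raw.rstrip("\n"))
            a, b = tokens
            if a == b:
                log.warning("%s:%d: dropping self-loop on node %r", path, lineno, a)
                G.add_node(a)
                continue
            G.add_edge(a, b)
    return G


def write_edge_list(G: nx.Graph, path) -> None:
    """Write ``G`` in the same whitespace-delimited dialect the reader accepts."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# undirected edge list: {G.number_of_nodes()} nodes, "
                 f"{G.number_of_edges()} edges\n")
        for a, b in G.edges():
            fh.write(f"{a} {b}\n")


def influence_weight(G: nx.Graph, v, w) -> float:
    """Influence weight ``b_{v,w} = 1/|N(v)|`` exerted by neighbor ``w`` on ``v``."""
    if not G.has_edge(v, w):
        raise ValueError(f"{w!r} is not a neighbor of {v!r}")
    return 1.0 / G.degree(v)
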