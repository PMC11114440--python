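"""Weighted functional graphs and betweenness-centrality hub profiles.

A subject's band-specific PLI matrix defines a complete undirected graph
over the electrodes in which stronger coupling means a shorter path:
the length of the edge (i, j) is 1 / PLI(i, j), and a zero-PLI pair has
no edge.  The hub statistic is normalized betweenness centrality

    b_i = [ sum over ordered pairs (h, j), h != j != i, of
            rho_hj(i) / rho_hj ] / ((n - 1)(n - 2))

with rho_hj the number of shortest h->j paths and rho_hj(i) those passing
through i; co-minimal paths split credit equally; unreachable pairs
contribute nothing.  The normalization maps a star center to exactly 1
and every leaf of a tree to 0.  Betweenness is computed on the whole
weighted graph — no minimum-spanning-tree pruning, which would discard
the weak links that shape global paths.

Shortest paths use Dijkstra with Brandes' dependency accumulation; path
ties are resolved by counting, never by arbitrary tie-breaks, with
relative tolerance 1e-12 on length comparisons.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
import numpy as np

from .connectivity import ConnectivityMatrix

#: Relative tolerance for deciding two path lengths are co-minimal.
TIE_RTOL = 1e-12


@dataclass
class FunctionalGraph:
    """Undirected graph with positive edge lengths (inf = no edge)."""

    labels: tuple[str, ...]
    lengths: np.ndarray  # n x n, symmetric, inf off-graph, diagonal ignored

    def __post_init__(self) -> None:
        L = np.asarray(self.lengths, dtype=float)
        if L.ndim != 2 or L.shape[0] != L.shape[1]:
            raise ValueError("length matrix must be square")
        if L.shape[0] != len(self.labels):
            raise ValueError("labels do not match matrix size")
        if not np.array_equal(L, L.T):
            raise ValueError("length matrix must be symmetric")
        off = L[~np.eye(L.shape[0], dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("edge lengths must be positive")
        self.lengths = L

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class HubProfile:
    """Normalized betweenness per electrode for one subject and band."""

    subject_id: str
    band_name: str
    labels: tuple[str, ...]
    bc: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.bc, dtype=float)
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("normalized betweenness must lie in [0, 1]")
        self.bc = np.clip(v, 0.0, 1.0)


def graph_from_pli(conn: ConnectivityMatrix) -> FunctionalGraph:
    """Complete graph minus zero-PLI edges; length = 1 / PLI."""
    pli = conn.values
    with np.errstate(divide="ignore"):
        lengths = np.where(pli > 0, 1.0 / np.where(pli > 0, pli, 1.0), np.inf)
    labels = conn.labels or tuple(str(i) for i in range(pli.shape[0]))
    return FunctionalGraph(labels=tuple(labels), lengths=lengths)


def _brandes_accumulate(lengths: np.ndarray) -> np.ndarray:
    """Sum over ordered source/target pairs of fractional path dependencies."""
    n = lengths.shape[0]
    neighbors = [np.flatnonzero(np.isfinite(lengths[v])) for v in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        preds: list[list[int]] = [[] for _ in range(n)]
        dist[s] = 0.0
        sigma[s] = 1.0
        done = np.zeros(n, dtype=bool)
        order: list[int] = []
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            d, v = heapq.heappop(heap)
            if done[v]:
                continue
            done[v] = True
            order.append(v)
            dv = dist[v]
            for w in neighbors[v]:
                if w == v or done[w]:
                    continue
                cand = dv + lengths[v, w]
                dw = dist[w]
                if not np.isfinite(dw):
                    dist[w] = cand
                    sigma[w] = sigma[v]
                    preds[w] = [v]
                    heapq.heappush(heap, (cand, w))
                    continue
                tol = TIE_RTOL * max(abs(cand), abs(dw))
                if cand < dw - tol:
                    dist[w] = cand
                    sigma[w] = sigma[v]
                    preds[w] = [v]
                    heapq.heappush(heap, (cand, w))
                elif abs(cand - dist[w]) <= tol:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc


def betweenness(graph: FunctionalGraph) -> np.ndarray:
    """Normalized betweenness b_i in [0, 1] for every node.

    Each unordered pair is visited from both of its endpoints as a source,
    so the accumulated dependencies already sum over ordered pairs; the
    (n-1)(n-2) normalization then bounds b_i by 1, attained exactly when i
    sits on every shortest path between every other pair.
    """
    n = graph.n
    if n < 3:
        raise ValueError("betweenness normalization needs at least 3 nodes")
    return _brandes_accumulate(graph.lengths) / ((n - 1) * (n - 2))


def hub_profile(conn: ConnectivityMatrix) -> HubProfile:
    """PLI matrix -> normalized betweenness profile for one subject/band."""
    graph = graph_from_pli(conn)
    return HubProfile(subject_id=conn.subject_id, band_name=conn.band_name,
                      labels=graph.labels, bc=betweenness(graph))
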