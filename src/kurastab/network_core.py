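"""Weighted structural networks: containers, text I/O and degree-preserving nulls.

A structural network couples two symmetric non-negative matrices over the same
node set: coupling strengths (GFA-scale, dimensionless) and mean tract lengths
(mm).  An edge exists iff both its strength and its length are positive, and the
graph induced by the edges must be connected — the null-model generator preserves
connectedness, so disconnected inputs are rejected up front.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "StructuralNetwork",
    "NetworkValidationError",
    "RewiringError",
    "read_network",
    "write_network",
    "randomize_network",
]

#: relative tolerance within which an input matrix may deviate from symmetry
#: before being rejected; matrices within tolerance are exactly symmetrised.
SYMMETRY_RTOL = 1e-8


class NetworkValidationError(ValueError):
    """A matrix pair violates the structural-network contract."""


class RewiringError(RuntimeError):
    """Degree-preserving rewiring could not achieve any successful swap."""


@dataclass(frozen=True)
class StructuralNetwork:
    """Symmetric weighted network with per-edge coupling strengths and tract lengths.

    Parameters
    ----------
    weights
        N x N symmetric matrix of coupling strengths (dimensionless, GFA scale).
    lengths
        N x N symmetric matrix of mean tract lengths in mm, sharing the support
        of ``weights``.
    labels
        N node identifiers; defaults to ``n0 .. n{N-1}``.
    """

    weights: np.ndarray
    lengths: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "lengths", lengths)
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"n{i}" for i in range(weights.shape[0]))
            )
        self.validate()

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def degree_sequence(self) -> np.ndarray:
        """Sorted binary degree sequence."""
        return np.sort((self.weights > 0).sum(axis=0))

    def edge_list(self) -> list[tuple[int, int, float, float]]:
        """Upper-triangle edges as ``(i, j, weight, length)`` tuples, i < j."""
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        return [
            (int(i), int(j), float(self.weights[i, j]), float(self.lengths[i, j]))
            for i, j in zip(ii, jj)
        ]

    def to_graph(self) -> nx.Graph:
        """networkx view with ``weight`` and ``length`` edge attributes."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for i, j, w, ln in self.edge_list():
            g.add_edge(i, j, weight=w, length=ln)
        return g

    def validate(self) -> None:
        w, ln = self.weights, self.lengths
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NetworkValidationError(f"weights matrix is not square: {w.shape}")
        if ln.shape != w.shape:
            raise NetworkValidationError(
                f"dimension mismatch: weights {w.shape} vs lengths {ln.shape}"
            )
        if len(self.labels) != w.shape[0]:
            raise NetworkValidationError(
                f"{len(self.labels)} labels for {w.shape[0]} nodes"
            )
        for name, m in (("weights", w), ("lengths", ln)):
            if not np.all(np.isfinite(m)):
                bad = np.argwhere(~np.isfinite(m))
                raise NetworkValidationError(f"non-finite {name} at {bad[:5].tolist()}")
            if not np.array_equal(m, m.T):
                bad = np.argwhere(m != m.T)
                raise NetworkValidationError(f"{name} asymmetric at {bad[:5].tolist()}")
            if np.any(np.diag(m) != 0):
                bad = np.nonzero(np.diag(m))[0]
                raise NetworkValidationError(
                    f"nonzero diagonal in {name} at nodes {bad[:5].tolist()}"
                )
            if np.any(m < 0):
                bad = np.argwhere(m < 0)
                raise NetworkValidationError(f"negative {name} at {bad[:5].tolist()}")
        support_mismatch = (w > 0) != (ln > 0)
        if np.any(support_mismatch):
            bad = np.argwhere(support_mismatch)
            raise NetworkValidationError(
                "edge support of weights and lengths differs at "
                f"{bad[:5].tolist()} (an edge needs both a strength and a length)"
            )
        if w.shape[0] > 1:
            g = nx.from_numpy_array(w > 0)
            if not nx.is_connected(g):
                comp = sorted(nx.connected_components(g), key=len)[0]
                raise NetworkValidationError(
                    f"graph is disconnected; smallest component: {sorted(comp)}"
                )


def _symmetrise(m: np.ndarray, name: str) -> np.ndarray:
    scale = max(np.abs(m).max(), 1.0)
    asym = np.abs(m - m.T)
    if asym.max() > SYMMETRY_RTOL * scale:
        bad = np.argwhere(asym > SYMMETRY_RTOL * scale)
        raise NetworkValidationError(
            f"{name} asymmetric beyond tolerance at {bad[:5].tolist()}"
        )
    out = (m + m.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return out


def _load_matrix(path: str | Path, header: bool) -> tuple[np.ndarray, list[str] | None]:
    path = Path(path)
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    labels: list[str] | None = None
    skip = 0
    if header:
        first = text.splitlines()[0]
        labels = [t.strip() for t in (first.split(",") if delimiter else first.split())]
        skip = 1
    m = np.loadtxt(path, delimiter=delimiter, skiprows=skip, ndmin=2)
    return m, labels


def read_network(
    weights_path: str | Path,
    lengths_path: str | Path,
    header: bool = False,
) -> StructuralNetwork:
    """Read a structural network from two delimited-text square matrices.

    Comma- or whitespace-delimited; with ``header=True`` the first row of the
    weights file carries node labels.  Near-symmetric input (relative deviation
    below :data:`SYMMETRY_RTOL`) is symmetrised by averaging; anything worse is
    an error naming the offending indices.
    """
    w, labels = _load_matrix(weights_path, header)
    ln, _ = _load_matrix(lengths_path, header)
    if w.shape != ln.shape:
        raise NetworkValidationError(
            f"dimension mismatch: {weights_path} is {w.shape}, "
            f"{lengths_path} is {ln.shape}"
        )
    if w.shape[0] != w.shape[1]:
        raise NetworkValidationError(f"matrices are not square: {w.shape}")
    w = _symmetrise(w, "weights")
    ln = _symmetrise(ln, "lengths")
    return StructuralNetwork(w, ln, tuple(labels) if labels else ())


def write_network(
    net: StructuralNetwork,
    weights_path: str | Path,
    lengths_path: str | Path,
    sidecar_path: str | Path | None = None,
    provenance: dict | None = None,
) -> None:
    """Write weight/length matrices as delimited text plus an optional JSON sidecar.

    The ``%.17g`` format round-trips float64 exactly, so write-then-read is
    bit-identical.
    """
    np.savetxt(weights_path, net.weights, fmt="%.17g", delimiter=",")
    np.savetxt(lengths_path, net.lengths, fmt="%.17g", delimiter=",")
    if sidecar_path is not None:
        meta = {"labels": list(net.labels), "n_nodes": net.n_nodes}
        if provenance:
            meta["provenance"] = provenance
        Path(sidecar_path).write_text(json.dumps(meta, indent=2) + "\n")


def randomize_network(
    net: StructuralNetwork,
    swaps_per_edge: int = 10,
    seed: int | None = None,
) -> StructuralNetwork:
    """Degree-preserving connected rewiring (Maslov-Sneppen double-edge swaps).

    Each successful swap replaces edges (a,b),(c,d) by (a,d),(c,b); the
    (weight, length) attribute pair travels with its surviving endpoint ``a``
    resp. ``c``, so the multiset of edge attribute pairs is conserved along with
    the node count, edge count and per-node degree sequence.  A swap that would
    disconnect the graph is reverted, mirroring the connectedness-preserving
    rewiring null model standard in brain-network analysis.

    Parameters
    ----------
    swaps_per_edge
        Target number of successful swaps per edge (default 10).
    seed
        Seeds the swap sequence; identical seed and input give an identical null.
    """
    if swaps_per_edge < 1:
        raise ValueError("swaps_per_edge must be >= 1")
    edges = net.edge_list()
    if len(edges) < 4:
        raise RewiringError(f"need at least 4 edges to rewire, got {len(edges)}")
    rng = np.random.default_rng(seed)
    g = net.to_graph()
    n_target = swaps_per_edge * len(edges)
    max_tries = 100 * n_target
    done = 0
    tries = 0
    while done < n_target and tries < max_tries:
        tries += 1
        current = list(g.edges())
        i1, i2 = rng.choice(len(current), size=2, replace=False)
        a, b = current[i1]
        c, d = current[i2]
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        attr_ab = dict(g.edges[a, b])
        attr_cd = dict(g.edges[c, d])
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d, **attr_ab)
        g.add_edge(c, b, **attr_cd)
        if not nx.is_connected(g):
            g.remove_edge(a, d)
            g.remove_edge(c, b)
            g.add_edge(a, b, **attr_ab)
            g.add_edge(c, d, **attr_cd)
            continue
        done += 1
    if done == 0:
        n = net.n_nodes
        if len(edges) == n * (n - 1) // 2:
            # complete graph: no alternative simple graph with this degree
            # sequence exists, so the input topology is the (only) null.
            return StructuralNetwork(
                net.weights.copy(), net.lengths.copy(), net.labels
            )
        raise RewiringError(
            f"no successful swap in {tries} attempts (pathological topology)"
        )
    n = net.n_nodes
    w = np.zeros((n, n))
    ln = np.zeros((n, n))
    for u, v, attrs in g.edges(data=True):
        w[u, v] = w[v, u] = attrs["weight"]
        ln[u, v] = ln[v, u] = attrs["length"]
    return StructuralNetwork(w, ln, net.labels)
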