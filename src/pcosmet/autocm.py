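"""Auto-contractive map, weight→distance transform, MST and semantic maps.

The auto-contractive map (Auto-CM) is an unsupervised three-layer network over
*N* binary nodes.  Each record ``x ∈ [0,1]^N`` is contracted twice:

    hidden   h_i   = x_i · (1 − v_i / C)
    net_j          = Σ_i h_i · (1 − W_ij / C)
    output   out_j = h_j · (1 − net_j / C)

with the mono-connected weights ``v`` and the full matrix ``W`` adapting by

    Δv_i  = x_i · (x_i − h_i) · (1 − v_i / C)
    ΔW_ij = (h_i − out_i) · (1 − W_ij / C) · h_j

where ``C`` is the contraction parameter (by convention the number of nodes).
Updates are accumulated over all records of an epoch and applied once, so
training is invariant to row order and fully deterministic.  As ``v``
saturates toward ``C`` the hidden activations vanish and learning quenches,
freezing ``W`` with larger entries for node pairs that co-occur more often.
Converged weights are read as association strengths and turned into distances
``d_ij = C − (W_ij + W_ji)/2``; the minimum spanning tree of the distance
matrix is the *semantic connectivity map* (SCM), and nodes are ranked by their
tree-path separation from an outcome pole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import json
import numpy as np
import pandas as pd
import networkx as nx

from .dichotomize import BinaryNodeMatrix

__all__ = [
    "AutoCM",
    "AutoCMResults",
    "SCMGraph",
    "train_autocm",
    "weights_to_distances",
    "minimum_spanning_tree",
    "build_scm",
]

#: Fraction of C used for the deterministic positive weight initialization.
INIT_FRACTION = 0.01


class AutoCM:
    """Auto-contractive map model over a binary node matrix.

    Parameters
    ----------
    X : array-like or BinaryNodeMatrix
        Records × nodes matrix with entries in [0, 1].
    node_names : sequence of str, optional
        Node labels; taken from the BinaryNodeMatrix when available.
    C : float, optional
        Contraction parameter; defaults to the number of nodes.
    """

    def __init__(self, X, node_names: Optional[Sequence[str]] = None, C: Optional[float] = None):
        if isinstance(X, BinaryNodeMatrix):
            node_names = X.node_names
            X = X.values
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be 2-D with at least 2 nodes")
        if np.isnan(X).any() or X.min() < 0 or X.max() > 1:
            raise ValueError("X entries must lie in [0, 1]")
        self.X = X
        self.n_nodes = X.shape[1]
        self.node_names = list(node_names) if node_names is not None else [
            f"node{j}" for j in range(self.n_nodes)
        ]
        if len(self.node_names) != self.n_nodes:
            raise ValueError("node_names length must match the number of columns")
        self.C = float(C) if C is not None else float(self.n_nodes)
        if self.C <= 0:
            raise ValueError("C must be > 0")

    def fit(self, max_epochs: int = 3000, tol: float = 1e-6) -> "AutoCMResults":
        """Batch-train to convergence of the total update energy."""
        X = self.X
        n, N = X.shape
        C = self.C
        v = np.full(N, INIT_FRACTION * C)
        W = np.full((N, N), INIT_FRACTION * C)
        energy_path = []
        converged = False
        epoch = 0
        for epoch in range(1, max_epochs + 1):
            h = X * (1.0 - v / C)                       # n × N
            net = h @ (1.0 - W / C)                     # n × N
            out = h * (1.0 - net / C)
            dv = (X * (X - h)).mean(axis=0) * (1.0 - v / C)
            contraction = h - out                       # n × N, per-node residual
            dW = (contraction.T @ h) / n * (1.0 - W / C)
            v = v + dv
            W = W + dW
            energy = float(np.abs(dv).sum() + np.abs(dW).sum())
            energy_path.append(energy)
            if energy < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"Auto-CM did not reach energy < {tol} in {max_epochs} epochs "
                f"(final energy {energy_path[-1]:.3g})"
            )
        return AutoCMResults(
            model=self, v=v, W=W, C=C, n_epochs=epoch,
            energy_path=np.asarray(energy_path), converged=converged,
        )


def train_autocm(X, C: Optional[float] = None, max_epochs: int = 3000,
                 tol: float = 1e-6) -> "AutoCMResults":
    """Functional wrapper: build an :class:`AutoCM` and fit it."""
    return AutoCM(X, C=C).fit(max_epochs=max_epochs, tol=tol)


@dataclass
class AutoCMResults:
    """Converged Auto-CM weights and the derived association geometry."""

    model: AutoCM
    v: np.ndarray
    W: np.ndarray
    C: float
    n_epochs: int
    energy_path: np.ndarray
    converged: bool

    @property
    def node_names(self) -> list[str]:
        return self.model.node_names

    def distances(self, rescale: bool = False) -> pd.DataFrame:
        """Symmetric node distances d_ij = C − (W_ij + W_ji)/2, zero diagonal.

        With ``rescale=True`` the off-diagonal entries are min–max scaled to
        [0, 1] (cosmetic, for map layout); the spanning tree is always built
        on unrescaled distances.
        """
        if self.n_epochs == 0:
            raise ValueError("model is untrained")
        sym = (self.W + self.W.T) / 2.0
        d = self.C - sym
        np.fill_diagonal(d, 0.0)
        d = np.maximum(d, 0.0)
        if rescale:
            off = ~np.eye(len(d), dtype=bool)
            lo, hi = d[off].min(), d[off].max()
            if hi - lo < 1e-12:
                warnings.warn("all off-diagonal distances equal; rescaling degenerate, using 0.5")
                d = np.where(off, 0.5, 0.0)
            else:
                d = np.where(off, (d - lo) / (hi - lo), 0.0)
        return pd.DataFrame(d, index=self.node_names, columns=self.node_names)

    def semantic_map(self, pole: str) -> "SCMGraph":
        """MST of the distance matrix with priorities from the outcome pole."""
        d = self.distances(rescale=False)
        edges = minimum_spanning_tree(d.to_numpy(), labels=self.node_names)
        return SCMGraph.from_edges(self.node_names, edges, pole)

    def summary(self, top: int = 10) -> str:
        """Plain-text report: convergence and the strongest associations."""
        d = self.distances().to_numpy()
        iu = np.triu_indices(len(d), k=1)
        order = np.argsort(d[iu])[:top]
        lines = [
            "Auto-contractive map",
            "=" * 44,
            f"nodes:       {self.model.n_nodes}",
            f"records:     {self.model.X.shape[0]}",
            f"C:           {self.C:g}",
            f"epochs:      {self.n_epochs}",
            f"converged:   {self.converged}",
            f"final energy:{self.energy_path[-1]:.3g}",
            "",
            f"strongest associations (smallest distances):",
        ]
        for k in order:
            i, j = iu[0][k], iu[1][k]
            lines.append(f"  {self.node_names[i]:<18} — {self.node_names[j]:<18} d={d[i, j]:.4f}")
        return "\n".join(lines)


def weights_to_distances(results: AutoCMResults, rescale: bool = False) -> pd.DataFrame:
    """Functional alias for :meth:`AutoCMResults.distances`."""
    return results.distances(rescale=rescale)


# ---------------------------------------------------------------------------
# Minimum spanning tree
# ---------------------------------------------------------------------------

def minimum_spanning_tree(
    d: np.ndarray, labels: Optional[Sequence[str]] = None
) -> list[tuple[int, int, float]]:
    """Kruskal MST of a symmetric distance matrix.

    Ties are broken lexicographically on (i, j); entries of ``inf`` mark
    absent edges.  Returns edges as (i, j, weight) with i < j.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n or n < 2:
        raise ValueError("need a square matrix over at least 2 nodes")
    finite = np.isfinite(d)
    if not np.allclose(np.where(finite & finite.T, d, 0.0),
                       np.where(finite & finite.T, d.T, 0.0)) or (finite != finite.T).any():
        raise ValueError("distance matrix must be symmetric")
    if (d[finite] < 0).any():
        raise ValueError("distance matrix must be non-negative")

    edges = [
        (d[i, j], i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if np.isfinite(d[i, j])
    ]
    edges.sort()  # (weight, i, j): lexicographic tie-break

    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tree: list[tuple[int, int, float]] = []
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.append((i, j, w))
            if len(tree) == n - 1:
                break
    if len(tree) != n - 1:
        raise ValueError("graph is disconnected; no spanning tree exists")
    return tree


# ---------------------------------------------------------------------------
# Semantic connectivity map
# ---------------------------------------------------------------------------

@dataclass
class SCMGraph:
    """The semantic connectivity map: a spanning tree plus pole priorities.

    ``pole_priorities`` lists every non-pole node ordered by (number of tree
    edges from the pole, summed path weight, name), each as
    ``(node, path_edges, path_weight)``.
    """

    graph: nx.Graph
    pole: str
    pole_priorities: list[tuple[str, int, float]] = field(default_factory=list)

    @classmethod
    def from_edges(
        cls, nodes: Sequence[str], edges: list[tuple[int, int, float]], pole: str
    ) -> "SCMGraph":
        if pole not in nodes:
            raise ValueError(f"pole {pole!r} is not a node")
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for i, j, w in edges:
            g.add_edge(nodes[i], nodes[j], weight=float(w))
        hops = nx.shortest_path_length(g, source=pole)
        wsum = nx.shortest_path_length(g, source=pole, weight="weight")
        priorities = sorted(
            ((node, hops[node], float(wsum[node])) for node in g.nodes if node != pole),
            key=lambda t: (t[1], t[2], t[0]),
        )
        return cls(graph=g, pole=pole, pole_priorities=priorities)

    def priority_rank(self, node: str) -> int:
        """0-based rank of a node in the pole-priority ordering."""
        for k, (name, _, _) in enumerate(self.pole_priorities):
            if name == node:
                return k
        raise KeyError(node)

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    def to_dot(self, path: str | Path) -> None:
        lines = ["graph SCM {"]
        for u, v, data in self.graph.edges(data=True):
            lines.append(f'  "{u}" -- "{v}" [label="{data["weight"]:.4f}"];')
        lines.append("}")
        Path(path).write_text("\n".join(lines))

    def priorities_json(self, path: Optional[str | Path] = None) -> str:
        payload = json.dumps(
            {
                "pole": self.pole,
                "priorities": [
                    {"node": n, "path_edges": h, "path_weight": w}
                    for n, h, w in self.pole_priorities
                ],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def plot(self, ax=None):
        """Spring-layout rendering of the tree (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 8))
        pos = nx.spring_layout(self.graph, seed=0, weight=None)
        colors = ["#d62728" if n == self.pole else "#1f77b4" for n in self.graph.nodes]
        nx.draw_networkx(self.graph, pos=pos, ax=ax, node_color=colors,
                         font_size=7, node_size=450)
        ax.set_axis_off()
        return ax


def build_scm(
    X,
    pole: str,
    C: Optional[float] = None,
    max_epochs: int = 3000,
    tol: float = 1e-6,
) -> SCMGraph:
    """Train Auto-CM on a node matrix and return the semantic map for a pole."""
    model = AutoCM(X, C=C)
    if pole not in model.node_names:
        raise ValueError(f"pole {pole!r} not among node names")
    results = model.fit(max_epochs=max_epochs, tol=tol)
    return results.semantic_map(pole)
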