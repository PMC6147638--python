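"""Layer graphs, interlayer coupling blocks, and supra-networks.

Node-layer indexing convention: node ``n`` of layer ``l`` (0-based) has
global index ``n + l * N`` in the supra-adjacency matrix, so replicas of the
same physical node sit ``N`` apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

_SYM_TOL = 1e-12


@dataclass
class LayerGraph:
    """One network layer: a symmetric non-negative weight matrix.

    Parameters
    ----------
    weights : ndarray, shape (N, N)
        Symmetric, non-negative, zero-diagonal weight matrix.
    name : str, optional
        Layer label (e.g. a frequency-band name).
    """

    weights: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"weights must be square, got shape {W.shape}")
        if not np.allclose(W, W.T, atol=_SYM_TOL, rtol=0):
            raise ValueError("layer weight matrix is not symmetric")
        if np.any(W < 0):
            raise ValueError("layer weight matrix has negative entries")
        if np.any(np.abs(np.diag(W)) > _SYM_TOL):
            raise ValueError("layer weight matrix has nonzero diagonal entries")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def strength(self) -> float:
        """Sum of all matrix entries (each edge counted twice)."""
        return float(self.weights.sum())


@dataclass
class InterlayerCoupling:
    """Coupling block between two layers.

    Parameters
    ----------
    block : ndarray, shape (N_a, N_b)
        Non-negative weights; entry (i, j) couples node i of the first layer
        to node j of the second. The reverse block is its transpose.
    structure : {"diagonal", "full", "partial"}
        Structure tag. ``diagonal`` requires all off-diagonal entries zero.
    """

    block: np.ndarray
    structure: str = "full"

    def __post_init__(self) -> None:
        B = np.asarray(self.block, dtype=float)
        if B.ndim != 2:
            raise ValueError("coupling block must be 2-D")
        if np.any(B < 0):
            raise ValueError("coupling block has negative entries")
        if self.structure not in ("diagonal", "full", "partial"):
            raise ValueError(f"unknown structure tag {self.structure!r}")
        if self.structure == "diagonal":
            off = B - np.diag(np.diag(B)) if B.shape[0] == B.shape[1] else B
            if B.shape[0] != B.shape[1] or np.any(off != 0):
                raise ValueError("'diagonal' coupling must be square with zero off-diagonal")
        self.block = B

    @property
    def shape(self) -> tuple[int, int]:
        return self.block.shape

    @property
    def strength(self) -> float:
        """Sum of the block entries (single direction)."""
        return float(self.block.sum())

    @property
    def n_active(self) -> int:
        """Number of nonzero coupling entries."""
        return int(np.count_nonzero(self.block))

    def scaled(self, p: float) -> "InterlayerCoupling":
        """Coupling with every weight multiplied by ``p``."""
        if p < 0:
            raise ValueError("scale factor must be non-negative")
        return InterlayerCoupling(self.block * p, structure=self.structure)


@dataclass
class SupraNetwork:
    """Ordered layers plus pairwise interlayer coupling blocks.

    ``couplings`` maps layer-index pairs ``(a, b)`` with ``a < b`` to the
    coupling block from layer ``a`` to layer ``b``; the symmetric counterpart
    is implied by transposition.
    """

    layers: list[LayerGraph]
    couplings: Mapping[tuple[int, int], InterlayerCoupling] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.layers = list(self.layers)
        if not self.layers:
            raise ValueError("need at least one layer")
        self.couplings = dict(self.couplings)
        n_layers = len(self.layers)
        for (a, b), coup in self.couplings.items():
            if not (0 <= a < b < n_layers):
                raise ValueError(f"coupling key {(a, b)} invalid for {n_layers} layers")
            want = (self.layers[a].n_nodes, self.layers[b].n_nodes)
            if coup.shape != want:
                raise ValueError(
                    f"coupling {(a, b)} has shape {coup.shape}, expected {want}"
                )

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def layer_sizes(self) -> list[int]:
        return [lg.n_nodes for lg in self.layers]

    @property
    def n_total(self) -> int:
        return sum(self.layer_sizes)

    def global_index(self, layer: int, node: int) -> int:
        """Supra index of node ``node`` in layer ``layer``."""
        return node + sum(self.layer_sizes[:layer])

    def coupling_between(self, a: int, b: int) -> InterlayerCoupling | None:
        """Coupling block from layer ``a`` to layer ``b`` (any order)."""
        if a == b:
            raise ValueError("a coupling joins two distinct layers")
        if a < b:
            return self.couplings.get((a, b))
        coup = self.couplings.get((b, a))
        if coup is None:
            return None
        return InterlayerCoupling(coup.block.T, structure=coup.structure)


def supranetwork_from_dense(
    M: np.ndarray, layer_sizes: list[int], layer_names: list[str] | None = None
) -> SupraNetwork:
    """Slice a dense supra-adjacency matrix into layers + coupling blocks."""
    M = np.asarray(M, dtype=float)
    total = sum(layer_sizes)
    if M.shape != (total, total):
        raise ValueError(f"matrix shape {M.shape} does not match layer sizes {layer_sizes}")
    names = layer_names or [f"layer{i}" for i in range(len(layer_sizes))]
    offsets = np.concatenate([[0], np.cumsum(layer_sizes)])
    layers = []
    for i, name in enumerate(names):
        blk = M[offsets[i]:offsets[i + 1], offsets[i]:offsets[i + 1]].copy()
        np.fill_diagonal(blk, 0.0)
        layers.append(LayerGraph(blk, name=name))
    couplings = {}
    for a in range(len(layer_sizes)):
        for b in range(a + 1, len(layer_sizes)):
            blk = M[offsets[a]:offsets[a + 1], offsets[b]:offsets[b + 1]].copy()
            off = blk - np.diag(np.diag(blk)) if blk.shape[0] == blk.shape[1] else blk
            if blk.shape[0] == blk.shape[1] and not np.any(off):
                tag = "diagonal"
            elif np.all(blk > 0):
                tag = "full"
            else:
                tag = "partial"
            couplings[(a, b)] = InterlayerCoupling(blk, structure=tag)
    return SupraNetwork(layers, couplings)


def _assemble_dense(net: SupraNetwork) -> np.ndarray:
    # Shared by spectral.supra_adjacency and the writers below.
    total = net.n_total
    offsets = np.concatenate([[0], np.cumsum(net.layer_sizes)])
    M = np.zeros((total, total))
    for i, lg in enumerate(net.layers):
        M[offsets[i]:offsets[i + 1], offsets[i]:offsets[i + 1]] = lg.weights
    for (a, b), coup in net.couplings.items():
        M[offsets[a]:offsets[a + 1], offsets[b]:offsets[b + 1]] = coup.block
        M[offsets[b]:offsets[b + 1], offsets[a]:offsets[a + 1]] = coup.block.T
    return M


def write_supranetwork(net: SupraNetwork, prefix: str | Path, extra_meta: dict | None = None) -> None:
    """Write a supra-network as dense TSV + JSON header + edge list.

    Produces ``<prefix>.tsv`` (dense supra-adjacency), ``<prefix>.json``
    (layer names/sizes, node ordering) and ``<prefix>_edges.tsv`` (columns
    layer_i, node_i, layer_j, node_j, weight). Output is bit-identical for
    identical networks.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    M = _assemble_dense(net)
    np.savetxt(prefix.with_suffix(".tsv"), M, delimiter="\t", fmt="%.17g")
    meta = {
        "layer_names": [lg.name for lg in net.layers],
        "layer_sizes": net.layer_sizes,
        "node_ordering": "node n of layer l has global index n + sum(sizes[:l])",
    }
    if extra_meta:
        meta.update(extra_meta)
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    offsets = np.concatenate([[0], np.cumsum(net.layer_sizes)])
    lines = ["layer_i\tnode_i\tlayer_j\tnode_j\tweight"]
    layer_of = np.concatenate(
        [np.full(sz, i) for i, sz in enumerate(net.layer_sizes)]
    )
    rows, cols = np.nonzero(np.triu(M, 1))
    for r, c in zip(rows, cols):
        li, lj = int(layer_of[r]), int(layer_of[c])
        lines.append(
            f"{li}\t{int(r - offsets[li])}\t{lj}\t{int(c - offsets[lj])}\t{M[r, c]:.17g}"
        )
    Path(str(prefix) + "_edges.tsv").write_text("\n".join(lines) + "\n")


def read_supranetwork(prefix: str | Path) -> SupraNetwork:
    """Read a supra-network written by :func:`write_supranetwork`."""
    prefix = Path(prefix)
    M = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return supranetwork_from_dense(M, meta["layer_sizes"], meta["layer_names"])
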