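"""Supra-adjacency assembly, combinatorial supra-Laplacian spectra,
algebraic connectivity, and transition-point detection.

The combinatorial Laplacian used throughout is the weighted form
``L = diag(s) - M`` with ``s_i = sum_j M_ij`` (the weighted degree), which
reduces to the unit-weight form when all edges have weight 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.sparse
import scipy.sparse.linalg

from freqlayer.network import (
    InterlayerCoupling,
    LayerGraph,
    SupraNetwork,
    _assemble_dense,
)

__all__ = [
    "SupraLaplacian",
    "SpectralScan",
    "TransitionResult",
    "GridRangeError",
    "supra_adjacency",
    "combinatorial_laplacian",
    "smallest_eigenvalues",
    "algebraic_connectivity",
    "aggregate_layers",
    "lambda2_agg",
    "mean_weighted_degree",
    "reference_lambda2",
    "scan_transition",
    "transition_point",
    "delta_lambda2",
    "percent_deviation_from_aggregate",
]

#: Below this eigenvalue the supra-graph is treated as disconnected.
DISCONNECTED_TOL = 1e-9

# Matrices at least this large and sparser than _SPARSE_MAX_DENSITY go
# through the shift-invert Lanczos path; everything else is solved densely.
_SPARSE_MIN_SIZE = 800
_SPARSE_MAX_DENSITY = 0.15


class GridRangeError(ValueError):
    """The scanned p-grid does not bracket the eigenvalue crossing."""


@dataclass
class SupraLaplacian:
    """Combinatorial (supra-)Laplacian with its layer partition.

    Invariants (validated on construction): symmetric, rows sum to zero
    (|row sum| < 1e-9) and positive semidefinite with smallest eigenvalue 0
    — the latter two hold by construction of ``diag(s) - M``.
    """

    matrix: np.ndarray
    layer_sizes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        L = np.asarray(self.matrix, dtype=float)
        if L.ndim != 2 or L.shape[0] != L.shape[1]:
            raise ValueError(f"Laplacian must be square, got {L.shape}")
        if not np.allclose(L, L.T, atol=1e-12, rtol=0):
            raise ValueError("Laplacian is not symmetric")
        rs = np.abs(L.sum(axis=1))
        if rs.size and rs.max() > 1e-9:
            raise ValueError(f"Laplacian rows do not sum to zero (max |sum| = {rs.max():g})")
        self.matrix = L
        if self.layer_sizes and sum(self.layer_sizes) != L.shape[0]:
            raise ValueError("layer_sizes do not match matrix dimension")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SpectralScan:
    """lambda2(p) and lambda3(p) over an ascending p-grid.

    ``p_star`` and ``crossed`` are filled in by :func:`transition_point`.
    ``references`` holds named closed-form reference curves evaluated on the
    same grid.
    """

    p_grid: np.ndarray
    lambda2: np.ndarray
    lambda3: np.ndarray
    p_star: float | None = None
    crossed: bool | None = None
    gap_tolerance: tuple[float, float] | None = None
    references: dict[str, np.ndarray] = field(default_factory=dict)
    _evaluator: Callable[[float], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.p_grid = np.asarray(self.p_grid, dtype=float)
        self.lambda2 = np.asarray(self.lambda2, dtype=float)
        self.lambda3 = np.asarray(self.lambda3, dtype=float)
        if not (self.p_grid.shape == self.lambda2.shape == self.lambda3.shape):
            raise ValueError("p_grid, lambda2, lambda3 must have equal shapes")
        if np.any(np.diff(self.p_grid) <= 0):
            raise ValueError("p_grid must be strictly ascending")

    @property
    def gap(self) -> np.ndarray:
        return self.lambda3 - self.lambda2


@dataclass(frozen=True)
class TransitionResult:
    """Outcome of the lambda2/lambda3 crossing search."""

    p_star: float
    crossed: bool
    gap: float


def supra_adjacency(net: SupraNetwork) -> np.ndarray:
    """Assemble the dense supra-adjacency matrix of a supra-network.

    Layer weight matrices form the diagonal blocks; coupling blocks (and
    their transposes) fill the off-diagonal blocks. The result is symmetric
    with zero diagonal for any valid :class:`SupraNetwork`.
    """
    return _assemble_dense(net)


def combinatorial_laplacian(
    M: np.ndarray | SupraNetwork, layer_sizes: Sequence[int] | None = None
) -> SupraLaplacian:
    """Weighted combinatorial Laplacian ``L = diag(s) - M``.

    Accepts either a symmetric weight matrix or a :class:`SupraNetwork`
    (assembled first). ``s_i`` is the weighted degree of node ``i``.
    """
    if isinstance(M, SupraNetwork):
        layer_sizes = M.layer_sizes
        M = supra_adjacency(M)
    M = np.asarray(M, dtype=float)
    L = np.diag(M.sum(axis=1)) - M
    return SupraLaplacian(L, list(layer_sizes) if layer_sizes else [])


def _as_matrix(L: SupraLaplacian | np.ndarray) -> np.ndarray:
    return L.matrix if isinstance(L, SupraLaplacian) else np.asarray(L, dtype=float)


def smallest_eigenvalues(L: SupraLaplacian | np.ndarray, k: int) -> np.ndarray:
    """The ``k`` algebraically smallest eigenvalues, ascending.

    Large sparse matrices go through ARPACK shift-invert Lanczos; smaller or
    denser ones use a direct LAPACK partial decomposition. Non-convergence
    raises, it is never silently approximated.
    """
    A = _as_matrix(L)
    n = A.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for a {n}x{n} matrix")
    density = np.count_nonzero(A) / max(n * n, 1)
    if n >= _SPARSE_MIN_SIZE and k < n - 1 and density < _SPARSE_MAX_DENSITY:
        S = scipy.sparse.csc_matrix(A)
        try:
            vals = scipy.sparse.linalg.eigsh(
                S, k=k, sigma=-1e-2, which="LM", return_eigenvectors=False
            )
        except scipy.sparse.linalg.ArpackNoConvergence as exc:
            raise RuntimeError(
                f"eigensolver failed to converge on a {n}x{n} matrix"
            ) from exc
        return np.sort(vals)
    vals = scipy.linalg.eigh(A, eigvals_only=True, subset_by_index=(0, k - 1))
    return np.asarray(vals)


def algebraic_connectivity(L: SupraLaplacian | np.ndarray) -> float:
    """Second-smallest Laplacian eigenvalue (Fiedler value).

    Zero (within tolerance) exactly when the graph is disconnected, in which
    case a warning is emitted rather than an error — edge-deletion sweeps
    legitimately disconnect the supra-graph.
    """
    vals = smallest_eigenvalues(L, 2)
    lam2 = float(vals[1])
    if lam2 < DISCONNECTED_TOL:
        warnings.warn("graph is disconnected (lambda2 ~ 0)", stacklevel=2)
        return 0.0
    return lam2


def aggregate_layers(net: SupraNetwork) -> LayerGraph:
    """Monolayer network from componentwise addition of the layer weights."""
    sizes = set(net.layer_sizes)
    if len(sizes) != 1:
        raise ValueError("aggregation requires equally sized layers")
    W = np.sum([lg.weights for lg in net.layers], axis=0)
    return LayerGraph(W, name="aggregated")


def lambda2_agg(net: SupraNetwork) -> float:
    """Aggregated-regime reference: ``(1/l) * lambda2(sum of layer Laplacians)``.

    For two layers this is the familiar half of the algebraic connectivity of
    the summed layer Laplacians.
    """
    agg = aggregate_layers(net)
    L = combinatorial_laplacian(agg.weights)
    return algebraic_connectivity(L) / net.n_layers


def mean_weighted_degree(C: np.ndarray) -> float:
    """Mean over rows of the row sums of a coupling structure matrix."""
    C = np.asarray(C, dtype=float)
    return float(C.sum(axis=1).mean())


def _bipartite_coupling_lambda2(net: SupraNetwork, p: float) -> float:
    """lambda2 of the graph whose only edges are the interlayer ones, scaled by p."""
    stripped = SupraNetwork(
        [LayerGraph(np.zeros_like(lg.weights), name=lg.name) for lg in net.layers],
        {key: c.scaled(p) for key, c in net.couplings.items()},
    )
    return algebraic_connectivity(combinatorial_laplacian(stripped))


def reference_lambda2(regime: str, p: float, net: SupraNetwork | None = None) -> float:
    """Closed-form reference value of lambda2 for a given coupling regime.

    Regimes
    -------
    ``multiplex_small_p``   : 2p
    ``multilayer_small_p``  : 2p<c> with <c> the mean weighted degree of the
                              coupling structure (blocks at unit scale)
    ``multiplex_large_p``   : lambda2 of the aggregated-layer reference
    ``multilayer_large_p``  : lambda2_min(layers) + lambda2 of the graph made
                              of the interlayer edges alone at scale p
    """
    if regime == "multiplex_small_p":
        return 2.0 * p
    if net is None:
        raise ValueError(f"regime {regime!r} needs the network")
    if regime == "multilayer_small_p":
        if not net.couplings:
            raise ValueError("network has no couplings")
        c_mean = np.mean(
            [mean_weighted_degree(c.block) for c in net.couplings.values()]
        )
        return 2.0 * p * float(c_mean)
    if regime == "multiplex_large_p":
        return lambda2_agg(net)
    if regime == "multilayer_large_p":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam2_min = min(
                algebraic_connectivity(combinatorial_laplacian(lg.weights))
                for lg in net.layers
            )
        return lam2_min + _bipartite_coupling_lambda2(net, p)
    raise ValueError(f"unknown regime {regime!r}")


def _coupling_map(
    layers: Sequence[LayerGraph],
    coupling_template: InterlayerCoupling | Mapping[tuple[int, int], InterlayerCoupling],
) -> dict[tuple[int, int], InterlayerCoupling]:
    if isinstance(coupling_template, InterlayerCoupling):
        n = len(layers)
        return {
            (a, b): coupling_template for a in range(n) for b in range(a + 1, n)
        }
    return dict(coupling_template)


def scan_transition(
    layers: Sequence[LayerGraph],
    coupling_template: InterlayerCoupling | Mapping[tuple[int, int], InterlayerCoupling],
    p_grid: np.ndarray,
    with_references: bool = False,
) -> SpectralScan:
    """Record lambda2(p) and lambda3(p) while scaling the coupling template.

    ``coupling_template`` holds the coupling *structure* at unit scale; at
    each grid point its weights are multiplied by ``p``, the supra-Laplacian
    is assembled and its three smallest eigenvalues are computed.

    p-grids spanning the transition are best taken logarithmically spaced —
    the crossing can sit orders of magnitude away from unit weight.
    """
    p_grid = np.asarray(p_grid, dtype=float)
    templates = _coupling_map(layers, coupling_template)

    def evaluate(p: float) -> np.ndarray:
        net = SupraNetwork(
            list(layers), {key: c.scaled(p) for key, c in templates.items()}
        )
        return smallest_eigenvalues(combinatorial_laplacian(net), 3)

    lam2 = np.empty_like(p_grid)
    lam3 = np.empty_like(p_grid)
    for i, p in enumerate(p_grid):
        vals = evaluate(p)
        lam2[i], lam3[i] = vals[1], vals[2]

    scan = SpectralScan(p_grid, lam2, lam3, _evaluator=evaluate)
    if with_references:
        net0 = SupraNetwork(list(layers), templates)
        diagonal = all(c.structure == "diagonal" for c in templates.values())
        small = "multiplex_small_p" if diagonal else "multilayer_small_p"
        large = "multiplex_large_p" if diagonal else "multilayer_large_p"
        scan.references[small] = np.array(
            [reference_lambda2(small, p, net0) for p in p_grid]
        )
        scan.references[large] = np.array(
            [reference_lambda2(large, p, net0) for p in p_grid]
        )
    return scan


def _local_min_candidates(gap: np.ndarray) -> list[int]:
    """Interior local minima of the gap, in ascending p order.

    Comparisons carry a tiny flatness tolerance: past a crossing the gap is
    often constant up to floating-point jitter, and exact comparisons would
    either miss the plateau edge or flag every jitter dip. Runs of
    consecutive plateau indices are collapsed to their first index.
    """
    flat_tol = 1e-9 * (1.0 + float(gap.max() - gap.min()))
    cands: list[int] = []
    last = -5
    for i in range(1, len(gap) - 1):
        if gap[i] <= gap[i - 1] + flat_tol and gap[i] <= gap[i + 1] + flat_tol:
            if i - 1 != last:
                cands.append(i)
            last = i
    return cands


def transition_point(
    scan: SpectralScan, atol: float = 1e-6, rtol: float = 1e-4, n_refine: int = 40
) -> TransitionResult:
    """Locate the smallest p at which the lambda2 and lambda3 branches cross.

    Interior local minima of the gap ``lambda3 - lambda2`` are examined in
    ascending p order; each candidate interval is re-sampled on a finer
    local grid (the true crossing can be far narrower than the scan
    resolution). The first candidate whose refined gap satisfies
    ``gap <= atol + rtol * lambda3`` is declared the crossing, and its
    *onset* — the smallest p within tolerance — is isolated by bisection
    (past a crossing the branches can stay degenerate over a whole interval,
    so a plain gap minimum is ambiguous). The 2p branch also intersects
    higher branches at larger p; scanning candidates in ascending order
    keeps the first crossing.

    If no candidate crosses (e.g. heterogeneous couplings whose branches
    avoid each other), the gap-minimizing p is polished by golden-section
    search and returned with ``crossed=False``.

    Raises
    ------
    GridRangeError
        If the gap is monotone over the whole grid (no interior minimum).
    """
    gap = scan.gap
    candidates = _local_min_candidates(gap)
    if not candidates:
        raise GridRangeError(
            "gap between lambda3 and lambda2 is monotone over the grid; "
            "widen the p grid to bracket the crossing"
        )

    def finalize(p_star: float, crossed: bool, g: float) -> TransitionResult:
        scan.p_star = p_star
        scan.crossed = crossed
        scan.gap_tolerance = (atol, rtol)
        return TransitionResult(p_star=p_star, crossed=crossed, gap=g)

    if scan._evaluator is None:
        # Serialized scans lose their evaluator; fall back to grid points.
        for i in candidates:
            g, lam3 = float(gap[i]), float(scan.lambda3[i])
            if g <= atol + rtol * lam3:
                return finalize(float(scan.p_grid[i]), True, g)
        i = min(candidates, key=lambda j: gap[j])
        return finalize(float(scan.p_grid[i]), False, float(gap[i]))

    def eval_at(p: float) -> tuple[float, float]:
        vals = scan._evaluator(p)
        return float(vals[2] - vals[1]), float(vals[2])

    def below_tol(g: float, lam3: float) -> bool:
        return g <= atol + rtol * lam3

    best_fallback: tuple[float, float, float, float] | None = None  # g, p, a, c
    for i in candidates:
        lo, hi = float(scan.p_grid[i - 1]), float(scan.p_grid[i + 1])
        fine = (
            np.geomspace(lo, hi, n_refine) if lo > 0 else np.linspace(lo, hi, n_refine)
        )
        fine_pairs = [eval_at(p) for p in fine]
        hits = [j for j, (g, l3) in enumerate(fine_pairs) if below_tol(g, l3)]
        if hits:
            j0 = hits[0]
            if j0 == 0:
                return finalize(float(fine[0]), True, fine_pairs[0][0])
            p_lo, p_hi = float(fine[j0 - 1]), float(fine[j0])
            g = fine_pairs[j0][0]
            for _ in range(50):
                mid = 0.5 * (p_lo + p_hi)
                gm, l3m = eval_at(mid)
                if below_tol(gm, l3m):
                    p_hi, g = mid, gm
                else:
                    p_lo = mid
                if (p_hi - p_lo) <= 1e-9 * max(p_hi, 1e-300):
                    break
            return finalize(p_hi, True, g)
        j = int(np.argmin([g for g, _ in fine_pairs]))
        if best_fallback is None or fine_pairs[j][0] < best_fallback[0]:
            best_fallback = (
                fine_pairs[j][0],
                float(fine[j]),
                float(fine[max(j - 1, 0)]),
                float(fine[min(j + 1, n_refine - 1)]),
            )

    # no candidate crossed: polish the best gap minimum
    g_best, p_best, a, c = best_fallback

    def gap_at(p: float) -> float:
        return eval_at(p)[0]

    try:
        res = scipy.optimize.minimize_scalar(
            gap_at, bracket=(a, p_best, c), method="golden",
            options={"xtol": 1e-8},
        )
        p_star = float(res.x)
    except ValueError:
        # Flat neighborhoods can defeat the bracketing requirement.
        res = scipy.optimize.minimize_scalar(
            gap_at, bounds=(a, c), method="bounded", options={"xatol": 1e-8}
        )
        p_star = float(res.x)
    if res.fun > g_best:  # polishing must never lose the minimum
        p_star = p_best
    g, lam3 = eval_at(p_star)
    return finalize(p_star, below_tol(g, lam3), g)


def delta_lambda2(reference_scan: SpectralScan, scan: SpectralScan) -> np.ndarray:
    """Per-p difference of lambda2 between a reference scan and another scan."""
    if not np.array_equal(reference_scan.p_grid, scan.p_grid):
        raise ValueError("scans were taken on different p grids")
    return reference_scan.lambda2 - scan.lambda2


def percent_deviation_from_aggregate(lam2: float, lam2_agg: float) -> float:
    """``100 * (lambda2_agg - lambda2) / lambda2_agg``."""
    if lam2_agg == 0:
        raise ValueError("aggregated lambda2 is zero")
    return 100.0 * (lam2_agg - lam2) / lam2_agg
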