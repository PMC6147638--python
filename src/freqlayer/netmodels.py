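"""Random layer graphs and interlayer coupling structures.

ER/BA layers, homogeneous and heterogeneous diagonal couplings, random edge
deletion, and multiplex-to-multilayer densification. Every generator is
seed-deterministic.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np

from freqlayer.network import InterlayerCoupling, LayerGraph, SupraNetwork

__all__ = [
    "er_layer",
    "ba_layer",
    "diagonal_coupling",
    "heterogeneous_weights",
    "full_coupling",
    "remove_interlayer_edges",
    "densify_from_multiplex",
    "strengths",
]

MAX_SIGMA = 1.0 / math.sqrt(3.0)  # larger sigma would force negative weights


def er_layer(
    N: int,
    p_con: float,
    seed: int,
    ensure_connected: bool = True,
    max_resamples: int = 1000,
) -> LayerGraph:
    """G(N, p_con) Erdos-Renyi layer with unit edge weights.

    Disconnected realizations are resampled (with a warning) when
    ``ensure_connected`` is set, since connectivity scans assume connected
    layers; the number of resamples is recorded on the returned layer as
    ``er_layer.last_resamples`` for logging.
    """
    if not 0 <= p_con <= 1:
        raise ValueError(f"p_con must be in [0, 1], got {p_con}")
    ss = np.random.SeedSequence([int(seed), N])
    resamples = 0
    for sub_seed in ss.generate_state(max_resamples + 1):
        G = nx.fast_gnp_random_graph(N, p_con, seed=int(sub_seed))
        if not ensure_connected or nx.is_connected(G):
            if resamples:
                warnings.warn(
                    f"resampled {resamples} disconnected ER realization(s) "
                    f"(N={N}, p_con={p_con})",
                    stacklevel=2,
                )
            er_layer.last_resamples = resamples
            W = nx.to_numpy_array(G, nodelist=range(N), dtype=float)
            return LayerGraph(W, name="er")
        resamples += 1
    raise RuntimeError(
        f"no connected G({N}, {p_con}) realization in {max_resamples} attempts"
    )


er_layer.last_resamples = 0


def ba_layer(N: int, m: int, seed: int) -> LayerGraph:
    """Barabasi-Albert preferential-attachment layer with unit weights.

    Uses the standard convention that growth starts from ``m`` isolated
    nodes, so the edge count is exactly ``m * (N - m)``.
    """
    if not 1 <= m < N:
        raise ValueError(f"need 1 <= m < N, got m={m}, N={N}")
    G = nx.barabasi_albert_graph(N, m, seed=int(seed))
    W = nx.to_numpy_array(G, nodelist=range(N), dtype=float)
    return LayerGraph(W, name="ba")


def diagonal_coupling(N: int, p: float, h: np.ndarray | None = None) -> InterlayerCoupling:
    """Diagonal (multiplex) coupling with entries ``p * h_k``.

    ``h`` defaults to all ones (homogeneous coupling of uniform weight p).
    """
    if p < 0:
        raise ValueError("p must be non-negative")
    if h is None:
        h = np.ones(N)
    h = np.asarray(h, dtype=float)
    if h.shape != (N,):
        raise ValueError(f"h must have shape ({N},), got {h.shape}")
    if np.any(h < 0):
        raise ValueError("h has negative entries")
    return InterlayerCoupling(np.diag(p * h), structure="diagonal")


def heterogeneous_weights(N: int, sigma: float, seed: int) -> np.ndarray:
    """i.i.d. interlayer weights, uniform with mean 1 and target sd ``sigma``.

    Drawn uniformly on ``[1 - a, 1 + a]`` with half-width ``a = sigma *
    sqrt(3)`` (the variance of that uniform distribution is ``a**2 / 3``).
    ``sigma`` above ``1/sqrt(3)`` would require negative weights and raises.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma > MAX_SIGMA + 1e-12:
        raise ValueError(
            f"sigma={sigma} exceeds 1/sqrt(3) ~ {MAX_SIGMA:.4f}; weights "
            "would go negative"
        )
    a = sigma * math.sqrt(3.0)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), N]))
    return rng.uniform(1.0 - a, 1.0 + a, size=N)


def full_coupling(N: int, p: float, C: np.ndarray | None = None) -> InterlayerCoupling:
    """All-to-all coupling block ``p * C``; ``C`` defaults to all ones."""
    if p < 0:
        raise ValueError("p must be non-negative")
    if C is None:
        C = np.ones((N, N))
    C = np.asarray(C, dtype=float)
    if C.shape != (N, N):
        raise ValueError(f"C must have shape ({N}, {N}), got {C.shape}")
    return InterlayerCoupling(p * C, structure="full")


def remove_interlayer_edges(
    P: InterlayerCoupling, fraction: float, seed: int
) -> InterlayerCoupling:
    """Zero out ``round(fraction * n_active)`` randomly chosen nonzero entries.

    The transposed block mirrors the deletion implicitly (couplings are
    stored one-directionally), so the supra-adjacency stays symmetric.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    block = P.block.copy()
    active = np.flatnonzero(block)
    n_remove = round(fraction * active.size)
    if n_remove:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), active.size]))
        drop = rng.choice(active, size=n_remove, replace=False)
        block.flat[drop] = 0.0
    structure = P.structure
    if structure == "full" and n_remove:
        structure = "partial"
    return InterlayerCoupling(block, structure=structure)


def densify_from_multiplex(
    N: int, percent_active: float, p: float, seed: int
) -> InterlayerCoupling:
    """Coupling interpolating between multiplex and full multilayer.

    Starts from the N diagonal entries and adds uniformly random off-diagonal
    entries until ``round(percent_active * N**2 / 100)`` entries are active,
    all with weight ``p``.
    """
    target = round(percent_active * N * N / 100.0)
    if target < N:
        raise ValueError(
            f"percent_active={percent_active} gives {target} active entries; "
            f"at least the {N} diagonal entries are required"
        )
    if target > N * N:
        raise ValueError("percent_active cannot exceed 100")
    block = np.zeros((N, N))
    np.fill_diagonal(block, p)
    n_extra = target - N
    if n_extra:
        off = np.flatnonzero(~np.eye(N, dtype=bool))
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), N, target]))
        add = rng.choice(off, size=n_extra, replace=False)
        block.flat[add] = p
    if target == N:
        structure = "diagonal"
    elif target == N * N:
        structure = "full"
    else:
        structure = "partial"
    return InterlayerCoupling(block, structure=structure)


def strengths(net: SupraNetwork) -> dict:
    """Layer and coupling strengths plus the interlayer/intralayer ratio.

    Layer strength is the full-matrix entry sum (each intralayer edge counted
    twice); coupling strength ``S_P`` is the single-direction block sum. The
    ratio is ``sum(S_P over coupling blocks) / sum(layer strengths)``.
    """
    layer_s = [lg.strength for lg in net.layers]
    coupling_s = {key: c.strength for key, c in net.couplings.items()}
    total_layers = sum(layer_s)
    total_coupling = sum(coupling_s.values())
    ratio = total_coupling / total_layers if total_layers > 0 else float("nan")
    return {
        "layer_strengths": layer_s,
        "coupling_strengths": coupling_s,
        "ratio": ratio,
    }
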