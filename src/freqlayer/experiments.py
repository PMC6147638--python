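"""Ensemble sweeps and empirical network summaries.

Orchestrates the synthetic-network experiments (interlayer-weight
heterogeneity, missing interlayer edges, multiplex-to-multilayer
densification) at configurable scale and computes per-subject summary
statistics of the four network representations (unfiltered, aggregated,
multiplex, full multilayer). Canonical outputs are tidy tables.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from freqlayer.netmodels import (
    ba_layer,
    densify_from_multiplex,
    diagonal_coupling,
    er_layer,
    full_coupling,
    heterogeneous_weights,
    strengths,
)
from freqlayer.network import InterlayerCoupling, LayerGraph, SupraNetwork
from freqlayer.spectral import (
    GridRangeError,
    algebraic_connectivity,
    combinatorial_laplacian,
    lambda2_agg,
    mean_weighted_degree,
    percent_deviation_from_aggregate,
    reference_lambda2,
    scan_transition,
    transition_point,
)

__all__ = [
    "SweepConfig",
    "run_heterogeneity_sweep",
    "run_missing_edges_sweep",
    "run_densification_sweep",
    "summarize_network",
    "rescale_coupling_to_pstar",
    "homogenize_couplings",
]


@dataclass
class SweepConfig:
    """Full specification of one ensemble sweep."""

    model: str = "er"  # "er" or "ba"
    n_nodes: int = 250
    p_con: float = 0.05
    m: int = 3  # BA attachment parameter
    n_layers: int = 2
    coupling: str = "multiplex"  # "multiplex" or "full"
    sigmas: list[float] = field(default_factory=lambda: [0.0])
    missing_fractions: list[float] = field(default_factory=lambda: [0.0])
    percents_active: list[float] = field(default_factory=list)
    p_grid: list[float] = field(
        default_factory=lambda: [float(p) for p in np.logspace(-2, 1, 25)]
    )
    n_realizations: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        # plain floats keep configs YAML/JSON-serializable
        self.sigmas = [float(s) for s in self.sigmas]
        self.missing_fractions = [float(f) for f in self.missing_fractions]
        self.percents_active = [float(p) for p in self.percents_active]
        self.p_grid = [float(p) for p in self.p_grid]
        if self.model not in ("er", "ba"):
            raise ValueError(f"unknown layer model {self.model!r}")
        if self.coupling not in ("multiplex", "full"):
            raise ValueError(f"unknown coupling regime {self.coupling!r}")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if not self.sigmas or not self.missing_fractions or not self.p_grid:
            raise ValueError("sigmas, missing_fractions and p_grid must be non-empty")

    @classmethod
    def from_yaml(cls, path: str) -> "SweepConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _realization_seed(cfg: SweepConfig, realization: int) -> int:
    # stable per-realization derivation: base seed offset by the index
    return cfg.base_seed + realization


def _make_layers(cfg: SweepConfig, realization: int) -> list[LayerGraph]:
    seed0 = _realization_seed(cfg, realization)
    layers = []
    for l in range(cfg.n_layers):
        sub = int(np.random.SeedSequence([seed0, 100 + l]).generate_state(1)[0])
        if cfg.model == "er":
            layers.append(er_layer(cfg.n_nodes, cfg.p_con, seed=sub))
        else:
            layers.append(ba_layer(cfg.n_nodes, cfg.m, seed=sub))
    return layers


def _coupling_template(
    cfg: SweepConfig, sigma: float, realization: int, variant: int = 0
) -> InterlayerCoupling:
    """Unit-scale coupling template, heterogeneous when sigma > 0."""
    N = cfg.n_nodes
    seed0 = _realization_seed(cfg, realization)
    sub = int(np.random.SeedSequence([seed0, 200 + variant]).generate_state(1)[0])
    if cfg.coupling == "multiplex":
        h = None if sigma == 0 else heterogeneous_weights(N, sigma, seed=sub)
        return diagonal_coupling(N, 1.0, h)
    if sigma == 0:
        return full_coupling(N, 1.0)
    C = heterogeneous_weights(N * N, sigma, seed=sub).reshape(N, N)
    return full_coupling(N, 1.0, C)


def _detect_pstar(scan) -> tuple[float, bool]:
    try:
        res = transition_point(scan)
        return res.p_star, res.crossed
    except GridRangeError:
        return float("nan"), False


def _tag(df: pd.DataFrame, cfg: SweepConfig, sweep: str) -> pd.DataFrame:
    df.insert(0, "sweep", sweep)
    df["config_hash"] = cfg.config_hash()
    df["base_seed"] = cfg.base_seed
    return df


def run_heterogeneity_sweep(cfg: SweepConfig) -> pd.DataFrame:
    """Mean lambda2(p) per heterogeneity level sigma, with references.

    For each realization the same layer pair is reused across all sigma
    values (baseline pairing), so delta_lambda2 against the sigma=0 baseline
    is exactly zero when sigma = 0. Output is a tidy table with one row per
    (sigma, p) carrying ensemble means and the homogeneous reference curves.
    """
    p_grid = np.asarray(cfg.p_grid, dtype=float)
    lam2 = {s: [] for s in cfg.sigmas}
    pstars = {s: [] for s in cfg.sigmas}
    ref_small = []
    ref_large = []
    for r in range(cfg.n_realizations):
        layers = _make_layers(cfg, r)
        for si, sigma in enumerate(cfg.sigmas):
            template = _coupling_template(cfg, sigma, r, variant=si)
            scan = scan_transition(layers, template, p_grid)
            lam2[sigma].append(scan.lambda2)
            p_star, _ = _detect_pstar(scan)
            pstars[sigma].append(p_star)
        net0 = SupraNetwork(layers, {(0, 1): _coupling_template(cfg, 0.0, r)})
        small = "multiplex_small_p" if cfg.coupling == "multiplex" else "multilayer_small_p"
        large = "multiplex_large_p" if cfg.coupling == "multiplex" else "multilayer_large_p"
        ref_small.append([reference_lambda2(small, p, net0) for p in p_grid])
        ref_large.append([reference_lambda2(large, p, net0) for p in p_grid])
    zero_key = next((s for s in cfg.sigmas if float(s) == 0.0), None)
    rows = []
    for sigma in cfg.sigmas:
        mean = np.mean(lam2[sigma], axis=0)
        if zero_key is not None:
            delta = np.mean(
                np.asarray(lam2[zero_key]) - np.asarray(lam2[sigma]), axis=0
            )
        else:
            delta = np.full_like(mean, np.nan)
        ps = np.asarray(pstars[sigma], dtype=float)
        for k, p in enumerate(p_grid):
            rows.append(
                {
                    "sigma": sigma,
                    "p": p,
                    "lambda2_mean": mean[k],
                    "delta_lambda2_mean": delta[k],
                    "reference_small_p": np.mean(ref_small, axis=0)[k],
                    "reference_large_p": np.mean(ref_large, axis=0)[k],
                    "p_star_mean": float(np.nanmean(ps)),
                    "n_realizations": cfg.n_realizations,
                }
            )
    return _tag(pd.DataFrame(rows), cfg, "heterogeneity")


def run_missing_edges_sweep(cfg: SweepConfig) -> pd.DataFrame:
    """Mean lambda2(p) per missing-interlayer-edge fraction.

    delta_lambda2 is taken against the complete-coupling baseline of the
    same realization.
    """
    from freqlayer.netmodels import remove_interlayer_edges

    p_grid = np.asarray(cfg.p_grid, dtype=float)
    lam2 = {f: [] for f in cfg.missing_fractions}
    pstars = {f: [] for f in cfg.missing_fractions}
    for r in range(cfg.n_realizations):
        layers = _make_layers(cfg, r)
        complete = _coupling_template(cfg, 0.0, r)
        for fi, frac in enumerate(cfg.missing_fractions):
            sub = int(
                np.random.SeedSequence(
                    [_realization_seed(cfg, r), 300 + fi]
                ).generate_state(1)[0]
            )
            template = (
                complete if frac == 0 else remove_interlayer_edges(complete, frac, sub)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # deletions may disconnect
                scan = scan_transition(layers, template, p_grid)
            lam2[frac].append(scan.lambda2)
            p_star, _ = _detect_pstar(scan)
            pstars[frac].append(p_star)
    zero_key = next((f for f in cfg.missing_fractions if float(f) == 0.0), None)
    rows = []
    for frac in cfg.missing_fractions:
        mean = np.mean(lam2[frac], axis=0)
        if zero_key is not None:
            delta = np.mean(np.asarray(lam2[zero_key]) - np.asarray(lam2[frac]), axis=0)
        else:
            delta = np.full_like(mean, np.nan)
        ps = np.asarray(pstars[frac], dtype=float)
        for k, p in enumerate(p_grid):
            rows.append(
                {
                    "missing_fraction": frac,
                    "p": p,
                    "lambda2_mean": mean[k],
                    "delta_lambda2_mean": delta[k],
                    "p_star_mean": float(np.nanmean(ps)),
                    "n_realizations": cfg.n_realizations,
                }
            )
    return _tag(pd.DataFrame(rows), cfg, "missing_edges")


def run_densification_sweep(cfg: SweepConfig) -> pd.DataFrame:
    """lambda2(p) while densifying the coupling from multiplex to full.

    One row per (percent_active, p), carrying the mean lambda2 and the mean
    interlayer-to-intralayer strength ratio S_P / (S_alpha + S_beta).
    """
    if not cfg.percents_active:
        raise ValueError("percents_active must be non-empty for a densification sweep")
    p_grid = np.asarray(cfg.p_grid, dtype=float)
    rows = []
    for percent in cfg.percents_active:
        lam2_all, ratio_all = [], []
        for r in range(cfg.n_realizations):
            layers = _make_layers(cfg, r)
            sub = int(
                np.random.SeedSequence(
                    [_realization_seed(cfg, r), 400]
                ).generate_state(1)[0]
            )
            template = densify_from_multiplex(cfg.n_nodes, percent, 1.0, seed=sub)
            scan = scan_transition(layers, template, p_grid)
            lam2_all.append(scan.lambda2)
            ratios = []
            for p in p_grid:
                net = SupraNetwork(layers, {(0, 1): template.scaled(p)})
                ratios.append(strengths(net)["ratio"])
            ratio_all.append(ratios)
        lam2_mean = np.mean(lam2_all, axis=0)
        ratio_mean = np.mean(ratio_all, axis=0)
        for k, p in enumerate(p_grid):
            rows.append(
                {
                    "percent_active": percent,
                    "p": p,
                    "lambda2_mean": lam2_mean[k],
                    "strength_ratio_mean": ratio_mean[k],
                    "n_realizations": cfg.n_realizations,
                }
            )
    return _tag(pd.DataFrame(rows), cfg, "densification")


def _interlayer_entries(net: SupraNetwork, diagonal_only: bool) -> np.ndarray:
    vals = []
    for coup in net.couplings.values():
        if diagonal_only:
            vals.append(np.diag(coup.block))
        else:
            vals.append(coup.block.ravel())
    return np.concatenate(vals) if vals else np.array([])


def _sigma_of(entries: np.ndarray) -> float:
    nz = entries[entries > 0]
    return float(nz.std()) if nz.size else float("nan")


def _monolayer_summary(lg: LayerGraph) -> dict:
    W = lg.weights
    off = W[~np.eye(lg.n_nodes, dtype=bool)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lam2 = algebraic_connectivity(combinatorial_laplacian(W))
    return {
        "lambda2": lam2,
        "sigma_weights": _sigma_of(off),
        "percent_missing": 100.0 * float(np.mean(off == 0)),
    }


def _supra_summary(net: SupraNetwork, diagonal_only: bool) -> dict:
    entries = _interlayer_entries(net, diagonal_only)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lam2 = algebraic_connectivity(combinatorial_laplacian(net))
    return {
        "lambda2": lam2,
        "sigma_weights": _sigma_of(entries),
        "percent_missing": 100.0 * float(np.mean(entries == 0)) if entries.size else 0.0,
    }


def _strength_percentages(net: SupraNetwork) -> dict:
    """Intralayer/interlayer strength percentages of the entrywise 1-norm.

    For layer l the intralayer share is 100 * ||M^l||_1 / ||M||_1; the
    interlayer share credits each coupling block once to each of its two
    endpoint layers (i.e. half of the both-direction interlayer weight
    incident to the layer). With this split the shares over all layers sum
    to exactly 100, matching the printed per-layer strength tables.
    """
    layer_norms = [lg.strength for lg in net.layers]
    total = sum(layer_norms)
    inter = np.zeros(net.n_layers)
    for (a, b), coup in net.couplings.items():
        inter[a] += coup.strength
        inter[b] += coup.strength
        total += 2.0 * coup.strength
    if total == 0:
        raise ValueError("network has zero total strength")
    names = [lg.name or f"layer{i}" for i, lg in enumerate(net.layers)]
    return {
        "intralayer_strength_percent": {
            nm: 100.0 * s / total for nm, s in zip(names, layer_norms)
        },
        "interlayer_strength_percent": {
            nm: 100.0 * s / total for nm, s in zip(names, inter)
        },
    }


def _pairwise_lambda2(net: SupraNetwork) -> dict:
    out = {}
    names = [lg.name or f"layer{i}" for i, lg in enumerate(net.layers)]
    for (a, b), coup in net.couplings.items():
        sub = SupraNetwork([net.layers[a], net.layers[b]], {(0, 1): coup})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[f"{names[a]}-{names[b]}"] = algebraic_connectivity(
                combinatorial_laplacian(sub)
            )
    return out


def summarize_network(
    unfiltered: LayerGraph | None = None,
    aggregated: LayerGraph | None = None,
    multiplex: SupraNetwork | None = None,
    multilayer: SupraNetwork | None = None,
    p_grid: np.ndarray | None = None,
) -> dict:
    """Summary statistics of one subject's four network representations.

    Computes lambda2, the standard deviation of the (interlayer) edge
    weights, and the missing-edge percentage for each representation; for
    the full multilayer network additionally the per-layer strength
    percentages, all two-layer lambda2 values, the percent deviation from
    the aggregated reference, and (when ``p_grid`` is given) the detected
    transition point of the rescaled coupling.

    Missing-edge convention: for monolayer networks the percentage counts
    zero off-diagonal entries of the whole matrix; for the multiplex it
    counts zeros among the diagonal interlayer entries; for the full
    multilayer it counts zeros among all interlayer entries.
    """
    out: dict = {}
    if unfiltered is not None:
        out["unfiltered"] = _monolayer_summary(unfiltered)
    if aggregated is not None:
        out["aggregated"] = _monolayer_summary(aggregated)
    if multiplex is not None:
        out["multiplex"] = _supra_summary(multiplex, diagonal_only=True)
    if multilayer is not None:
        ml = _supra_summary(multilayer, diagonal_only=False)
        ml.update(_strength_percentages(multilayer))
        ml["pairwise_lambda2"] = _pairwise_lambda2(multilayer)
        lam2_agg_ref = lambda2_agg(multilayer)
        ml["lambda2_agg"] = lam2_agg_ref
        ml["percent_delta_lambda2"] = percent_deviation_from_aggregate(
            ml["lambda2"], lam2_agg_ref
        )
        if p_grid is not None:
            scan, res, position = rescale_coupling_to_pstar(multilayer, p_grid)
            ml["p_star"] = res.p_star
            ml["p_star_crossed"] = res.crossed
            ml["p1_position"] = position
        out["multilayer"] = ml
    if not out:
        raise ValueError("no network representation given")
    return out


def homogenize_couplings(net: SupraNetwork) -> SupraNetwork:
    """Reference network with every allowed interlayer entry set to the block mean.

    For a diagonal (multiplex) coupling the mean over the N diagonal entries
    is assigned to all diagonal entries; otherwise the mean over all entries
    is assigned to every entry. Total interlayer strength is preserved, so
    the homogeneous reference is comparable at equal S_P.
    """
    couplings = {}
    for key, coup in net.couplings.items():
        if coup.structure == "diagonal":
            mean = float(np.diag(coup.block).mean())
            block = np.diag(np.full(coup.shape[0], mean))
            couplings[key] = InterlayerCoupling(block, structure="diagonal")
        else:
            mean = float(coup.block.mean())
            couplings[key] = InterlayerCoupling(
                np.full(coup.shape, mean), structure="full"
            )
    return SupraNetwork(list(net.layers), couplings)


def rescale_coupling_to_pstar(net: SupraNetwork, p_grid: np.ndarray):
    """Scale the network's own couplings by p and locate the transition.

    Returns ``(scan, transition_result, position)`` where ``position`` says
    whether the unscaled network (p = 1) sits "below", "above" or "at" the
    detected transition point.
    """
    p_grid = np.asarray(p_grid, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scan = scan_transition(net.layers, dict(net.couplings), p_grid)
    res = transition_point(scan)
    if np.isclose(1.0, res.p_star, rtol=0.05):
        position = "at"
    elif 1.0 < res.p_star:
        position = "below"
    else:
        position = "above"
    return scan, res, position
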