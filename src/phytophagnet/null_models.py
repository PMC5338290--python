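"""Degree-constrained randomization of bipartite networks and Z-scores.

Two null models are provided:

``fixed_fixed``
    Checkerboard-swap (curveball-style) randomization that preserves both
    degree sequences *exactly*.  This is the default: it makes edge counts
    and node degrees trivially conserved, which the evenness and
    food-pairing Z-tests require to be meaningful.

``probabilistic``
    Each insect-plant cell is filled independently with probability
    proportional to the product of the node degrees, scaled so the
    expected edge count equals the observed one (cell probabilities
    capped at 1).  Degrees are preserved in expectation only.

Every observed statistic X is scored against the null ensemble as
Z = (X_obs − mean(X_null)) / sd(X_null), with the sample SD (n−1
denominator).  A null ensemble with zero SD yields a flagged degenerate
result rather than an infinite Z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .model import PlantHerbivoreNetwork

log = logging.getLogger(__name__)

__all__ = [
    "NullModelConfig",
    "ZScoreResult",
    "randomize_fixed_fixed",
    "randomize_probabilistic",
    "zscore",
    "null_distribution",
]

NULL_MODELS = ("fixed_fixed", "probabilistic")


@dataclass(frozen=True)
class NullModelConfig:
    """Randomization settings; a fixed seed makes the replicate stream reproducible."""

    model: str = "fixed_fixed"
    replicates: int = 1000
    seed: int = 0
    swaps_per_edge: int = 10

    def __post_init__(self) -> None:
        if self.model not in NULL_MODELS:
            raise ValueError(f"model must be one of {NULL_MODELS}, got {self.model!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")


@dataclass(frozen=True)
class ZScoreResult:
    """Observed statistic vs a null ensemble.

    ``z`` is None exactly when the null SD is zero (``degenerate``);
    downstream tables print such cells as NA.
    """

    observed: float
    null_mean: float
    null_sd: float
    z: Optional[float]
    replicates: int
    degenerate: bool

    def z_or_nan(self) -> float:
        return float("nan") if self.z is None else self.z


def zscore(observed: float, null_values: Sequence[float]) -> ZScoreResult:
    """Score ``observed`` against ``null_values`` (sample SD, n−1 denominator)."""
    vals = np.asarray(null_values, dtype=float)
    if vals.size == 0:
        raise ValueError("null_values must be non-empty")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if sd == 0.0:
        return ZScoreResult(float(observed), mean, 0.0, None, vals.size, True)
    return ZScoreResult(float(observed), mean, sd, (float(observed) - mean) / sd, vals.size, False)


def _indexed_edges(net: PlantHerbivoreNetwork):
    insects = sorted(net.insects)
    plants = sorted(net.plants)
    i_idx = {s: k for k, s in enumerate(insects)}
    p_idx = {s: k for k, s in enumerate(plants)}
    edges = sorted((i_idx[i], p_idx[p]) for i, p in net.edges)
    return insects, plants, edges


def _swap_chain(edges: list[tuple[int, int]], rng: np.random.Generator, attempts: int) -> int:
    """In-place checkerboard swaps on an edge list; returns accepted count.

    Each accepted swap exchanges (a,p),(b,q) for (a,q),(b,p), which
    conserves every node degree and the edge count.
    """
    m = len(edges)
    present = set(edges)
    picks = rng.integers(0, m, size=(attempts, 2))
    accepted = 0
    for k in range(attempts):
        e1, e2 = picks[k]
        a, p = edges[e1]
        b, q = edges[e2]
        if a == b or p == q:
            continue
        if (a, q) in present or (b, p) in present:
            continue
        present.discard((a, p))
        present.discard((b, q))
        present.add((a, q))
        present.add((b, p))
        edges[e1] = (a, q)
        edges[e2] = (b, p)
        accepted += 1
    return accepted


def randomize_fixed_fixed(
    net: PlantHerbivoreNetwork,
    seed: Union[int, np.random.Generator] = 0,
    swaps_per_edge: int = 10,
) -> PlantHerbivoreNetwork:
    """Degree-preserving randomization via checkerboard swaps.

    Attempts ``swaps_per_edge * |edges|`` swaps as burn-in.  Networks
    admitting no valid swap (e.g. complete bipartite) come back unchanged.
    """
    if net.n_edges < 2:
        raise ValueError("fixed_fixed randomization needs at least 2 edges")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    insects, plants, edges = _indexed_edges(net)
    accepted = _swap_chain(edges, rng, swaps_per_edge * len(edges))
    if accepted == 0:
        log.info("no valid checkerboard swap found; returning the input network unchanged")
    return PlantHerbivoreNetwork(
        [(insects[i], plants[p]) for i, p in edges],
        insects=net.insects,
        plants=net.plants,
        _normalized=True,
    )


def cell_probabilities(net: PlantHerbivoreNetwork):
    """Per-cell fill probabilities of the probabilistic null model.

    p_ij = min(1, d_i * d_j / m): proportional to the degree product and
    scaled so the expected edge count equals the observed m (before capping).
    Returns (insects, plants, matrix).
    """
    insects = sorted(net.insects)
    plants = sorted(net.plants)
    di = np.array([net.insect_degree(s) for s in insects], dtype=float)
    dp = np.array([net.plant_degree(s) for s in plants], dtype=float)
    m = net.n_edges
    probs = np.minimum(1.0, np.outer(di, dp) / m)
    return insects, plants, probs


def randomize_probabilistic(
    net: PlantHerbivoreNetwork, seed: Union[int, np.random.Generator] = 0
) -> PlantHerbivoreNetwork:
    """Independent-cell randomization preserving degrees in expectation."""
    if net.n_edges < 1:
        raise ValueError("probabilistic randomization needs at least 1 edge")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    insects, plants, probs = cell_probabilities(net)
    fill = rng.random(probs.shape) < probs
    ii, pp = np.nonzero(fill)
    return PlantHerbivoreNetwork(
        [(insects[i], plants[p]) for i, p in zip(ii, pp)],
        insects=net.insects,
        plants=net.plants,
        _normalized=True,
    )


def null_distribution(
    net: PlantHerbivoreNetwork,
    statistic: Callable[[PlantHerbivoreNetwork], Union[float, np.ndarray]],
    config: NullModelConfig,
) -> np.ndarray:
    """Evaluate ``statistic`` on independently randomized replicates.

    One master seed spawns one child seed per replicate, so replicate r is
    reproducible in isolation.  Returns an array of shape (replicates,) for
    scalar statistics or (replicates, k) for vector-valued ones.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.replicates)
    values = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        if config.model == "fixed_fixed":
            rep = randomize_fixed_fixed(net, rng, config.swaps_per_edge)
        else:
            rep = randomize_probabilistic(net, rng)
        try:
            values.append(statistic(rep))
        except Exception as exc:
            raise RuntimeError(f"statistic failed on null replicate {r}: {exc}") from exc
    return np.asarray(values, dtype=float)
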