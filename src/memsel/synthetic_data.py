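"""Synthetic baseline inputs: site layouts, river networks, communities.

The generator stands in for real survey data: it produces planar or
river-tree site layouts and presence/absence matrices whose statistical
structure matches what multi-species survey data typically look like —
species intercepts drawn on the logit scale with most species rare
(right-skewed prevalence), spatial slopes on a subset of eigenvectors, and
sites and species conditionally independent given the design.

All randomness comes from ``numpy.random.SeedSequence(seed, spawn_key=...)``
substreams in a fixed, documented order: spawn key (0,) for coordinates and
network, (1,) for the baseline community. Identical configs therefore give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from memsel.spatial_basis import ORIGIN, EdgeList, EigenBasis

__all__ = [
    "SyntheticBaselineConfig",
    "generate_coordinates",
    "generate_baseline_community",
]

LAYOUTS = ("uniform-plane", "river-tree")


@dataclass(frozen=True)
class SyntheticBaselineConfig:
    """Configuration of one synthetic baseline dataset.

    Parameters
    ----------
    n_sites, n_species
        Dimensions of the community matrix (n_sites >= 5, n_species >= 2).
    layout
        ``uniform-plane``: sites uniform on a rectangle; ``river-tree``:
        sites on a random branching river network flowing from a single
        upstream origin.
    intercept_mean, intercept_sd
        Logit-scale species intercept distribution. The default mean of -2
        puts median prevalence near 0.12, giving the many-rare-species
        profile typical of community surveys.
    slope_sd
        Standard deviation of non-zero spatial slopes (logit scale per
        unit-norm eigenvector).
    slope_prob
        Probability that any given eigenvector carries non-zero slopes in
        the baseline community.
    extent
        Side length of the square sampling window for ``uniform-plane``.
    """

    n_sites: int
    n_species: int
    layout: str = "uniform-plane"
    intercept_mean: float = -2.0
    intercept_sd: float = 1.5
    slope_sd: float = 2.0
    slope_prob: float = 0.5
    extent: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 5:
            raise ValueError("n_sites must be at least 5")
        if self.n_species < 2:
            raise ValueError("n_species must be at least 2")
        if self.layout not in LAYOUTS:
            raise ValueError(f"layout must be one of {LAYOUTS}")
        if self.intercept_sd <= 0 and self.slope_sd < 0:
            raise ValueError("standard deviations must be positive")
        if self.intercept_sd <= 0:
            raise ValueError("intercept_sd must be positive")
        if self.slope_sd < 0:
            raise ValueError("slope_sd must be non-negative")


def _rng(cfg: SyntheticBaselineConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


def _river_tree(n: int, rng: np.random.Generator) -> tuple[np.ndarray, EdgeList]:
    """Random binary-branching river network with exponential edge lengths.

    Sites are added one at a time, each attached downstream of a node
    (or the virtual origin) that still has fewer than two downstream
    branches; attachment favours current leaves so chains form tributaries
    rather than a star. Positions follow the flow direction with small
    random turns, giving a planar embedding with distinct positions.
    """
    parent = np.full(n, ORIGIN, dtype=int)
    n_children = {ORIGIN: 0}
    pos = {ORIGIN: np.array([0.0, 0.0])}
    heading = {ORIGIN: rng.uniform(0, 2 * np.pi)}
    lengths = np.empty(n)
    for i in range(n):
        open_nodes = [v for v, c in n_children.items() if c < 2]
        # leaves extend with weight 4, interior nodes branch with weight 1
        wts = np.array([4.0 if n_children[v] == 0 else 1.0 for v in open_nodes])
        p = int(rng.choice(len(open_nodes), p=wts / wts.sum()))
        par = open_nodes[p]
        parent[i] = par
        n_children[par] += 1
        n_children[i] = 0
        lengths[i] = rng.exponential(1.0)
        turn = rng.normal(0.0, 0.5) + (0.9 if n_children[par] == 2 else 0.0)
        heading[i] = heading[par] + turn
        pos[i] = pos[par] + lengths[i] * np.array(
            [np.cos(heading[i]), np.sin(heading[i])]
        )
    xy = np.array([pos[i] for i in range(n)])
    edges = np.array([[parent[i], i] for i in range(n)], dtype=int)
    return xy, EdgeList(edges=edges, lengths=lengths, directed=True)


def generate_coordinates(
    cfg: SyntheticBaselineConfig,
) -> tuple[pd.DataFrame, EdgeList | None]:
    """Generate site coordinates (and the directed network for river-tree).

    Returns a ``site,x,y`` data frame and, for ``river-tree`` layouts, a
    directed :class:`EdgeList` whose virtual upstream origin is coded as -1.
    """
    rng = _rng(cfg, 0)
    if cfg.layout == "uniform-plane":
        xy = rng.uniform(0.0, cfg.extent, size=(cfg.n_sites, 2))
        network = None
    else:
        xy, network = _river_tree(cfg.n_sites, rng)
    coords = pd.DataFrame(
        {"site": [f"s{i:03d}" for i in range(cfg.n_sites)], "x": xy[:, 0], "y": xy[:, 1]}
    )
    return coords, network


def generate_baseline_community(
    cfg: SyntheticBaselineConfig, basis: EigenBasis
) -> np.ndarray:
    """Simulate a baseline presence/absence matrix on a spatial basis.

    Species intercepts are Normal(intercept_mean, intercept_sd); each
    eigenvector carries non-zero slopes (Normal(0, slope_sd) per species)
    with probability ``slope_prob``. Presences are Bernoulli draws of the
    logistic probabilities (the true-absence mechanism), so the matrix has
    known, controllable spatial structure.
    """
    if basis.m == 0:
        raise ValueError("cannot simulate a community from an empty basis")
    if basis.n != cfg.n_sites:
        raise ValueError("basis was not built from this configuration's sites")
    rng = _rng(cfg, 1)
    n, m, p = cfg.n_sites, basis.m, cfg.n_species
    intercepts = rng.normal(cfg.intercept_mean, cfg.intercept_sd, size=p)
    active = rng.random(m) < cfg.slope_prob
    slopes = np.where(
        active[:, None], rng.normal(0.0, cfg.slope_sd, size=(m, p)), 0.0
    )
    eta = intercepts[None, :] + basis.vectors @ slopes
    prob = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random((n, p)) < prob).astype(np.int8)
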