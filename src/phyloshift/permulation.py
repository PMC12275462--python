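"""Phylogeny-aware null trait generation for binary traits (permulation).

A null foreground set is drawn by simulating Brownian motion down the
tree (independent Gaussian increments per branch, variance equal to
branch length) and taking the k tips with the largest simulated values,
where k is the observed foreground count.  Rejection sampling then
enforces that the candidate matches the observed trait's phylogenetic
structure, operationalized as an equal number of maximal foreground-only
clades.  Because ranking is scale-invariant the BM variance per unit
branch length is fixed at 1.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .likelihood import ForegroundSpec, foreground_branches
from .tree import PhyloTree

__all__ = [
    "PermulationConfig",
    "NullTrait",
    "PermulationError",
    "simulate_bm_tips",
    "permulate_binary",
    "null_trait_stream",
]


class PermulationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy its constraint."""


@dataclass
class PermulationConfig:
    n_max: int = 1000
    match_clades: bool = True
    max_rejections: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.max_rejections < 1:
            raise ValueError("max_rejections must be >= 1")


@dataclass(frozen=True)
class NullTrait:
    fg_tips: frozenset[str]
    draw_index: int


def _rng_for_draw(seed: int, draw_index: int) -> np.random.Generator:
    # independent sub-streams, deterministic in (seed, draw_index)
    return np.random.default_rng(np.random.SeedSequence([seed, draw_index]))


def simulate_bm_tips(
    tree: PhyloTree, seed_or_rng: int | np.random.Generator
) -> dict[str, float]:
    """One Brownian-motion draw: tip value = sum of N(0, branch length)
    increments along the root-to-tip path; the root sits at 0."""
    if not np.any(tree.lengths > 0):
        raise ValueError("all branch lengths are zero: degenerate BM covariance")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    incr = rng.normal(0.0, np.sqrt(tree.lengths))
    value = np.zeros(tree.n_nodes)
    # preorder: parents have larger ids, so iterate from the root down
    for v in range(tree.n_nodes - 1, -1, -1):
        p = tree.parent[v]
        value[v] = incr[v] + (value[p] if p >= 0 else 0.0)
    return {tree.names[int(v)]: float(value[v]) for v in tree.tip_ids}


def _top_k_tips(values: dict[str, float], k: int) -> frozenset[str]:
    # stable sort: ties broken by the order tips were drawn (tree order)
    names = list(values)
    order = np.argsort([-values[n] for n in names], kind="stable")
    return frozenset(names[i] for i in order[:k])


def permulate_binary(
    tree: PhyloTree,
    observed_fg: ForegroundSpec,
    config: PermulationConfig,
    draw_index: int = 0,
) -> NullTrait:
    """Draw one accepted null foreground set."""
    k = len(observed_fg.fg_tips)
    rng = _rng_for_draw(config.seed, draw_index)
    for _ in range(config.max_rejections):
        values = simulate_bm_tips(tree, rng)
        candidate = _top_k_tips(values, k)
        if not config.match_clades:
            return NullTrait(candidate, draw_index)
        spec = foreground_branches(tree, candidate)
        if spec.n_clades == observed_fg.n_clades:
            return NullTrait(candidate, draw_index)
    raise PermulationError(
        f"no candidate with {observed_fg.n_clades} foreground clade(s) "
        f"in {config.max_rejections} draws"
    )


def null_trait_stream(
    tree: PhyloTree, observed_fg: ForegroundSpec, config: PermulationConfig
) -> Iterator[NullTrait]:
    """Up to n_max accepted null traits with per-draw derived sub-seeds.

    Draws are independent given (seed, draw_index), so the stream is
    reproducible and order-independent; duplicate foreground sets across
    draws are permitted (sampling with replacement).
    """
    for i in range(config.n_max):
        yield permulate_binary(tree, observed_fg, config, draw_index=i)
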