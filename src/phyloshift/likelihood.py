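"""Felsenstein pruning log-likelihood under per-branch scaling.

Two scale factors act on the neutral branch lengths: a global factor rho
applied to every branch, and an extra factor lam applied only to the
*foreground* branch set induced by the foreground species.  The
foreground branch set consists of the terminal branches of the
foreground tips plus every internal branch whose entire tip descendant
set is foreground — i.e. the branches of all maximal foreground-only
subtrees.

Missing data ('N') and alignment gaps ('-') are both marginalized: a
missing character contributes a partial-likelihood vector of ones, so an
all-missing column contributes exactly zero log-likelihood.  Identical
column patterns are collapsed and weighted before pruning.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .substitution import ALPHABET, NeutralModel
from .tree import PhyloTree

__all__ = [
    "Alignment",
    "ForegroundSpec",
    "BranchScaling",
    "foreground_branches",
    "log_likelihood",
    "LikelihoodEngine",
    "MISSING",
    "GAP",
]

logger = logging.getLogger(__name__)

MISSING = 4  # integer code for N
GAP = 5      # integer code for '-'; marginalized like N, preserved in I/O
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_CODE.update({"N": MISSING, "-": GAP})
_DECODE = np.array(list(ALPHABET + "N-"))


@dataclass
class Alignment:
    """Species-by-column nucleotide matrix with missing-data semantics.

    ``data`` holds integer codes 0..3 for ACGT and 4 for missing (N or
    gap).  Rows are species; all rows have equal length.
    """

    species: list[str]
    data: np.ndarray  # (n_species, length) int8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.species):
            raise ValueError("data must be (n_species, length)")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species names")

    @classmethod
    def from_strings(cls, seqs: dict[str, str]) -> "Alignment":
        names = list(seqs)
        lens = {len(s) for s in seqs.values()}
        if len(lens) > 1:
            raise ValueError("ragged alignment: unequal sequence lengths")
        rows = []
        for name in names:
            s = seqs[name].upper()
            try:
                rows.append([_CODE[c] for c in s])
            except KeyError as exc:
                raise ValueError(f"invalid character {exc} in sequence {name}") from exc
        data = np.array(rows, dtype=np.int8) if rows else np.zeros((0, 0), np.int8)
        return cls(names, data)

    def to_strings(self) -> dict[str, str]:
        return {
            name: "".join(_DECODE[self.data[i]]) for i, name in enumerate(self.species)
        }

    @property
    def length(self) -> int:
        return self.data.shape[1]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def slice_columns(self, start: int, end: int) -> "Alignment":
        return Alignment(list(self.species), self.data[:, start:end])

    def n_informative_species(self) -> int:
        """Number of rows with at least one non-missing character."""
        if self.length == 0:
            return 0
        return int((self.data < MISSING).any(axis=1).sum())


@dataclass(frozen=True)
class ForegroundSpec:
    """Foreground tip set and the branch set it induces on a tree."""

    fg_tips: frozenset[str]
    fg_branches: frozenset[int]  # node ids at the child end of each branch
    n_clades: int


@dataclass
class BranchScaling:
    """Global scale rho on all branches; extra scale lam on foreground."""

    rho: float
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.rho < 0 or self.lam < 0:
            raise ValueError("rho and lam must be non-negative")


def foreground_branches(tree: PhyloTree, fg_tips) -> ForegroundSpec:
    """Map a foreground species set to its induced branch set.

    The set contains the terminal branches of the foreground tips and
    every internal branch whose clade is entirely foreground.
    ``n_clades`` counts maximal foreground-only subtrees (connected
    components of the foreground branch set).
    """
    fg = frozenset(fg_tips)
    tips = set(tree.tip_names)
    unknown = fg - tips
    if unknown:
        raise ValueError(f"unknown tip name(s): {sorted(unknown)}")
    if not fg:
        raise ValueError("foreground set is empty")
    if fg == tips:
        raise ValueError("foreground cannot include every tip")

    # postorder: a node is all-foreground iff it is a fg tip, or internal
    # with all children all-foreground
    all_fg = np.zeros(tree.n_nodes, dtype=bool)
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            all_fg[v] = tree.names[v] in fg
        else:
            all_fg[v] = all(all_fg[c] for c in tree.children[v])
    branches = frozenset(
        int(v) for v in range(tree.n_nodes) if all_fg[v] and tree.parent[v] != -1
    )
    n_clades = sum(
        1 for v in branches if int(tree.parent[v]) not in branches
    )
    return ForegroundSpec(fg, branches, n_clades)


def _collapse_patterns(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique columns and their multiplicities."""
    patterns, counts = np.unique(data, axis=1, return_counts=True)
    return patterns, counts


def effective_lengths(
    tree: PhyloTree, scaling: BranchScaling, fg: ForegroundSpec | None
) -> np.ndarray:
    t = tree.lengths * scaling.rho
    if fg is not None and scaling.lam != 1.0:
        idx = np.fromiter(fg.fg_branches, dtype=np.int64, count=len(fg.fg_branches))
        t[idx] *= scaling.lam
    return t


class LikelihoodEngine:
    """Pruning likelihood with column patterns collapsed once.

    Built per (alignment, model) pair; ``loglik`` may then be called many
    times with different scale factors and foreground branch sets, as the
    rate-shift optimizer and the permulation loop require.
    """

    def __init__(
        self,
        alignment: Alignment,
        model: NeutralModel,
        *,
        collapse: bool = True,
    ) -> None:
        tree = model.tree
        if tree is None:
            raise ValueError("model has no tree")
        if alignment.length == 0:
            raise ValueError("zero-length alignment")
        tip_of = tree.tip_index()
        shared = [s for s in alignment.species if s in tip_of]
        dropped = [s for s in alignment.species if s not in tip_of]
        if dropped:
            logger.warning(
                "dropping %d species absent from tree: %s", len(dropped), dropped
            )
        if not shared:
            raise ValueError("no alignment species matches a tree tip")
        self.model = model
        self.tree = tree
        self.length = alignment.length

        rows = np.full((tree.n_nodes, alignment.length), MISSING, dtype=np.int8)
        row_of = {name: i for i, name in enumerate(alignment.species)}
        for name, node in tip_of.items():
            if name in row_of:
                rows[node] = alignment.data[row_of[name]]
        tip_data = rows[tree.tip_ids]
        if collapse:
            self.patterns, self.counts = _collapse_patterns(tip_data)
        else:
            self.patterns = tip_data
            self.counts = np.ones(alignment.length)
        # precomputed tip partials: one-hot; ones for missing (N or gap)
        lookup = np.vstack([np.eye(4), np.ones(4), np.ones(4)])
        self._tip_partials = {
            int(v): lookup[self.patterns[i]] for i, v in enumerate(tree.tip_ids)
        }

    def loglik(
        self, rho: float, lam: float = 1.0, fg: ForegroundSpec | None = None
    ) -> float:
        if rho < 0 or lam < 0:
            raise ValueError("rho and lam must be non-negative")
        tree = self.tree
        t_eff = effective_lengths(tree, BranchScaling(rho, lam), fg)
        P = self.model.transition_matrices(t_eff)  # root entry unused
        npat = self.patterns.shape[1]
        partial: list[np.ndarray | None] = [None] * tree.n_nodes
        for v in range(tree.n_nodes):
            if tree.is_tip(v):
                partial[v] = self._tip_partials[v]
            else:
                acc = np.ones((npat, 4))
                for c in tree.children[v]:
                    acc *= partial[c] @ P[c].T
                    partial[c] = None
                partial[v] = acc
        site_lik = partial[tree.root] @ self.model.pi
        if np.any(site_lik <= 0):
            site_lik = np.maximum(site_lik, np.finfo(float).tiny)
        return float(np.dot(self.counts, np.log(site_lik)))


def log_likelihood(
    alignment: Alignment,
    model: NeutralModel,
    scaling: BranchScaling,
    fg: ForegroundSpec | None = None,
    *,
    collapse: bool = True,
) -> float:
    """Pruning log-likelihood of the alignment under the scaled model.

    Species in the alignment but absent from the model tree are dropped
    with a warning; tree tips absent from the alignment are treated as
    all-missing.  Raises if no species is shared or the alignment has
    zero columns.
    """
    engine = LikelihoodEngine(alignment, model, collapse=collapse)
    return engine.loglik(scaling.rho, scaling.lam, fg)
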