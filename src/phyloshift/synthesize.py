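"""Forward simulation under the neutral model, with optional rate shifts.

The simulator is the likelihood's generative process run forward: the
root state is drawn from pi, each branch evolves the child from the
parent through exp(Q * b * rho [* lam on foreground branches]), and
cells are masked to missing i.i.d. with a given probability.  This
mirrors the inference parameterization exactly, so parameter-recovery
tests are clean.  Missingness is i.i.d. per cell, not indel-shaped.

``make_fixture`` writes small self-contained datasets (.mod + FASTA +
BED + foreground list) that the CLI can run end-to-end.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import Region, write_phast_mod
from .likelihood import MISSING, Alignment, ForegroundSpec, foreground_branches
from .substitution import NeutralModel, build_rev
from .tree import PhyloTree, read_newick

__all__ = ["SimSpec", "simulate_alignment", "make_fixture", "demo_model", "FIXTURES"]


@dataclass
class SimSpec:
    model: NeutralModel
    length: int
    fg: ForegroundSpec | None = None
    rho: float = 1.0
    lam: float = 1.0
    missing_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0 <= self.missing_frac < 1:
            raise ValueError("missing_frac must be in [0, 1)")
        if self.rho <= 0 or self.lam <= 0:
            raise ValueError("rho and lam must be positive")


def simulate_alignment(spec: SimSpec) -> Alignment:
    """Evolve an alignment down the model tree; deterministic given seed."""
    model, tree = spec.model, spec.model.tree
    if tree is None:
        raise ValueError("model has no tree")
    rng = np.random.default_rng(spec.seed)
    fg_branches = spec.fg.fg_branches if spec.fg is not None else frozenset()
    t_eff = tree.lengths * spec.rho
    for b in fg_branches:
        t_eff[b] *= spec.lam
    P = model.transition_matrices(t_eff)
    # cumulative transition rows for inverse-CDF sampling
    cum = np.cumsum(P, axis=2)
    states = np.empty((tree.n_nodes, spec.length), dtype=np.int8)
    states[tree.root] = rng.choice(4, size=spec.length, p=model.pi)
    for v in range(tree.n_nodes - 2, -1, -1):  # preorder below the root
        parent_states = states[tree.parent[v]]
        u = rng.random(spec.length)
        states[v] = (u[:, None] < cum[v][parent_states]).argmax(axis=1)
    data = states[tree.tip_ids].copy()
    if spec.missing_frac > 0:
        mask = rng.random(data.shape) < spec.missing_frac
        data[mask] = MISSING
    return Alignment([tree.names[int(v)] for v in tree.tip_ids], data)


# ---------------------------------------------------------------------------
# Canned fixtures


def demo_model(tree: PhyloTree) -> NeutralModel:
    """A mildly transition-biased reversible model with skewed frequencies."""
    m = build_rev([1.0, 3.0, 1.0, 1.0, 3.0, 1.0], [0.3, 0.2, 0.2, 0.3])
    return NeutralModel(m.Q, m.pi, tree)


_CHERRY4_NEWICK = "((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);"


def _toy24_newick() -> str:
    """A 24-tip tree with 4 foreground tips in 3 independent lineages:
    a sister pair (fg1, fg2) plus two singletons (fg3, fg4)."""
    def cherry(a: str, b: str, bl: float = 0.08) -> str:
        return f"({a}:{bl},{b}:{bl})"

    bg = [f"sp{i:02d}" for i in range(1, 21)]
    c1 = f"({cherry('fg1', 'fg2', 0.06)}:0.05,{cherry(bg[0], bg[1])}:0.05)"
    c2 = f"(fg3:0.12,{cherry(bg[2], bg[3])}:0.05)"
    c3 = f"(fg4:0.12,{cherry(bg[4], bg[5])}:0.05)"
    rest = [cherry(bg[i], bg[i + 1]) + ":0.05" for i in range(6, 20, 2)]
    left = f"(({c1}:0.04,{c2}:0.04):0.03,{c3}:0.06)"
    right = rest[0]
    for r in rest[1:]:
        right = f"({right},{r}):0.03"
    return f"({left}:0.04,{right}:0.04);"


FIXTURES = {"cherry4", "toy24"}


def make_fixture(name: str, out_dir: str | Path, seed: int = 17) -> Path:
    """Write a self-contained demo dataset; returns the directory path.

    cherry4 — 4 species ((A,B),(C,D)); foreground {A,B}; 3 elements of
        150 bp on a synthetic chromosome, the middle one evolved with a
        5x foreground acceleration.
    toy24 — 24 species with 4 foreground tips (a sister pair and two
        singletons); 21 elements of 200 bp, element 10 evolved with a
        5x foreground acceleration, the rest neutral.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name == "cherry4":
        newick, fg_tips = _CHERRY4_NEWICK, ["A", "B"]
        n_elements, el_len, planted = 3, 150, {1}
    elif name == "toy24":
        newick, fg_tips = _toy24_newick(), ["fg1", "fg2", "fg3", "fg4"]
        n_elements, el_len, planted = 21, 200, {10}
    else:
        raise ValueError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")

    tree = read_newick(newick)
    model = demo_model(tree)
    fg = foreground_branches(tree, fg_tips)
    chunks = []
    bed_lines = []
    for i in range(n_elements):
        lam = 5.0 if i in planted else 1.0
        spec = SimSpec(model, el_len, fg=fg, lam=lam, seed=seed * 10_000 + i)
        chunks.append(simulate_alignment(spec))
        bed_lines.append(f"chrS\t{i * el_len}\t{(i + 1) * el_len}\telement_{i}")
    species = chunks[0].species
    data = np.hstack([c.data for c in chunks])
    aln = Alignment(species, data)

    (out / f"{name}.mod").write_text(write_phast_mod(model))
    with open(out / f"{name}.fa", "w") as fh:
        for sp, seq in aln.to_strings().items():
            fh.write(f">{sp}\n{seq}\n")
    (out / f"{name}.bed").write_text("\n".join(bed_lines) + "\n")
    (out / f"{name}.fg.txt").write_text("\n".join(fg_tips) + "\n")
    return out


def read_foregrounds(source: str | Path) -> list[str]:
    """Plain-text foreground species list, one tip name per line."""
    names = [
        line.strip()
        for line in Path(source).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if not names:
        raise ValueError(f"no foreground species in {source}")
    return names
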