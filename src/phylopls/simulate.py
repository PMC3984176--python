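"""Random trees, multivariate Brownian motion, and the rejection-rate study.

The study design mirrors the standard calibration exercise for an
integration test: for each cell of a grid over the number of taxa N, the
total trait dimension p (split equally into two blocks), and the
between-block input covariance b, repeatedly (1) generate a random
pure-birth phylogeny, (2) build an input covariance matrix with unit
variances and covariance b between paired dimensions of the two blocks,
(3) simulate Brownian traits on the tree, then run the phylogenetic PLS
permutation test and record the rejection proportion at level alpha.
With b = 0 that proportion estimates the Type I error rate; with b > 0 it
estimates power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pls import phylo_pls
from .tree import (
    BlockSpec,
    PhyloError,
    PhyloTree,
    TraitMatrix,
    read_newick,
    tree_to_C,
)

__all__ = [
    "InputCovariance",
    "SimulationConfig",
    "RejectionTable",
    "random_tree",
    "build_input_cov",
    "simulate_bm",
    "run_study",
    "plot_power_curves",
]


@dataclass(frozen=True)
class InputCovariance:
    """The p x p covariance used to generate traits.

    Diagonal entries are all ``sigma2`` (isotropic rates); every
    off-diagonal entry is ``b * sigma2`` (equicorrelation), so b is the
    common covariation among all trait dimensions — in particular between
    the two blocks — and b = 0 gives fully independent dimensions.
    """

    Sigma: np.ndarray
    sigma2: float
    b: float
    structure: str = "equicorrelated"

    @property
    def p(self) -> int:
        return self.Sigma.shape[0]


def build_input_cov(p: int, b: float, sigma2: float = 1.0) -> InputCovariance:
    """Equicorrelated input covariance: unit diagonal, b off-diagonal.

    Eigenvalues are ``sigma2 * (1 + (p-1) b)`` (once, for the equal-weights
    direction) and ``sigma2 * (1 - b)`` (p-1 times), so the matrix is
    positive definite for all 0 <= b < 1 regardless of p.  Concentrating
    the shared covariation on a single direction means the cross-block
    signal grows with dimensionality, which is what lets the integration
    test gain rather than lose power as p increases.
    """
    if p < 2 or p % 2:
        raise PhyloError(f"p must be even and >= 2, got {p}")
    if not 0.0 <= b < 1.0:
        raise PhyloError(
            f"between-block covariance must satisfy 0 <= b < 1 "
            f"(positive definiteness), got {b}"
        )
    if sigma2 <= 0:
        raise PhyloError("sigma2 must be positive")
    Sigma = np.full((p, p), b * sigma2)
    np.fill_diagonal(Sigma, sigma2)
    return InputCovariance(Sigma=Sigma, sigma2=sigma2, b=b)


def random_tree(n_tips: int, seed: int) -> PhyloTree:
    """Pure-birth (Yule) bifurcating tree rescaled to unit root-to-tip depth.

    Lineages split at unit rate; after the last split the process runs for
    one more exponential waiting time so terminal sister branches have
    positive length.  All tips end at the same time (ultrametric) and all
    branch lengths are divided by the total depth, so every tree has
    root-to-tip depth exactly 1.  Deterministic per seed.
    """
    if n_tips < 3:
        raise PhyloError(f"need at least 3 tips, got {n_tips}")
    rng = np.random.default_rng(seed)

    # nodes as dicts: children (pair of node ids), birth time of the split
    split_time: dict[int, float] = {}
    children: dict[int, tuple[int, int]] = {}
    next_id = 0

    def new_node() -> int:
        nonlocal next_id
        next_id += 1
        return next_id - 1

    root = new_node()
    split_time[root] = 0.0
    a, b_ = new_node(), new_node()
    children[root] = (a, b_)
    active = [a, b_]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node = active.pop(i)
        split_time[node] = t
        c1, c2 = new_node(), new_node()
        children[node] = (c1, c2)
        active.extend([c1, c2])
    t_end = t + rng.exponential(1.0 / n_tips)

    labels = {node: f"t{i + 1:03d}" for i, node in enumerate(sorted(active))}

    def newick(node: int, parent_time: float) -> str:
        if node in children:
            left, right = children[node]
            sub = f"({newick(left, split_time[node])},{newick(right, split_time[node])})"
            length = (split_time[node] - parent_time) / t_end
            return sub if node == root else f"{sub}:{length!r}"
        length = (t_end - parent_time) / t_end
        return f"{labels[node]}:{length!r}"

    return read_newick(newick(root, 0.0) + ";")


def simulate_bm(
    tree: PhyloTree,
    cov: InputCovariance | np.ndarray,
    seed: int,
    root_state: np.ndarray | None = None,
) -> TraitMatrix:
    """Simulate multivariate Brownian traits on a tree.

    ``Y = L_C Z L_Sigma' + 1 a'`` with L_C, L_Sigma Cholesky factors of the
    phylogenetic covariance C and the trait covariance Sigma, Z i.i.d.
    standard normal, and root state a (zero by default) — the joint matrix
    normal implied by Brownian motion on the tree.  Rows follow the sorted
    tip order.
    """
    Sigma = cov.Sigma if isinstance(cov, InputCovariance) else np.asarray(cov, float)
    order = tuple(sorted(tree.tip_labels))
    C = tree_to_C(tree, order).C
    try:
        L_C = np.linalg.cholesky(C)
        L_S = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise PhyloError(f"covariance not positive definite: {exc}") from exc
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((C.shape[0], Sigma.shape[0]))
    Y = L_C @ Z @ L_S.T
    if root_state is not None:
        Y = Y + np.asarray(root_state, dtype=float)
    return TraitMatrix(
        values=Y,
        row_labels=order,
        col_labels=tuple(f"x{j + 1}" for j in range(Sigma.shape[0])),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Grid and budget for the Type I error / power study."""

    N_values: tuple[int, ...] = (16, 32, 64, 128)
    p_values: tuple[int, ...] = (6, 8, 10, 16, 20, 30)
    b_values: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1))
    n_datasets: int = 1000
    n_permutations: int = 199
    alpha: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise PhyloError("alpha must be in (0, 1)")
        if self.n_datasets < 1:
            raise PhyloError("n_datasets must be >= 1")
        for p in self.p_values:
            if p % 2:
                raise PhyloError(f"p must be even for an equal block split: {p}")
        for b in self.b_values:
            if not 0.0 <= b < 1.0:
                raise PhyloError(f"b out of range [0, 1): {b}")


@dataclass(frozen=True)
class RejectionTable:
    """Rejection proportions per (N, p, b) cell with Monte-Carlo errors."""

    table: pd.DataFrame

    def write(self, path: str, delimiter: str = "\t") -> None:
        self.table.to_csv(path, sep=delimiter, index=False)

    def rate(self, N: int, p: int, b: float) -> float:
        t = self.table
        row = t[(t.N == N) & (t.p == p) & (np.isclose(t.b, b))]
        if row.empty:
            raise KeyError(f"no cell (N={N}, p={p}, b={b})")
        return float(row.rejection_rate.iloc[0])


_SEED_CAP = 2**31 - 1


def run_study(config: SimulationConfig, progress: bool = False) -> RejectionTable:
    """Run the full rejection-rate study over the configured grid.

    Every dataset gets a fresh random tree; per-dataset tree, data and
    permutation seeds are drawn from one deterministic stream per cell, so
    the whole study reproduces bit-identically from ``config.seed``.
    Per-dataset failures (degenerate draws) are counted, never silently
    dropped.
    """
    rows = []
    for iN, N in enumerate(config.N_values):
        for ip, p in enumerate(config.p_values):
            blocks = BlockSpec.halves(p)
            for ib, b in enumerate(config.b_values):
                cell_rng = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=config.seed, spawn_key=(iN, ip, ib)
                    )
                )
                rejections = 0
                failures = 0
                for _ in range(config.n_datasets):
                    tree_seed, data_seed, perm_seed = cell_rng.integers(
                        _SEED_CAP, size=3
                    )
                    try:
                        tree = random_tree(N, int(tree_seed))
                        traits = simulate_bm(
                            tree, build_input_cov(p, b), int(data_seed)
                        )
                        res = phylo_pls(
                            traits,
                            tree,
                            blocks,
                            n_permutations=config.n_permutations,
                            seed=int(perm_seed),
                        )
                    except PhyloError:
                        failures += 1
                        continue
                    rejections += res.p_value <= config.alpha
                n_ok = config.n_datasets - failures
                rate = rejections / n_ok if n_ok else np.nan
                rows.append(
                    {
                        "N": N,
                        "p": p,
                        "b": b,
                        "rejection_rate": rate,
                        "n_datasets": n_ok,
                        "mc_stderr": np.sqrt(rate * (1 - rate) / n_ok)
                        if n_ok
                        else np.nan,
                        "n_failed": failures,
                    }
                )
                if progress:
                    print(
                        f"N={N} p={p} b={b:.1f}: rate={rate:.3f} "
                        f"({n_ok} datasets)",
                        flush=True,
                    )
    return RejectionTable(table=pd.DataFrame(rows))


def plot_power_curves(table: RejectionTable, path: str) -> None:
    """One panel per N: rejection rate vs b, one curve per p."""
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    t = table.table
    Ns = sorted(t.N.unique())
    fig = Figure(figsize=(4 * len(Ns), 3.5))
    axes = fig.subplots(1, len(Ns), squeeze=False)[0]
    for ax, N in zip(axes, Ns):
        sub = t[t.N == N]
        for p in sorted(sub.p.unique()):
            cell = sub[sub.p == p].sort_values("b")
            ax.plot(cell.b, cell.rejection_rate, marker="o", label=f"p={p}")
        ax.axhline(0.05, color="gray", lw=0.8, ls="--")
        ax.set_ylim(0, 1.02)
        ax.set_xlabel("between-block covariance b")
        ax.set_title(f"N = {N}")
        ax.legend(fontsize=8)
    axes[0].set_ylabel("rejection rate")
    fig.tight_layout()
    FigureCanvasAgg(fig).print_figure(path, dpi=150)
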