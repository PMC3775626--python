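"""Deterministic generators for toy trees and two-state community tables.

The two-state generator produces a "dominated" state L (one leaf carries most
of the Dirichlet weight, so diversity is low) and an "even" state H
(symmetric Dirichlet), with multinomial sequencing noise and per-sample read
depths drawn from a range — a minimal stand-in for dysbiosis-style datasets
where one state is markedly more diverse than the other.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .data_model import CountTable, PhyloTree, SampleCounts, read_newick

__all__ = ["SimParams", "toy_tree_T0", "random_tree", "simulate_two_state", "write_fixture"]

T0_NEWICK = "((A:1.0,B:1.0):1.0,C:1.0);"


@dataclass
class SimParams:
    """Parameters of the two-state community generator."""

    n_leaves: int = 64
    n_samples: int = 50  # per state
    alpha_dom: float = 10.0
    alpha_bg: float = 0.1
    depth_min: int = 500
    depth_max: int = 2500
    seed: int = 0
    fixed_dominant: bool = False
    score_means: tuple[float, float] = (2.0, 7.0)  # (state L, state H)
    score_sd: float = 1.5

    def validate(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not (self.alpha_dom >= self.alpha_bg > 0):
            raise ValueError("need alpha_dom >= alpha_bg > 0")
        if not (1 <= self.depth_min <= self.depth_max):
            raise ValueError("need 1 <= depth_min <= depth_max")


def toy_tree_T0() -> tuple[PhyloTree, SampleCounts]:
    """The canonical worked example: ((A:1,B:1):1,C:1) with counts {A:2,B:1,C:1}."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tree = read_newick(T0_NEWICK)
    return tree, SampleCounts({"A": 2, "B": 1, "C": 1}, name="S1")


def random_tree(n_leaves: int, seed: int = 0) -> PhyloTree:
    """Random rooted binary tree: uniformly random sequential pairwise joins
    with exponential(mean 1) branch lengths; leaves labeled L0001, L0002, ...
    Deterministic for a given seed."""
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    rng = np.random.default_rng(seed)
    subtrees = [f"L{i + 1:04d}" for i in range(n_leaves)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        li, lj = rng.exponential(1.0, size=2)
        merged = f"({subtrees[i]}:{li:.10g},{subtrees[j]}:{lj:.10g})"
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)] + [merged]
    return read_newick(subtrees[0] + ";")


def simulate_two_state(tree: PhyloTree, params: SimParams) -> tuple[CountTable, pd.DataFrame]:
    """Draw a two-state count table plus metadata from the generator.

    Returns ``(table, metadata)`` where metadata has columns ``state``
    (L = dominated, H = even), ``stratum`` (two arbitrary sites, for the
    ANOVA path) and a continuous ``score`` emulating a clinical gradient
    (state-dependent Gaussian, clipped to [0, 10]).
    """
    params.validate()
    leaves = tree.tip_labels
    if len(leaves) != params.n_leaves:
        raise ValueError(f"tree has {len(leaves)} leaves but params.n_leaves={params.n_leaves}")
    rng = np.random.default_rng(params.seed)
    cols: dict[str, np.ndarray] = {}
    meta = []
    fixed_dom = int(rng.integers(len(leaves))) if params.fixed_dominant else None
    for state, mean_score in zip(("L", "H"), params.score_means):
        for i in range(params.n_samples):
            sid = f"{state}{i + 1:03d}"
            if state == "L":
                alphas = np.full(len(leaves), params.alpha_bg)
                dom = fixed_dom if fixed_dom is not None else int(rng.integers(len(leaves)))
                alphas[dom] = params.alpha_dom
            else:
                alphas = np.ones(len(leaves))
            p = rng.dirichlet(alphas)
            depth = int(rng.integers(params.depth_min, params.depth_max + 1))
            cols[sid] = rng.multinomial(depth, p)
            score = float(np.clip(rng.normal(mean_score, params.score_sd), 0.0, 10.0))
            meta.append(
                {"sample_id": sid, "state": state,
                 "stratum": f"site{int(rng.integers(2)) + 1}", "score": score}
            )
    table = CountTable(pd.DataFrame(cols, index=leaves))
    metadata = pd.DataFrame(meta).set_index("sample_id")
    return table, metadata


def write_fixture(outdir, tree: PhyloTree, table: CountTable, metadata: pd.DataFrame, params: SimParams) -> None:
    """Write tree.nwk, table.tsv, metadata.tsv and a params sidecar to a directory."""
    import os

    from .data_model import write_newick

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(write_newick(tree) + "\n")
    table.to_tsv(os.path.join(outdir, "table.tsv"))
    metadata.to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t")
    with open(os.path.join(outdir, "params.json"), "w") as fh:
        json.dump(asdict(params), fh, indent=2)
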