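"""Phylogenetic alpha-diversity measures.

All measures are sums over tree edges of the edge length times a function of
the distal read fraction x = D_s(i):

* ``pd_unrooted``      — step weight g(x) = 1 on (0,1), 0 at the boundary
* ``bwpd``             — g_theta(x) = [2 min(x, 1-x)]**theta, the
                         one-parameter bridge from PD (theta=0) to fully
                         balance-weighted PD (theta=1)
* ``rbwpd``            — rooted variant, weight x**theta
* ``pqe``              — quadratic entropy, weight x(1-x)
* ``phylo_entropy``    — weight -x ln x (rooted)
* ``hill_qdt``         — order-q effective-diversity transform (rooted)

``pd_unrooted``, ``bwpd`` and ``pqe`` are invariant to the choice of root;
``rbwpd``, ``phylo_entropy`` and ``hill_qdt`` are not, and expect the caller
to have fixed a meaningful root.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from . import discrete_alpha
from .data_model import CountTable, EdgeMassVector, PhyloTree, SampleCounts, compute_edge_masses

__all__ = [
    "g_theta",
    "pd_unrooted",
    "bwpd",
    "rbwpd",
    "pqe",
    "phylo_entropy",
    "hill_qdt",
    "resolve_measure",
    "compute_measure_matrix",
    "DEFAULT_MEASURES",
]

THETA_GRID = (0.0, 0.25, 0.5, 1.0)
Q_GRID = (0.0, 0.25, 0.5)

DEFAULT_MEASURES = (
    ["pd_u"]
    + [f"bwpd_{t:g}" for t in THETA_GRID if t > 0]
    + ["pqe", "phylo_entropy"]
    + [f"qdt_{q:g}" for q in Q_GRID]
)


def g_theta(x, theta: float):
    """Balance weight [2*min(x, 1-x)]**theta on [0, 1].

    theta = 0 returns the pointwise limit: the step function that is 1 on the
    open interval and 0 at both endpoints (0**theta := 0 for theta > 0).
    """
    if theta < 0 or not np.isfinite(theta):
        raise ValueError(f"theta must be finite and >= 0, got {theta}")
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("x must lie in [0, 1]")
    base = 2.0 * np.minimum(arr, 1.0 - arr)
    if theta == 0:
        out = (base > 0).astype(float)
    else:
        out = base**theta
    return out if isinstance(x, np.ndarray) else float(out)


def _masses(tree: PhyloTree, sample) -> EdgeMassVector:
    if isinstance(sample, EdgeMassVector):
        return sample
    return compute_edge_masses(tree, sample)


def pd_unrooted(tree: PhyloTree, sample) -> float:
    """Unrooted phylogenetic diversity: total length of edges with reads on
    both the distal and proximal side."""
    em = _masses(tree, sample)
    d = em.edge_counts()
    ell = em.edge_lengths()
    return float(ell[(d > 0) & (d < em.n)].sum())


def bwpd(tree: PhyloTree, sample, theta: float) -> float:
    """Balance-weighted phylogenetic diversity of order theta."""
    em = _masses(tree, sample)
    if theta == 0:
        # the pointwise-limit convention makes theta = 0 reproduce PD exactly
        return pd_unrooted(tree, em)
    x = em.edge_fractions()
    return float(np.sum(em.edge_lengths() * g_theta(x, theta)))


def rbwpd(tree: PhyloTree, sample, theta: float) -> float:
    """Rooted abundance-weighted PD: sum of l_i * D_s(i)**theta (0**theta := 0)."""
    if theta < 0 or not np.isfinite(theta):
        raise ValueError(f"theta must be finite and >= 0, got {theta}")
    em = _masses(tree, sample)
    x = em.edge_fractions()
    ell = em.edge_lengths()
    mask = x > 0
    return float(np.sum(ell[mask] * x[mask] ** theta))


def pqe(tree: PhyloTree, sample) -> float:
    """Phylogenetic quadratic entropy: (1/n^2) * sum l_i * d_i * (n - d_i).

    Accumulated with integer d_i so the numerator is exact.
    """
    em = _masses(tree, sample)
    d = em.edge_counts().astype(np.int64)
    n = em.n
    return float(np.sum(em.edge_lengths() * (d * (n - d))) / (n * n))


def phylo_entropy(tree: PhyloTree, sample, base: float | None = None) -> float:
    """Phylogenetic entropy: -sum l_i * p_i * log p_i with p_i the rooted
    distal fraction; 0 log 0 := 0. Natural log by default."""
    em = _masses(tree, sample)
    x = em.edge_fractions()
    ell = em.edge_lengths()
    mask = x > 0
    h = -np.sum(ell[mask] * x[mask] * np.log(x[mask]))
    if base is not None:
        h /= np.log(base)
    return float(h)


def hill_qdt(tree: PhyloTree, sample, q: float, scaled: bool = False) -> float:
    """Order-q phylogenetic Hill diversity (mean-diversity form).

    With branch abundances a_i = rooted distal fractions and
    Tbar = sum l_i a_i:

      q != 1:  [ sum_{a_i>0} (l_i/Tbar) a_i**q ] ** (1/(1-q))
      q == 1:  exp( -sum (l_i/Tbar) a_i ln a_i )

    ``scaled=True`` returns the product Tbar * value instead of the
    effective-number form.
    """
    if q < 0 or not np.isfinite(q):
        raise ValueError(f"q must be finite and >= 0, got {q}")
    em = _masses(tree, sample)
    a = em.edge_fractions()
    ell = em.edge_lengths()
    mask = a > 0
    a, ell = a[mask], ell[mask]
    tbar = float(np.sum(ell * a))
    if tbar <= 0:
        raise ValueError("all read mass sits on zero-length edges (Tbar = 0)")
    if q == 1.0:
        val = float(np.exp(-np.sum((ell / tbar) * a * np.log(a))))
    else:
        val = float(np.sum((ell / tbar) * a**q) ** (1.0 / (1.0 - q)))
    return tbar * val if scaled else val


# -- measure registry ---------------------------------------------------------


def resolve_measure(measure_id: str):
    """Map a measure id like ``bwpd_0.25`` or ``shannon`` to a callable
    ``f(tree, sample) -> float``. Discrete measures ignore the tree."""
    mid = measure_id.strip()
    if mid == "pd_u":
        return pd_unrooted
    if mid == "pqe":
        return pqe
    if mid == "phylo_entropy":
        return phylo_entropy
    for prefix, fn in (("bwpd_", bwpd), ("rbwpd_", rbwpd), ("qdt_", hill_qdt)):
        if mid.startswith(prefix):
            try:
                param = float(mid[len(prefix):])
            except ValueError:
                raise ValueError(f"bad parameter in measure id {measure_id!r}") from None
            return lambda tree, sample, _fn=fn, _p=param: _fn(tree, sample, _p)
    discrete = {
        "shannon": discrete_alpha.shannon,
        "simpson": discrete_alpha.simpson_gini,
        "chao1": discrete_alpha.chao1,
        "ace": discrete_alpha.ace,
    }
    if mid in discrete:
        return lambda tree, sample, _fn=discrete[mid]: _fn(_counts_of(sample))
    raise ValueError(f"unknown measure id {measure_id!r}")


def _counts_of(sample) -> np.ndarray:
    if isinstance(sample, SampleCounts):
        return np.array(list(sample.counts.values()), dtype=np.int64)
    if isinstance(sample, Mapping):
        return np.array(list(sample.values()), dtype=np.int64)
    return np.asarray(sample, dtype=np.int64)


def compute_measure_matrix(
    tree: PhyloTree | None,
    table: CountTable,
    measures: list[str] | None = None,
) -> pd.DataFrame:
    """Evaluate measures for every sample; rows = samples, columns = measures.

    Edge masses are computed once per sample and shared across the
    phylogenetic measures.
    """
    measures = list(measures) if measures is not None else list(DEFAULT_MEASURES)
    fns = {m: resolve_measure(m) for m in measures}
    rows = {}
    for sample in table.samples():
        em = compute_edge_masses(tree, sample) if tree is not None else None
        vals = {}
        for m, fn in fns.items():
            arg = sample if _is_discrete(m) or em is None else em
            vals[m] = fn(tree, arg)
        rows[sample.name] = vals
    out = pd.DataFrame.from_dict(rows, orient="index", columns=measures)
    out.index.name = "sample"
    return out


def _is_discrete(measure_id: str) -> bool:
    return measure_id in {"shannon", "simpson", "chao1", "ace"}
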