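"""Rarefaction: subsampling without replacement and its expectations.

Rarefying a sample to depth k draws k of its n reads uniformly without
replacement, i.e. the rarefied leaf counts follow a multivariate
hypergeometric distribution. The closed form

    E[PQE_k] = (k-1) / (k n (n-1)) * sum_i l_i d_i (n - d_i)

gives the exact expectation of phylogenetic quadratic entropy under that
model; no such closed form is provided for the balance-weighted family, for
which only Monte Carlo estimation is available here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CountTable, PhyloTree, SampleCounts, compute_edge_masses
from .phylo_alpha import resolve_measure

__all__ = [
    "RarefactionPlan",
    "SensitivityReport",
    "rarefy_counts",
    "rarefy_table",
    "mean_rarefied_measure",
    "expected_pqe_rarefied",
    "sensitivity_experiment",
]


@dataclass
class RarefactionPlan:
    """Target depth k, replicate count R, and base seed."""

    k: int
    R: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("rarefaction depth k must be >= 1")
        if self.R < 1:
            raise ValueError("replicate count R must be >= 1")

    def replicate_rng(self, replicate: int) -> np.random.Generator:
        """Deterministic, order-independent per-replicate generator."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, replicate]))


@dataclass
class SensitivityReport:
    """Full vs rarefied values per (sample, measure), plus per-measure MARD."""

    per_sample: pd.DataFrame  # columns: sample, measure, full, rarefied, abs_dev, rel_dev
    summary: pd.DataFrame  # index: measure; columns: mard, n_samples, n_excluded
    k: int
    seed: int

    def mard(self, measure: str) -> float:
        return float(self.summary.loc[measure, "mard"])

    def write_tsv(self, per_sample_path, summary_path) -> None:
        self.per_sample.to_csv(per_sample_path, sep="\t", index=False)
        self.summary.to_csv(summary_path, sep="\t", index_label="measure")


def rarefy_counts(sample: SampleCounts, k: int, seed: int | np.random.Generator = 0) -> SampleCounts:
    """Draw k reads without replacement (multivariate hypergeometric)."""
    n = sample.n
    if not (1 <= k <= n):
        raise ValueError(f"rarefaction depth k={k} outside [1, n={n}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = list(sample.counts)
    colors = np.array([sample.counts[lab] for lab in labels], dtype=np.int64)
    draw = rng.multivariate_hypergeometric(colors, k)
    return SampleCounts(dict(zip(labels, draw.tolist())), name=sample.name)


def rarefy_table(
    table: CountTable,
    k: int,
    seed: int = 0,
    policy: str = "skip",
) -> CountTable:
    """Rarefy every sample of a table to depth k.

    Samples shallower than k are dropped with a warning (``policy='skip'``)
    or raise (``policy='error'``). Each sample gets its own deterministic
    substream of ``seed``.
    """
    cols = {}
    for idx, sample in enumerate(table.samples()):
        if sample.n < k:
            if policy == "error":
                raise ValueError(f"sample {sample.name!r} has {sample.n} < k={k} reads")
            warnings.warn(f"skipping sample {sample.name!r}: {sample.n} < k={k}", UserWarning)
            continue
        rng = np.random.default_rng(np.random.SeedSequence([seed, idx]))
        cols[sample.name] = rarefy_counts(sample, k, rng).counts
    if not cols:
        raise ValueError("no sample is deep enough to rarefy")
    df = pd.DataFrame(cols, index=table.leaf_labels).fillna(0)
    return CountTable(df)


def mean_rarefied_measure(
    tree: PhyloTree | None,
    sample: SampleCounts,
    measure: str,
    plan: RarefactionPlan,
) -> float:
    """Mean of a measure over R independent rarefactions to depth k."""
    if plan.k > sample.n:
        raise ValueError(f"rarefaction depth k={plan.k} exceeds sample total n={sample.n}")
    fn = resolve_measure(measure)
    total = 0.0
    for r in range(plan.R):
        sub = rarefy_counts(sample, plan.k, plan.replicate_rng(r))
        total += fn(tree, sub)
    return total / plan.R


def expected_pqe_rarefied(tree: PhyloTree, sample: SampleCounts, k: int) -> float:
    """Exact expectation of phylogenetic quadratic entropy after rarefying
    to k reads: (k-1)/(k n (n-1)) * sum_i l_i d_i (n - d_i)."""
    em = compute_edge_masses(tree, sample)
    n = em.n
    if n < 2:
        raise ValueError("expectation undefined for n < 2")
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, n={n}]")
    d = em.edge_counts().astype(np.int64)
    q = float(np.sum(em.edge_lengths() * (d * (n - d))) / (n * n))
    # identical to (k-1)/(k n (n-1)) * sum l_i d_i (n-d_i); this form makes
    # k = n recover the unrarefied value bit-exactly
    return q * (((k - 1) * n) / (k * (n - 1)))


def sensitivity_experiment(
    tree: PhyloTree | None,
    table: CountTable,
    measures: list[str],
    k: int,
    seed: int = 0,
    replicates: int = 1,
) -> SensitivityReport:
    """Full-data vs rarefied measure values across a table.

    Each sample is rarefied to depth k (a single rarefaction by default, or
    the mean over ``replicates``); per-measure MARD is the mean over samples
    of |rarefied - full| / full, excluding (and counting) samples whose full
    value is 0. Samples shallower than k are skipped with a warning.
    """
    fns = {m: resolve_measure(m) for m in measures}
    records = []
    for sample in table.samples():
        if sample.n < k:
            warnings.warn(f"skipping sample {sample.name!r}: {sample.n} < k={k}", UserWarning)
            continue
        plan = RarefactionPlan(k=k, R=replicates, seed=seed)
        full_vals = {m: fn(tree, sample) for m, fn in fns.items()}
        rare_vals = {m: mean_rarefied_measure(tree, sample, m, plan) for m in measures}
        for m in measures:
            full, rare = full_vals[m], rare_vals[m]
            abs_dev = abs(rare - full)
            rel_dev = abs_dev / full if full != 0 else np.nan
            records.append(
                {"sample": sample.name, "measure": m, "full": full, "rarefied": rare,
                 "abs_dev": abs_dev, "rel_dev": rel_dev}
            )
    per_sample = pd.DataFrame.from_records(records)
    rows = {}
    for m in measures:
        sub = per_sample[per_sample["measure"] == m]
        ok = sub["rel_dev"].dropna()
        rows[m] = {"mard": float(ok.mean()) if len(ok) else np.nan,
                   "n_samples": int(len(ok)), "n_excluded": int(sub["rel_dev"].isna().sum())}
    summary = pd.DataFrame.from_dict(rows, orient="index")
    return SensitivityReport(per_sample=per_sample, summary=summary, k=k, seed=seed)
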