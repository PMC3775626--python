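"""Independent brute-force oracles.

Everything here recomputes quantities from first principles — explicit
leaf-set enumeration per edge, exhaustive subset enumeration for rarefaction
expectations, naive O(M^3) agglomeration for clustering — sharing no
traversal or formula code with the package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def distal_leaf_labels(tree, v: int) -> set[str]:
    """Labels of tips in the subtree below node v, by explicit BFS."""
    out = set()
    queue = [v]
    tips = set(tree.tip_ids())
    while queue:
        w = queue.pop()
        if w in tips and tree.labels[w] is not None:
            out.add(tree.labels[w])
        queue.extend(tree.children[w])
    return out


def brute_edge_masses(tree, counts: dict[str, int]) -> dict[int, int]:
    """d_i per edge by summing counts over the explicitly enumerated distal leaf set."""
    return {
        int(v): sum(counts.get(lab, 0) for lab in distal_leaf_labels(tree, v))
        for v in tree.edge_ids()
    }


def _edges(tree, counts):
    n = sum(counts.values())
    d = brute_edge_masses(tree, counts)
    return [(float(tree.length[v]), d[v]) for v in tree.edge_ids()], n


def brute_pd_u(tree, counts) -> float:
    edges, n = _edges(tree, counts)
    return sum(l for l, d in edges if 0 < d < n)


def brute_bwpd(tree, counts, theta: float) -> float:
    edges, n = _edges(tree, counts)
    total = 0.0
    for l, d in edges:
        x = d / n
        m = 2.0 * min(x, 1.0 - x)
        if theta == 0:
            w = 1.0 if m > 0 else 0.0
        else:
            w = m**theta
        total += l * w
    return total


def brute_rbwpd(tree, counts, theta: float) -> float:
    edges, n = _edges(tree, counts)
    return sum(l * (d / n) ** theta for l, d in edges if d > 0)


def brute_pqe(tree, counts) -> float:
    edges, n = _edges(tree, counts)
    return sum(l * d * (n - d) for l, d in edges) / (n * n)


def brute_phylo_entropy(tree, counts) -> float:
    edges, n = _edges(tree, counts)
    return -sum(l * (d / n) * math.log(d / n) for l, d in edges if d > 0)


def brute_hill(tree, counts, q: float) -> float:
    edges, n = _edges(tree, counts)
    active = [(l, d / n) for l, d in edges if d > 0]
    tbar = sum(l * a for l, a in active)
    if q == 1.0:
        return math.exp(-sum((l / tbar) * a * math.log(a) for l, a in active))
    return sum((l / tbar) * a**q for l, a in active) ** (1.0 / (1.0 - q))


def enumerate_expected_pqe(tree, counts: dict[str, int], k: int) -> float:
    """Mean PQE over every k-subset of the sample's individual reads."""
    reads = [lab for lab, c in counts.items() for _ in range(c)]
    vals = []
    for combo in itertools.combinations(range(len(reads)), k):
        sub: dict[str, int] = {}
        for idx in combo:
            sub[reads[idx]] = sub.get(reads[idx], 0) + 1
        vals.append(brute_pqe(tree, sub))
    return sum(vals) / len(vals)


def naive_complete_linkage(dist: np.ndarray, labels: list[str]):
    """O(M^3) agglomeration; returns [(frozenset_a, frozenset_b, height), ...]."""
    clusters: dict[int, frozenset] = {i: frozenset([lab]) for i, lab in enumerate(labels)}
    d = {
        (i, j): float(dist[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    merges = []
    next_id = len(labels)
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: kv[1])
        merges.append((clusters[i], clusters[j], h))
        merged = clusters[i] | clusters[j]
        del clusters[i], clusters[j]
        newd = {}
        for (a, b), v in d.items():
            if a in (i, j) or b in (i, j):
                continue
            newd[(a, b)] = v
        for c in clusters:
            pairs = []
            for other in (i, j):
                key = (min(c, other), max(c, other))
                pairs.append(d[key])
            newd[(min(c, next_id), max(c, next_id))] = max(pairs)  # complete linkage
        clusters[next_id] = merged
        next_id += 1
        d = newd
    return merges


def welch_pvalue_by_formula(a, b) -> float:
    """Textbook Welch t-test transcription (statistic + Welch-Satterthwaite df)."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(2 * tdist.sf(abs(t), df))


def anova_pvalue_by_formula(groups) -> float:
    """One-way fixed-effects F-test from the raw sums of squares."""
    from scipy.stats import f as fdist

    groups = [np.asarray(g, float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(fdist.sf(F, df_b, df_w))


def hill_number(p: np.ndarray, q: float) -> float:
    """Classical Hill number of a proportion vector."""
    p = p[p > 0]
    if q == 1.0:
        return math.exp(-(p * np.log(p)).sum())
    return float((p**q).sum() ** (1.0 / (1.0 - q)))
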