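"""Discrete (non-phylogenetic) diversity and richness measures.

Operate on plain abundance vectors of non-negative integer counts. Variant
choices mirror the defaults of the standard R implementations: Gini-Simpson
for ``simpson``, bias-corrected Chao1, ACE with rare-category cutoff 10.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["shannon", "simpson_gini", "chao1", "ace", "abundance_stats"]


def _clean(v) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValueError("empty abundance vector")
    if np.any(arr != np.floor(arr)) or np.any(arr < 0):
        raise ValueError("abundances must be non-negative integers")
    arr = arr.astype(np.int64)
    if arr.sum() < 1:
        raise ValueError("abundance vector has zero total count")
    return arr


def abundance_stats(v) -> dict:
    """Summary quantities: n, S_obs, and the frequency-of-frequencies f_k."""
    arr = _clean(v)
    pos = arr[arr > 0]
    ks, fs = np.unique(pos, return_counts=True)
    return {"n": int(arr.sum()), "s_obs": int(pos.size), "f": dict(zip(ks.tolist(), fs.tolist()))}


def shannon(v) -> float:
    """Shannon entropy of the count proportions, natural log, 0 ln 0 := 0."""
    arr = _clean(v)
    p = arr[arr > 0] / arr.sum()
    return float(-(p * np.log(p)).sum())


def simpson_gini(v, inverse: bool = False) -> float:
    """Gini-Simpson index 1 - sum p^2 (or inverse Simpson 1/sum p^2)."""
    arr = _clean(v)
    p = arr[arr > 0] / arr.sum()
    ss = float((p * p).sum())
    return 1.0 / ss if inverse else 1.0 - ss


def chao1(v, bias_corrected: bool = True) -> float:
    """Chao1 richness: S_obs + f1(f1-1)/(2(f2+1)), or classic S_obs + f1^2/(2 f2)."""
    st = abundance_stats(v)
    f1 = st["f"].get(1, 0)
    f2 = st["f"].get(2, 0)
    if bias_corrected:
        return st["s_obs"] + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f1 > 0 and f2 == 0:
        # classic estimator is undefined at f2 = 0; use the bias-corrected
        # limit as the conventional fallback
        return st["s_obs"] + f1 * (f1 - 1) / 2.0
    if f2 == 0:
        return float(st["s_obs"])
    return st["s_obs"] + f1 * f1 / (2.0 * f2)


def ace(v, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator.

    S_abund + S_rare/C + (f1/C) * gamma^2, with C = 1 - f1/N_rare and the
    squared coefficient of variation gamma^2 floored at 0. Falls back to
    Chao1 (with a warning) when the sample coverage C is 0, i.e. when every
    rare category is a singleton.
    """
    arr = _clean(v)
    pos = arr[arr > 0]
    rare = pos[pos <= rare_threshold]
    s_abund = int((pos > rare_threshold).sum())
    s_rare = int(rare.size)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        warnings.warn("ACE undefined (all rare categories are singletons); falling back to Chao1", UserWarning)
        return chao1(arr)
    ks = np.arange(1, rare_threshold + 1)
    fk = np.array([(rare == k).sum() for k in ks])
    top = float((ks * (ks - 1) * fk).sum())
    gamma2 = (s_rare / c_ace) * top / (n_rare * (n_rare - 1.0)) - 1.0 if n_rare > 1 else 0.0
    gamma2 = max(gamma2, 0.0)
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2
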