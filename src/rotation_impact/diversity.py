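"""Rarefaction and alpha-diversity of OTU count tables.

Samples are subsampled without replacement to a common read depth
(rarefaction) to remove unequal sequencing effort, then characterized by
six within-sample diversity indices: richness, Shannon-Weaver (natural
log), Gini-Simpson, Pielou evenness, and the Chao1 and ACE richness
estimators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def rarefy(
    table: pd.DataFrame, depth: int | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Subsample each column of a taxa x samples count table to equal depth.

    ``depth`` defaults to the minimum column sum.  Sampling is without
    replacement (multivariate hypergeometric), deterministic given
    ``seed``.  Samples shallower than ``depth`` raise an error listing
    them.
    """
    counts = table.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("OTU counts must be integers")
        counts = counts.astype(np.int64)
    if (counts < 0).any():
        raise ValueError("OTU counts must be nonnegative")
    totals = counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    short = [str(c) for c, t in zip(table.columns, totals) if t < depth]
    if short:
        raise ValueError(f"samples shallower than depth {depth}: {short}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def _frequency_counts(counts: np.ndarray, upto: int) -> np.ndarray:
    """F[i] = number of taxa observed exactly i times, for i = 1..upto."""
    return np.array([int(np.sum(counts == i)) for i in range(1, upto + 1)])


def chao1(counts: np.ndarray) -> float:
    """Chao1 richness estimator.

    S + F1^2 / (2 F2) with singleton/doubleton counts F1/F2; the
    bias-corrected form S + F1 (F1 - 1) / (2 (F2 + 1)) is used when no
    doubletons exist.
    """
    s = int(np.sum(counts > 0))
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    if f2 > 0:
        return s + f1 * f1 / (2.0 * f2)
    return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def ace(counts: np.ndarray, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator of richness.

    Splits taxa into rare (count <= threshold) and abundant groups; the
    rare group's sample coverage and coefficient of variation correct the
    observed richness.  When every rare read is a singleton the coverage
    is zero and the Chao1 estimate is returned instead.
    """
    counts = counts[counts > 0]
    s_abund = int(np.sum(counts > rare_threshold))
    rare = counts[counts <= rare_threshold]
    s_rare = rare.size
    n_rare = int(rare.sum())
    if s_rare == 0:
        return float(s_abund)
    f1 = int(np.sum(rare == 1))
    if f1 == n_rare:
        return chao1(counts)
    c_ace = 1.0 - f1 / n_rare
    freqs = _frequency_counts(rare, rare_threshold)
    i = np.arange(1, rare_threshold + 1)
    sum_i = float(np.sum(i * (i - 1) * freqs))
    gamma2 = max(s_rare / c_ace * sum_i / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    return s_abund + s_rare / c_ace + f1 / c_ace * gamma2


def alpha_diversity(counts: np.ndarray | pd.Series, rare_threshold: int = 10) -> dict[str, float]:
    """Six alpha-diversity indices of one sample's OTU counts.

    Returns richness S, Shannon H = -Sum p ln p, Gini-Simpson 1 - Sum
    p^2 (the raw dominance Sum p^2 is also emitted), Pielou J = H / ln S
    (NaN for a single-taxon sample), Chao1 and ACE.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero sample has no diversity")
    p = c[c > 0] / total
    h = float(-np.sum(p * np.log(p)))
    s = int(p.size)
    dominance = float(np.sum(p**2))
    return {
        "richness": float(s),
        "shannon": h,
        "simpson": 1.0 - dominance,
        "dominance": dominance,
        "pielou": h / np.log(s) if s > 1 else float("nan"),
        "chao1": float(chao1(c)),
        "ace": float(ace(c, rare_threshold=rare_threshold)),
    }


def alpha_diversity_table(table: pd.DataFrame, rare_threshold: int = 10) -> pd.DataFrame:
    """Per-sample alpha diversity of a taxa x samples table (samples as rows)."""
    rows = {
        str(col): alpha_diversity(table[col].to_numpy(), rare_threshold=rare_threshold)
        for col in table.columns
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out
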