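"""Entropy-weighted TOPSIS comprehensive evaluation index (CEI).

Rotation alternatives are compared over several criteria (equivalent
yield, economic benefit, nutrition yield, soil biodiversity, soil health,
soil carbon sequestration as benefits; net GHG emissions as a cost).
Criteria are min-max normalized with direction handling, weighted by
information entropy (criteria that discriminate more between alternatives
receive more weight), and each alternative is ranked by its relative
closeness to the positive ideal: CEI = D- / (D+ + D-) in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

#: default criterion directions for the rotation assessment
DEFAULT_DIRECTIONS: dict[str, str] = {
    "equivalent_yield": "positive",
    "economic_benefit": "positive",
    "nutrition_yield": "positive",
    "soil_biodiversity": "positive",
    "soil_health": "positive",
    "c_sequestration": "positive",
    "net_ghg": "negative",
}


def normalize_matrix(
    matrix: pd.DataFrame, directions: Mapping[str, str]
) -> pd.DataFrame:
    """Direction-aware min-max normalization of a decision matrix.

    ``matrix`` is alternatives x criteria.  Benefit ("positive") criteria
    map to (x - min)/(max - min) and cost ("negative") criteria to
    (max - x)/(max - min), so 1 is always best.  A criterion constant
    across alternatives is degenerate and raises an error naming it.
    """
    if matrix.shape[0] < 2:
        raise ValueError("decision matrix needs at least 2 alternatives")
    if matrix.isna().any().any():
        raise ValueError("decision matrix has missing cells")
    missing = set(matrix.columns) - set(directions)
    if missing:
        raise ValueError(f"no direction for criteria: {sorted(missing)}")
    b = pd.DataFrame(index=matrix.index, columns=matrix.columns, dtype=float)
    for crit in matrix.columns:
        col = matrix[crit].astype(float)
        span = col.max() - col.min()
        if span == 0:
            raise ValueError(f"criterion {crit!r} is constant across alternatives")
        if directions[crit] == "positive":
            b[crit] = (col - col.min()) / span
        elif directions[crit] == "negative":
            b[crit] = (col.max() - col) / span
        else:
            raise ValueError(f"unknown direction {directions[crit]!r} for {crit!r}")
    return b


@dataclass(frozen=True)
class EntropyWeights:
    weights: pd.Series
    entropy: pd.Series
    proportions: pd.DataFrame


def entropy_weights(b: pd.DataFrame) -> EntropyWeights:
    """Objective criterion weights from information entropy.

    Per criterion j the normalized values across the m alternatives are
    turned into proportions f_ij = b_ij / Sum_i b_ij (when the column
    contains a zero, the shifted form f_ij = (1 + b_ij) / Sum_i (1 + b_ij)
    keeps every logarithm finite), the entropy is
    H_j = -(1/ln m) Sum_i f_ij ln f_ij, and the weight is
    W_j = (1 - H_j) / Sum_k (1 - H_k); weights sum to one.
    """
    m = b.shape[0]
    if m < 2:
        raise ValueError("entropy weights need at least 2 alternatives")
    f = pd.DataFrame(index=b.index, columns=b.columns, dtype=float)
    for crit in b.columns:
        col = b[crit].to_numpy(dtype=float)
        if np.any(col == 0.0):
            shifted = 1.0 + col
            f[crit] = shifted / shifted.sum()
        else:
            f[crit] = col / col.sum()
    fv = f.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        flogf = np.where(fv > 0, fv * np.log(fv), 0.0)
    h = pd.Series(-flogf.sum(axis=0) / np.log(m), index=b.columns)
    one_minus = 1.0 - h
    denom = one_minus.sum()
    if denom <= 0:
        raise ValueError("all criteria are maximally uniform; entropy weights undefined")
    return EntropyWeights(weights=one_minus / denom, entropy=h, proportions=f)


@dataclass(frozen=True)
class CEIResult:
    """All intermediate quantities of the entropy-TOPSIS evaluation."""

    normalized: pd.DataFrame
    proportions: pd.DataFrame
    entropy: pd.Series
    weights: pd.Series
    weighted: pd.DataFrame
    ideal_positive: pd.Series
    ideal_negative: pd.Series
    distance_positive: pd.Series
    distance_negative: pd.Series
    cei: pd.Series
    ranks: pd.Series
    ties: bool


def topsis_cei(
    b: pd.DataFrame,
    ew: EntropyWeights,
    weight_on: str = "b",
) -> CEIResult:
    """Rank alternatives by closeness to the ideal solution.

    The weighted matrix is z_ij = W_j * b_ij (``weight_on="f"`` applies
    the weights to the entropy proportions instead); ideal vectors are the
    column maxima/minima, distances are Euclidean, and
    CEI_i = D_i- / (D_i+ + D_i-).  Ranks are 1 for the highest CEI; exact
    ties share a rank and are flagged.
    """
    w = ew.weights
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    base = b if weight_on == "b" else ew.proportions
    if weight_on not in ("b", "f"):
        raise ValueError("weight_on must be 'b' or 'f'")
    z = base * w
    z_plus = z.max(axis=0)
    z_minus = z.min(axis=0)
    d_plus = np.sqrt(((z - z_plus) ** 2).sum(axis=1))
    d_minus = np.sqrt(((z - z_minus) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    if (denom == 0).all():
        raise ValueError("all alternatives identical; CEI undefined")
    cei = d_minus / denom
    ranks = cei.rank(ascending=False, method="min").astype(int)
    return CEIResult(
        normalized=b,
        proportions=ew.proportions,
        entropy=ew.entropy,
        weights=w,
        weighted=z,
        ideal_positive=z_plus,
        ideal_negative=z_minus,
        distance_positive=d_plus,
        distance_negative=d_minus,
        cei=cei,
        ranks=ranks,
        ties=bool(cei.duplicated().any()),
    )


def cei_from_matrix(
    matrix: pd.DataFrame,
    directions: Mapping[str, str] | None = None,
    weight_on: str = "b",
) -> CEIResult:
    """Convenience chain: normalize, entropy-weight, and TOPSIS-rank."""
    directions = DEFAULT_DIRECTIONS if directions is None else directions
    b = normalize_matrix(matrix, directions)
    return topsis_cei(b, entropy_weights(b), weight_on=weight_on)
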