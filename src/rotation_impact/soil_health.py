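"""Cornell-style soil-health scoring with PCA-derived indicator weights.

Each of ten soil indicators (bulk density, water content, pH, total N,
SOC, DOC, nitrate-N, available P, microbial biomass C and N) is scored
0-100 against the pooled sample distribution with a cumulative-normal
curve whose orientation depends on whether more of the indicator is
better, less is better, or an optimum value exists (pH).  Indicator
weights are the summed absolute loadings of the leading principal
components (Kaiser criterion, eigenvalue > 1, capped at three), and the
overall score is the weight-averaged indicator score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

#: default scoring orientation of the ten indicators
DEFAULT_DIRECTIONS: dict[str, str] = {
    "BD": "less",
    "SWC": "more",
    "pH": "optimum",
    "TN": "more",
    "SOC": "more",
    "DOC": "more",
    "NO3N": "more",
    "AP": "more",
    "MBC": "more",
    "MBN": "more",
}

#: default optimum targets for 'optimum' indicators
DEFAULT_OPTIMA: dict[str, float] = {"pH": 7.0}


def csha_normalize(
    values: np.ndarray | pd.Series,
    direction: str,
    mean: float | None = None,
    sd: float | None = None,
    optimum: float | None = None,
) -> np.ndarray:
    """Score indicator values 0-100 with a cumulative-normal curve.

    more-is-better: 100*Phi(z); less-is-better: 100*(1-Phi(z)); optimum:
    a symmetric penalty 100*(1-|2*Phi(z_t)-1|) around the target, where z
    standardizes against the pooled mean/SD (computed from ``values`` when
    not supplied).
    """
    x = np.asarray(values, dtype=float)
    if mean is None:
        mean = float(np.mean(x))
    if sd is None:
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if sd <= 0:
        raise ValueError("zero or negative SD: degenerate indicator cannot be scored")
    if direction == "more":
        score = 100.0 * norm.cdf((x - mean) / sd)
    elif direction == "less":
        score = 100.0 * (1.0 - norm.cdf((x - mean) / sd))
    elif direction == "optimum":
        if optimum is None:
            raise ValueError("optimum direction requires a target value")
        score = 100.0 * (1.0 - np.abs(2.0 * norm.cdf((x - optimum) / sd) - 1.0))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return np.clip(score, 0.0, 100.0)


@dataclass(frozen=True)
class PCAReport:
    eigenvalues: np.ndarray
    explained_variance_pct: np.ndarray
    n_retained: int
    loadings: pd.DataFrame  # indicators x components


def pca_weights(
    matrix: pd.DataFrame, max_components: int = 3
) -> tuple[pd.Series, PCAReport]:
    """Indicator weights from a PCA of the standardized indicator matrix.

    Columns are standardized to zero mean and unit variance; components
    with eigenvalue > 1 are retained (at least one, at most
    ``max_components``) and each indicator's weight is the sum of its
    absolute loadings on the retained components.  Eigenvector sign is
    arbitrary, hence the absolute value.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 indicators")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        degenerate = list(matrix.columns[sd == 0])
        raise ValueError(f"constant indicator columns cannot be weighted: {degenerate}")
    z = (x - x.mean(axis=0)) / sd
    corr = np.cov(z, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_retained = int(np.sum(eigval > 1.0))
    n_retained = max(1, min(n_retained, max_components))
    loadings = pd.DataFrame(
        eigvec,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(eigvec.shape[1])],
    )
    weights = loadings.iloc[:, :n_retained].abs().sum(axis=1)
    report = PCAReport(
        eigenvalues=eigval,
        explained_variance_pct=100.0 * eigval / eigval.sum(),
        n_retained=n_retained,
        loadings=loadings,
    )
    return weights, report


def soil_health_score(scores, weights) -> float:
    """Overall soil health, %: weighted average of the indicator scores."""
    a = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if a.shape != w.shape:
        raise ValueError("scores and weights differ in length")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("weights sum to zero")
    return float(np.sum(a * w) / w.sum())


def score_indicator_table(
    table: pd.DataFrame,
    directions: Mapping[str, str] | None = None,
    optima: Mapping[str, float] | None = None,
    max_components: int = 3,
) -> tuple[pd.DataFrame, pd.Series, PCAReport]:
    """Score a long indicator table and derive the overall score per sample.

    ``table`` has columns plot, timepoint, indicator, value; all plots and
    timepoints are pooled into one scoring population so that scores are
    comparable across years.  Returns (per-sample frame with indicator
    scores and an ``overall`` column, indicator weights, PCA report).
    """
    directions = dict(DEFAULT_DIRECTIONS if directions is None else directions)
    optima = dict(DEFAULT_OPTIMA if optima is None else optima)
    wide = table.pivot_table(
        index=["plot", "timepoint"], columns="indicator", values="value"
    )
    if wide.isna().any().any():
        raise ValueError("indicator table has missing cells for scored samples")
    unassigned = set(wide.columns) - set(directions)
    if unassigned:
        raise ValueError(f"no direction assigned for indicators: {sorted(unassigned)}")
    scores = pd.DataFrame(index=wide.index)
    for ind in wide.columns:
        scores[ind] = csha_normalize(
            wide[ind], directions[ind], optimum=optima.get(ind)
        )
    weights, report = pca_weights(wide, max_components=max_components)
    weights = weights.reindex(scores.columns)
    scores["overall"] = [
        soil_health_score(row, weights.to_numpy())
        for row in scores[wide.columns].to_numpy()
    ]
    return scores, weights, report
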