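"""Group statistics for the rotation trial: one-way ANOVA, LSD letters, correlations."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupStats:
    means: pd.Series
    f_statistic: float
    p_value: float
    mse: float
    df_error: int
    pairwise_p: pd.DataFrame
    letters: dict[str, str]


def _compact_letter_display(
    groups: list[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``groups`` are ordered best-first; groups sharing a letter are not
    significantly different.
    """
    columns: list[set[str]] = [set(groups)]
    for a, b in sorted(significant):
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.append(col - {a})
            columns.append(col - {b})
        # absorb: drop empties, duplicates, and columns contained in another
        kept: list[set[str]] = []
        for col in columns:
            if col and not any(col < other for other in columns) and col not in kept:
                kept.append(col)
        columns = kept
    order = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda col: min(order[g] for g in col))
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        ch = chr(ord("a") + i)
        for g in col:
            letters[g] += ch
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def group_stats(
    data: pd.DataFrame, value: str, group: str, alpha: float = 0.05
) -> GroupStats:
    """One-way ANOVA with LSD post-hoc letters across rotation groups.

    The least-significant-difference test compares each pair with a t
    statistic based on the pooled error mean square; groups not separated
    at ``alpha`` share a lowercase letter (letters assigned by the
    insert-absorb algorithm, best mean first).
    """
    grouped = {k: v[value].to_numpy(dtype=float) for k, v in data.groupby(group)}
    if len(grouped) < 2:
        raise ValueError("group statistics need at least 2 groups")
    if any(len(v) < 2 for v in grouped.values()):
        raise ValueError("every group needs at least 2 replicates")
    names = list(grouped)
    k = len(names)
    n_total = sum(len(v) for v in grouped.values())
    grand = np.concatenate(list(grouped.values())).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in grouped.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in grouped.values())
    df_b, df_e = k - 1, n_total - k
    mse = ss_within / df_e
    if mse == 0:
        raise ValueError("zero within-group variance; ANOVA undefined")
    f_stat = (ss_between / df_b) / mse
    p_val = float(sps.f.sf(f_stat, df_b, df_e))

    means = pd.Series({g: grouped[g].mean() for g in names}).sort_values(ascending=False)
    pw = pd.DataFrame(np.nan, index=names, columns=names)
    significant: set[tuple[str, str]] = set()
    for a, b in combinations(names, 2):
        se = np.sqrt(mse * (1.0 / len(grouped[a]) + 1.0 / len(grouped[b])))
        t = abs(grouped[a].mean() - grouped[b].mean()) / se
        p = 2.0 * sps.t.sf(t, df_e)
        pw.loc[a, b] = pw.loc[b, a] = p
        if p < alpha:
            significant.add((a, b))
    letters = _compact_letter_display(list(means.index), significant)
    return GroupStats(
        means=means,
        f_statistic=float(f_stat),
        p_value=p_val,
        mse=float(mse),
        df_error=df_e,
        pairwise_p=pw,
        letters=letters,
    )


def correlation_matrix(metrics: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between columns of a metric table.

    Needs at least 3 rows; a constant column has no defined correlation
    and yields NaN off-diagonal (its diagonal is set to 1).
    """
    if metrics.shape[0] < 3:
        raise ValueError("Pearson correlations need at least 3 paired observations")
    r = metrics.corr(method="pearson")
    np.fill_diagonal(r.values, 1.0)
    return r
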