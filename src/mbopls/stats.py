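"""Nonparametric group comparisons and compact letter displays.

The univariate layer compares inhibition values (and selected-ion peak areas)
across organ x site groups: a global Kruskal-Wallis test, all-pairs two-group
Kruskal-Wallis post hocs with Bonferroni adjustment, Dunn's many-to-one test
against a control (e.g. acarbose), and a compact letter display in which two
groups share a letter exactly when their adjusted p-value is >= alpha.

Tie handling is mid-ranks with the usual tie variance correction throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


def _split(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise StatsError("values and groups must be equal length")
    labels = list(pd.unique(groups))
    data = {g: values[groups == g] for g in labels}
    for g, v in data.items():
        if len(v) == 0:
            raise StatsError(f"group {g!r} is empty")
    return labels, data


def kruskal_wallis(values, groups):
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Complete ties (all values identical) give (0, 1).
    """
    labels, data = _split(values, groups)
    if len(labels) < 2:
        raise StatsError("need at least 2 groups")
    arrays = [data[g] for g in labels]
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def pairwise_posthoc(values, groups, adjust: str = "bonferroni") -> pd.DataFrame:
    """All-pairs two-group Kruskal-Wallis p-values, Bonferroni adjusted.

    Returns a symmetric DataFrame (diagonal NaN).  ``adjust='none'`` returns
    raw p-values.
    """
    if adjust not in ("bonferroni", "none"):
        raise StatsError(f"unknown adjustment {adjust!r}")
    labels, data = _split(values, groups)
    if len(labels) < 2:
        raise StatsError("need at least 2 groups")
    k = len(labels)
    m = k * (k - 1) // 2
    table = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for a, b in combinations(labels, 2):
        _, p = kruskal_wallis(np.concatenate([data[a], data[b]]),
                              np.array([a] * len(data[a]) + [b] * len(data[b]), dtype=object))
        if adjust == "bonferroni":
            p = min(1.0, p * m)
        table.loc[a, b] = table.loc[b, a] = p
    return table


def dunn_many_to_one(values, groups, control_label) -> pd.Series:
    """Dunn's z tests of each group against the control on joint mid-ranks.

    Tie-corrected variance; two-sided normal p-values with one-step
    Bonferroni over the (k - 1) comparisons, capped at 1.
    """
    labels, data = _split(values, groups)
    if control_label not in data:
        raise StatsError(f"control group {control_label!r} not present")
    flat = np.concatenate([data[g] for g in labels])
    ranks = sps.rankdata(flat)
    n_total = len(flat)
    rank_by_group, start = {}, 0
    for g in labels:
        rank_by_group[g] = ranks[start:start + len(data[g])]
        start += len(data[g])
    _, tie_counts = np.unique(flat, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        base_var -= tie_term / (12.0 * (n_total - 1))
    mean_c = rank_by_group[control_label].mean()
    n_c = len(data[control_label])
    others = [g for g in labels if g != control_label]
    p_values = {}
    for g in others:
        var = base_var * (1.0 / len(data[g]) + 1.0 / n_c)
        if var <= 0:
            p_values[g] = 1.0
            continue
        z = (rank_by_group[g].mean() - mean_c) / np.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
        p_values[g] = min(1.0, p * len(others))
    return pd.Series(p_values, name="p_vs_control")


# ---------------------------------------------------------------------------
# compact letter display
# ---------------------------------------------------------------------------

def _maximal_cliques(adj: np.ndarray) -> list:
    """All maximal cliques of a small undirected graph (subset enumeration)."""
    k = adj.shape[0]
    cliques = []
    for mask in range(1, 1 << k):
        members = [i for i in range(k) if mask >> i & 1]
        if all(adj[a, b] for a, b in combinations(members, 2)):
            cliques.append(frozenset(members))
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    return maximal


def minimum_clique_cover(adj: np.ndarray) -> list:
    """Smallest family of cliques covering every vertex and every edge.

    Exhaustive search over subfamilies of maximal cliques; intended for the
    handful of groups typical of a designed experiment (k <= ~12).
    """
    k = adj.shape[0]
    if k == 0:
        return []
    edges = [(a, b) for a, b in combinations(range(k), 2) if adj[a, b]]
    cliques = sorted(_maximal_cliques(adj), key=lambda c: sorted(c))
    for size in range(1, len(cliques) + 1):
        best = None
        for family in combinations(cliques, size):
            if not all(any(v in c for c in family) for v in range(k)):
                continue
            if not all(any(a in c and b in c for c in family) for a, b in edges):
                continue
            if best is None or [sorted(c) for c in family] < [sorted(c) for c in best]:
                best = family
        if best is not None:
            return [set(c) for c in best]
    raise StatsError("no clique cover found")  # unreachable


def compact_letter_display(pairwise_p: pd.DataFrame, alpha: float = 0.05,
                           group_order=None) -> pd.Series:
    """Minimal letters such that groups share a letter iff adjusted p >= alpha.

    ``pairwise_p`` is the symmetric adjusted p-value table.  Letters are
    assigned 'a', 'b', ... in first-use order over ``group_order`` (callers
    typically pass groups sorted by descending median); default order is the
    table's own.
    """
    if not 0 < alpha < 1:
        raise StatsError("alpha must be in (0, 1)")
    groups = list(pairwise_p.index)
    if list(pairwise_p.columns) != groups:
        raise StatsError("p table must be square with matching labels")
    arr = pairwise_p.to_numpy(dtype=float)
    off = ~np.eye(len(groups), dtype=bool)
    if not np.allclose(np.where(off, arr, 0.0), np.where(off, arr.T, 0.0), equal_nan=True):
        raise StatsError("p table must be symmetric")
    if group_order is None:
        group_order = groups
    if sorted(group_order) != sorted(groups):
        raise StatsError("group_order must be a permutation of the table labels")
    k = len(groups)
    pos = {g: i for i, g in enumerate(groups)}
    adj = np.zeros((k, k), dtype=bool)
    for a, b in combinations(groups, 2):
        adj[pos[a], pos[b]] = adj[pos[b], pos[a]] = arr[pos[a], pos[b]] >= alpha
    cover = minimum_clique_cover(adj)
    # letter naming: order cliques by the first ordered group they contain
    order_pos = {g: i for i, g in enumerate(group_order)}
    cover.sort(key=lambda c: sorted(order_pos[groups[v]] for v in c))
    letters = {g: "" for g in groups}
    for letter_idx, clique in enumerate(cover):
        ch = chr(ord("a") + letter_idx)
        for v in clique:
            letters[groups[v]] += ch
    return pd.Series({g: "".join(sorted(letters[g])) for g in groups}, name="letters")


# ---------------------------------------------------------------------------
# convenience: one-call group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    groups: list
    kw_statistic: float
    kw_p: float
    pairwise_adjusted_p: pd.DataFrame
    alpha: float
    letters: pd.Series


def compare_groups(values, groups, alpha: float = 0.05) -> GroupComparison:
    """Global KW + Bonferroni pairwise post hocs + letters (median-ordered)."""
    labels, data = _split(values, groups)
    h, p = kruskal_wallis(values, groups)
    table = pairwise_posthoc(values, groups, adjust="bonferroni")
    order = sorted(labels, key=lambda g: -float(np.median(data[g])))
    letters = compact_letter_display(table, alpha=alpha, group_order=order)
    return GroupComparison(groups=labels, kw_statistic=h, kw_p=p,
                           pairwise_adjusted_p=table, alpha=alpha, letters=letters)
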