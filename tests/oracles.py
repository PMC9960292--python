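"""Independent reference implementations used only to check the package.

These are deliberately naive (textbook formulas, exhaustive enumeration) and
share no code with the implementation under test.
"""

from itertools import combinations

import numpy as np
import pandas as pd


def pls1_single_component(X, y):
    """Textbook NIPALS PLS1, one component, on an already-scaled matrix.

    Returns predictions on the training samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    w = X.T @ yc
    w = w / np.linalg.norm(w)
    t = X @ w
    q = float(yc @ t / (t @ t))
    return y.mean() + q * t


def brute_force_intensity_filter(X, organs, threshold):
    """Kept column indices: mean within >= 1 organ strictly above threshold."""
    X = np.asarray(X, dtype=float)
    organs = np.asarray(organs)
    kept = []
    for j in range(X.shape[1]):
        means = [X[organs == o, j].mean() for o in pd.unique(organs)]
        if any(mu > threshold for mu in means):
            kept.append(j)
    return kept


def brute_force_prune(X, rts, r_threshold, rt_tolerance, ion_ids):
    """All-pairs correlation pruning by explicit graph construction.

    Edge iff |drt| <= tol and pearson r >= threshold (constant ions correlate
    with nothing); connected components found by BFS; keep the member with the
    highest median intensity, ties by smallest ion id.  Returns kept ids in
    input order.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    adj = {i: set() for i in range(n)}
    for i, j in combinations(range(n), 2):
        if abs(rts[i] - rts[j]) > rt_tolerance:
            continue
        xi, xj = X[:, i], X[:, j]
        if xi.std() == 0 or xj.std() == 0:
            continue
        r = np.corrcoef(xi, xj)[0, 1]
        if r >= r_threshold:
            adj[i].add(j)
            adj[j].add(i)
    seen, kept = set(), []
    for start in range(n):
        if start in seen:
            continue
        comp, queue = [], [start]
        while queue:
            v = queue.pop()
            if v in seen:
                continue
            seen.add(v)
            comp.append(v)
            queue.extend(adj[v] - seen)
        rep = min(comp, key=lambda v: (-float(np.median(X[:, v])), ion_ids[v]))
        kept.append(rep)
    keep_set = set(kept)
    return [ion_ids[i] for i in range(n) if i in keep_set]


def all_cliques(adj):
    """Every clique (as frozenset) of a small boolean adjacency matrix."""
    k = adj.shape[0]
    out = []
    for mask in range(1, 1 << k):
        members = [i for i in range(k) if mask >> i & 1]
        if all(adj[a, b] for a, b in combinations(members, 2)):
            out.append(frozenset(members))
    return out


def min_letter_count(adj):
    """Size of the smallest clique family covering all vertices and edges."""
    k = adj.shape[0]
    edges = [(a, b) for a, b in combinations(range(k), 2) if adj[a, b]]
    cliques = all_cliques(adj)
    # a cover can need more than k cliques (edge cover dominates vertex cover)
    for size in range(1, len(cliques) + 1):
        for family in combinations(cliques, size):
            if not all(any(v in c for c in family) for v in range(k)):
                continue
            if all(any(a in c and b in c for c in family) for a, b in edges):
                return size
    raise AssertionError("no cover found")
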