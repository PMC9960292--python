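"""Consensus multiblock OPLS: weighted-kernel OPLS with one predictive component.

Model
-----
Each block X_b (samples x ions, column-scaled) defines a linear sample-space
kernel K_b = X_b X_b', Frobenius-normalized so no block dominates by size.
The consensus kernel is the weighted sum K = sum_b w_b K_b with non-negative
weights summing to one.  An OPLS decomposition of (K, y) extracts one
y-predictive score vector t_pred plus ``n_ortho`` y-orthogonal score vectors,
and the weights are iterated: after each fit, w_b is set proportional to the
squared Frobenius congruence between K_b and the predictive-score outer
product t t' (an RV-type measure, bounded in [0, 1]), until the weights
stabilize.

Because every kernel here is linear, the kernel decomposition is computed in
the equivalent primal form: OPLS on the concatenation of the scaled blocks,
each multiplied by s_b = sqrt(w_b / ||K_b||_F).  The concatenated matrix
reproduces the consensus kernel exactly, all scores and fit metrics depend on
the data only through that kernel, and projecting new samples reduces to
applying the stored column centers/scales and block factors — exactly the
"training scaling parameters" required for honest cross-validation.

The predictive score is sign-oriented so that corr(t_pred, y) > 0: higher
scores mean higher response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd


class OplsError(ValueError):
    pass


class AlignmentError(OplsError):
    pass


class NotFittedError(OplsError):
    pass


# ---------------------------------------------------------------------------
# column scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingParams:
    center: np.ndarray
    scale: np.ndarray
    method: str
    zero_variance: np.ndarray  # boolean flags for constant columns

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale


def scale_block(X, method: str = "uv"):
    """Column-wise centering plus unit-variance ('uv'), pareto, or none.

    Zero-variance columns are centered only (scale 1) and flagged.
    Returns ``(scaled matrix, ScalingParams)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise OplsError("scaling needs a 2-D matrix with >= 2 samples")
    if method not in ("uv", "pareto", "center"):
        raise OplsError(f"unknown scaling method {method!r}")
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if method == "uv":
        scale = np.where(zero, 1.0, sd)
    elif method == "pareto":
        scale = np.where(zero, 1.0, np.sqrt(sd))
    else:
        scale = np.ones_like(sd)
    params = ScalingParams(center=center, scale=scale, method=method, zero_variance=zero)
    return params.apply(X), params


# ---------------------------------------------------------------------------
# OPLS core (primal NIPALS, single y)
# ---------------------------------------------------------------------------

def _opls_nipals(X: np.ndarray, y: np.ndarray, n_ortho: int):
    """Trygg-Wold OPLS for a single centred response.

    Returns dict with predictive (w, t, p, q) and per-component orthogonal
    (w_o, t_o, p_o) arrays.  The orthogonal scores are exactly orthogonal to
    the final predictive score.
    """
    Xd = X.copy()
    w = X.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        raise OplsError("response is orthogonal to all predictors")
    w = w / nw
    W_o, P_o, T_o = [], [], []
    for _ in range(n_ortho):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:          # no orthogonal variation left
            break
        w_o = w_o / n_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    q = (y @ t) / (t @ t)
    return {"w": w, "t": t, "p": p, "q": q,
            "W_o": W_o, "P_o": P_o, "T_o": T_o, "X_deflated": Xd}


# ---------------------------------------------------------------------------
# fitted-model container
# ---------------------------------------------------------------------------

@dataclass
class MBOPLSModel:
    block_names: list
    block_weights: np.ndarray
    block_slices: list                 # column ranges in the concatenated matrix
    scaling: list                      # ScalingParams per block
    kernel_fnorms: np.ndarray          # ||K_b||_F on training data
    w: np.ndarray
    W_o: list
    P_o: list
    t_pred: np.ndarray
    T_ortho: np.ndarray                # n x n_ortho (may have 0 columns)
    p_pred: np.ndarray
    q: float
    y_mean: float
    r2y: float
    explained_variance: dict           # {"predictive": f, "orthogonal": [f, ...]}
    n_ortho: int
    converged: bool
    n_iter: int
    q2: float | None = None
    scaling_method: str = "uv"
    sample_ids: list | None = None
    ion_ids: list | None = None        # per block

    # -- projection ---------------------------------------------------------
    def _weighted_concat(self, blocks) -> np.ndarray:
        mats = []
        for b, (params, (w_b, fnorm)) in enumerate(
                zip(self.scaling, zip(self.block_weights, self.kernel_fnorms))):
            Xs = params.apply(np.asarray(blocks[b], dtype=float))
            mats.append(np.sqrt(w_b / fnorm) * Xs)
        return np.hstack(mats)

    def transform(self, blocks):
        """Predictive and orthogonal scores for new samples."""
        if len(blocks) != len(self.block_names):
            raise AlignmentError("block count differs from the fitted model")
        Xw = self._weighted_concat(blocks)
        T_o = []
        for w_o, p_o in zip(self.W_o, self.P_o):
            t_o = Xw @ w_o
            Xw = Xw - np.outer(t_o, p_o)
            T_o.append(t_o)
        t = Xw @ self.w
        return t, (np.column_stack(T_o) if T_o else np.empty((Xw.shape[0], 0)))

    def predict(self, blocks) -> np.ndarray:
        t, _ = self.transform(blocks)
        return self.y_mean + self.q * t

    # -- serialization --------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "block_names": self.block_names,
            "block_weights": self.block_weights.tolist(),
            "kernel_fnorms": self.kernel_fnorms.tolist(),
            "r2y": self.r2y, "q2": self.q2,
            "explained_variance": self.explained_variance,
            "n_ortho": self.n_ortho, "converged": self.converged,
            "n_iter": self.n_iter, "scaling_method": self.scaling_method,
            "y_mean": self.y_mean, "q": self.q,
            "sample_ids": self.sample_ids,
            "t_pred": self.t_pred.tolist(),
            "T_ortho": self.T_ortho.tolist(),
            "scaling": [{"center": s.center.tolist(), "scale": s.scale.tolist(),
                         "method": s.method} for s in self.scaling],
            "w": self.w.tolist(),
            "W_o": [v.tolist() for v in self.W_o],
            "P_o": [v.tolist() for v in self.P_o],
            "p_pred": self.p_pred.tolist(),
            "ion_ids": self.ion_ids,
            "schema_version": 1,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _as_matrices(blocks):
    mats = []
    for X in blocks:
        if hasattr(X, "intensities"):   # FeatureBlock
            mats.append(X.intensities.to_numpy(dtype=float))
        else:
            mats.append(np.asarray(X, dtype=float))
    return mats


def fit_consensus_opls(blocks, y, n_ortho: int = 1, scaling: str = "uv",
                       max_iter: int = 100, tol: float = 1e-6,
                       block_names=None, sample_ids=None, ion_ids=None) -> MBOPLSModel:
    """Fit the weighted-kernel consensus OPLS model.

    ``blocks`` is a list of samples x ions matrices (raw peak areas); each is
    column-scaled internally with ``scaling`` and the parameters stored for
    projecting new samples.  ``n_ortho`` orthogonal components are extracted
    (default one).  Block weights start uniform and iterate to the
    congruence fixed point (change < ``tol``, at most ``max_iter`` rounds).
    """
    mats = _as_matrices(blocks)
    if not mats:
        raise OplsError("need at least one block")
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise AlignmentError("blocks have differing sample counts")
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != n:
        raise AlignmentError("response length does not match blocks")
    if n < 3:
        raise OplsError("need at least 3 samples")
    if n_ortho < 0:
        raise OplsError("n_ortho must be >= 0")
    if np.std(y) == 0:
        raise OplsError("zero-variance response")

    scaled, params = [], []
    for m in mats:
        Xs, sp = scale_block(m, scaling)
        scaled.append(Xs)
        params.append(sp)
    fnorms = np.array([np.linalg.norm(Xs @ Xs.T) for Xs in scaled])
    if (fnorms == 0).any():
        raise OplsError("a block has zero total variance")

    y_mean = float(y.mean())
    yc = y - y_mean
    n_blocks = len(scaled)
    weights = np.full(n_blocks, 1.0 / n_blocks)
    slices, start = [], 0
    for Xs in scaled:
        slices.append((start, start + Xs.shape[1]))
        start += Xs.shape[1]

    Kn = [Xs @ Xs.T / f for Xs, f in zip(scaled, fnorms)]  # unit Frobenius norm

    converged = False
    fit = None
    Xw = None
    for it in range(1, max_iter + 1):
        factors = np.sqrt(weights / fnorms)
        Xw = np.hstack([f * Xs for f, Xs in zip(factors, scaled)])
        fit = _opls_nipals(Xw, yc, n_ortho)
        t = fit["t"]
        T = np.outer(t, t)
        T /= np.linalg.norm(T)
        congr = np.array([float(np.sum(K * T)) ** 2 for K in Kn])
        if congr.sum() == 0:
            new_w = np.full(n_blocks, 1.0 / n_blocks)
        else:
            new_w = congr / congr.sum()
        delta = np.max(np.abs(new_w - weights))
        weights = new_w
        if delta < tol:
            converged = True
            break
    # final fit at the converged weights
    factors = np.sqrt(weights / fnorms)
    Xw0 = np.hstack([f * Xs for f, Xs in zip(factors, scaled)])
    fit = _opls_nipals(Xw0, yc, n_ortho)

    t, q = fit["t"], fit["q"]
    # orient: higher predictive score = higher response
    if (t @ yc) < 0:
        t, fit["w"], fit["p"], q = -t, -fit["w"], -fit["p"], -q

    y_hat = q * t
    ss_tot = float(yc @ yc)
    r2y = 1.0 - float((yc - y_hat) @ (yc - y_hat)) / ss_tot

    total_x = float(np.sum(Xw0 ** 2))
    ev_pred = float(np.sum(np.outer(t, fit["p"]) ** 2)) / total_x
    ev_orth = [float(np.sum(np.outer(t_o, p_o) ** 2)) / total_x
               for t_o, p_o in zip(fit["T_o"], fit["P_o"])]

    T_ortho = (np.column_stack(fit["T_o"]) if fit["T_o"]
               else np.empty((n, 0)))
    return MBOPLSModel(
        block_names=list(block_names) if block_names else [f"block_{i}" for i in range(n_blocks)],
        block_weights=weights,
        block_slices=slices,
        scaling=params,
        kernel_fnorms=fnorms,
        w=fit["w"], W_o=fit["W_o"], P_o=fit["P_o"],
        t_pred=t, T_ortho=T_ortho, p_pred=fit["p"], q=float(q), y_mean=y_mean,
        r2y=float(r2y),
        explained_variance={"predictive": ev_pred, "orthogonal": ev_orth},
        n_ortho=n_ortho, converged=converged, n_iter=it,
        scaling_method=scaling,
        sample_ids=list(sample_ids) if sample_ids is not None else None,
        ion_ids=[list(i) for i in ion_ids] if ion_ids is not None else None,
    )


# ---------------------------------------------------------------------------
# cross-validation and permutation test
# ---------------------------------------------------------------------------

def _fold_assignment(n: int, k_folds: int, rng: np.random.Generator,
                     strata=None) -> np.ndarray:
    """Seeded fold labels; round-robin within each stratum after shuffling."""
    folds = np.empty(n, dtype=int)
    if strata is None:
        order = rng.permutation(n)
        folds[order] = np.arange(n) % k_folds
    else:
        strata = np.asarray(strata)
        offset = 0
        for s in pd.unique(strata):
            idx = np.flatnonzero(strata == s)
            idx = rng.permutation(idx)
            folds[idx] = (np.arange(len(idx)) + offset) % k_folds
            offset += len(idx)
    return folds


def cross_validated_q2(blocks, y, n_ortho: int = 1, k_folds: int = 7,
                       seed: int = 0, strata=None, scaling: str = "uv") -> float:
    """Q2 = 1 - PRESS/SS_tot under seeded (optionally stratified) k-fold CV.

    Each fold refits the full iterative consensus model on the training
    samples only — including column scaling and kernel norms — and projects
    the held-out samples with those training parameters.
    """
    mats = _as_matrices(blocks)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if not 2 <= k_folds <= n:
        raise OplsError(f"k_folds must be in [2, {n}], got {k_folds}")
    rng = np.random.default_rng(seed)
    folds = _fold_assignment(n, k_folds, rng, strata)
    press = 0.0
    for f in range(k_folds):
        test = folds == f
        train = ~test
        if test.sum() == 0:
            continue
        model = fit_consensus_opls([m[train] for m in mats], y[train],
                                   n_ortho=n_ortho, scaling=scaling)
        y_hat = model.predict([m[test] for m in mats])
        press += float(np.sum((y[test] - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss_tot


@dataclass
class PermutationResult:
    observed_q2: float
    null_q2: list
    p_value: float


def permutation_test(blocks, y, n_ortho: int = 1, n_permutations: int = 99,
                     seed: int = 0, k_folds: int = 7, strata=None,
                     scaling: str = "uv") -> PermutationResult:
    """Permutation null for Q2: p = (1 + #{null >= observed}) / (1 + n_perm)."""
    if n_permutations < 19:
        raise OplsError("need at least 19 permutations")
    y = np.asarray(y, dtype=float).ravel()
    observed = cross_validated_q2(blocks, y, n_ortho, k_folds, seed, strata, scaling)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    null = []
    for _ in range(n_permutations):
        y_perm = rng.permutation(y)
        null.append(cross_validated_q2(blocks, y_perm, n_ortho, k_folds,
                                       seed, strata, scaling))
    p = (1 + sum(q >= observed for q in null)) / (1 + n_permutations)
    return PermutationResult(observed_q2=observed, null_q2=null, p_value=float(p))


# ---------------------------------------------------------------------------
# loadings
# ---------------------------------------------------------------------------

def back_project_loadings(model: MBOPLSModel, blocks) -> pd.DataFrame:
    """Per-ion coordinates on the predictive and orthogonal components.

    The coordinate of ion j in block b is the summed covariance of its
    column-scaled profile with the unit-norm predictive score,
    ``x_j' t / ||t||`` — for unit-variance scaling this equals
    ``sqrt(n - 1) * corr(x_j, t)``, so coordinates of strongly
    activity-tracking ions stand clear of the noise floor on a common scale
    across blocks.  Orthogonal coordinates use the same convention.
    """
    if model.t_pred is None:
        raise NotFittedError("model has no fitted scores")
    mats = _as_matrices(blocks)
    if len(mats) != len(model.block_names):
        raise AlignmentError("block count differs from the fitted model")
    t_hat = model.t_pred / np.linalg.norm(model.t_pred)
    orth_hats = [model.T_ortho[:, k] / np.linalg.norm(model.T_ortho[:, k])
                 for k in range(model.T_ortho.shape[1])]
    rows = []
    for b, X in enumerate(mats):
        Xs = model.scaling[b].apply(X)
        pred = Xs.T @ t_hat
        orth = [Xs.T @ th for th in orth_hats]
        ids = (model.ion_ids[b] if model.ion_ids is not None
               else [f"{model.block_names[b]}_{j}" for j in range(Xs.shape[1])])
        for j, ion in enumerate(ids):
            row = {"ion_id": ion, "block": model.block_names[b],
                   "predictive": float(pred[j])}
            for k, o in enumerate(orth):
                row[f"orthogonal_{k + 1}"] = float(o[j])
            rows.append(row)
    return pd.DataFrame(rows)
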