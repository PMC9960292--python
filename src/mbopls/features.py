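"""Feature-table container and the three-stage filter chain.

The multivariate matrix is assembled from the ions detected per ionization
mode by (1) restricting to the chromatographically reliable retention-time
window, (2) keeping only ions whose mean peak area exceeds an intensity
threshold in at least one organ group, and (3) collapsing co-eluting,
mutually correlated ions to a single representative.  The stages are applied
in that order, independently per block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class FeatureError(ValueError):
    pass


class AlignmentError(FeatureError):
    """Sample order of a block does not match the metadata."""


@dataclass
class FilterConfig:
    """Filter-chain constants.

    rt window and the intensity / correlation thresholds default to the
    standard untargeted workflow values: 0.5-5 min, peak area > 2000 in at
    least one organ, r >= 0.80 within an RT tolerance of 0.02 min.
    """

    rt_min: float = 0.5
    rt_max: float = 5.0
    intensity_threshold: float = 2000.0
    r_threshold: float = 0.80
    rt_tolerance: float = 0.02
    group_by: tuple = ("organ",)     # grouping columns for the intensity filter
    group_agg: str = "mean"          # or "max"
    absolute_correlation: bool = False
    log_correlation: bool = False    # correlate log1p(peak area) instead of raw

    def validate(self) -> None:
        if not self.rt_min < self.rt_max:
            raise FeatureError(f"rt_min must be < rt_max ({self.rt_min}, {self.rt_max})")
        if not 0.0 < self.r_threshold <= 1.0:
            raise FeatureError(f"r_threshold must be in (0, 1], got {self.r_threshold}")
        if self.intensity_threshold < 0:
            raise FeatureError("intensity_threshold must be >= 0")
        if self.rt_tolerance < 0:
            raise FeatureError("rt_tolerance must be >= 0")


class FeatureBlock:
    """samples x ions peak-area matrix for one ionization mode.

    ``intensities``: DataFrame indexed by sample_id with ion-id columns;
    ``ions``: DataFrame indexed by ion_id with ``mz`` and ``rt`` columns.
    """

    def __init__(self, intensities: pd.DataFrame, ions: pd.DataFrame, mode: str):
        if list(intensities.columns) != list(ions.index):
            raise FeatureError("intensity columns and ion table must list the same ions in order")
        if ions.index.has_duplicates:
            raise FeatureError("duplicate ion ids within a block")
        if (intensities.to_numpy() < 0).any():
            raise FeatureError("negative peak areas")
        self.intensities = intensities
        self.ions = ions
        self.mode = mode

    # -- basic accessors ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_ions(self) -> int:
        return self.intensities.shape[1]

    @property
    def ion_ids(self) -> list:
        return list(self.intensities.columns)

    def subset(self, ion_ids) -> "FeatureBlock":
        ion_ids = list(ion_ids)
        return FeatureBlock(self.intensities[ion_ids], self.ions.loc[ion_ids], self.mode)

    def values(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)

    # -- plain-text serialization -------------------------------------------
    # Layout: header = ion ids; two annotation rows keyed "#mz" / "#rt" in the
    # sample_id column; then one row per sample.
    def to_csv(self, path) -> None:
        header = pd.DataFrame(
            [self.ions["mz"].to_numpy(), self.ions["rt"].to_numpy()],
            index=pd.Index(["#mz", "#rt"], name="sample_id"),
            columns=self.intensities.columns,
        )
        pd.concat([header, self.intensities]).to_csv(path)

    @classmethod
    def from_csv(cls, path, mode: str) -> "FeatureBlock":
        raw = pd.read_csv(path, index_col=0)
        if not {"#mz", "#rt"}.issubset(raw.index):
            raise FeatureError(f"{path}: missing #mz / #rt annotation rows")
        ions = pd.DataFrame({
            "mz": raw.loc["#mz"].astype(float),
            "rt": raw.loc["#rt"].astype(float),
        })
        ions.index.name = "ion_id"
        intensities = raw.drop(index=["#mz", "#rt"]).astype(float)
        intensities.index.name = "sample_id"
        return cls(intensities=intensities, ions=ions, mode=mode)


def _check_alignment(block: FeatureBlock, metadata: pd.DataFrame) -> None:
    if list(block.intensities.index) != list(metadata["sample_id"]):
        raise AlignmentError(f"{block.mode}: sample order does not match metadata")


# ---------------------------------------------------------------------------
# filter stages
# ---------------------------------------------------------------------------

def restrict_rt(block: FeatureBlock, config: FilterConfig) -> FeatureBlock:
    """Keep ions with rt in the closed window [rt_min, rt_max], order preserved."""
    config.validate()
    keep = block.ions.index[(block.ions["rt"] >= config.rt_min)
                            & (block.ions["rt"] <= config.rt_max)]
    return block.subset(keep)


def filter_by_intensity(block: FeatureBlock, metadata: pd.DataFrame,
                        config: FilterConfig) -> FeatureBlock:
    """Keep ions whose aggregated peak area exceeds the threshold in >= 1 group.

    The grouping (default: organ, pooling sites) and aggregation (default:
    mean) follow the "retained in at least one condition" rule; the
    inequality is strict.
    """
    config.validate()
    _check_alignment(block, metadata)
    for col in config.group_by:
        if col not in metadata.columns:
            raise FeatureError(f"metadata lacks grouping column {col!r}")
    if "organ" in config.group_by:
        known = {"leaf", "stem_bark", "fruit"}
        bad = set(metadata["organ"]) - known
        if bad:
            raise FeatureError(f"unknown organ labels: {sorted(bad)}")
    if block.n_ions == 0:
        return block
    key = metadata[list(config.group_by)].astype(str).agg("/".join, axis=1).to_numpy()
    grouped = block.intensities.groupby(key)
    agg = grouped.max() if config.group_agg == "max" else grouped.mean()
    keep = block.intensities.columns[(agg > config.intensity_threshold).any(axis=0).to_numpy()]
    return block.subset(keep)


def _correlation_matrix(X: np.ndarray, log: bool) -> tuple[np.ndarray, list]:
    """Pearson r between ion columns; constant ions get r = 0 everywhere."""
    if log:
        X = np.log1p(X)
    sd = X.std(axis=0)
    constant = [int(j) for j in np.flatnonzero(sd == 0)]
    Xs = X - X.mean(axis=0)
    safe_sd = np.where(sd == 0, 1.0, sd)
    Xs = Xs / safe_sd
    r = (Xs.T @ Xs) / X.shape[0]
    if constant:
        r[constant, :] = 0.0
        r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    return r, constant


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def prune_correlated(block: FeatureBlock, config: FilterConfig):
    """Collapse co-eluting correlated ions to one representative each.

    Two ions are linked when their retention times differ by at most
    ``rt_tolerance`` *and* their Pearson correlation across samples is
    >= ``r_threshold`` (inclusive).  Within each connected component of that
    graph the ion with the highest median peak area is retained (ties broken
    by lexicographically smallest ion id); the rest are removed.  Constant
    ions correlate with nothing (r treated as 0) and are noted in the log.

    Returns ``(pruned block, removal_log)`` where the log has one row per
    removed ion: removed ion, its representative, and their correlation.
    """
    config.validate()
    if block.n_samples < 2:
        raise FeatureError("correlation pruning needs at least 2 samples")
    n = block.n_ions
    if n == 0:
        return block, pd.DataFrame(columns=["removed", "representative", "r"])
    X = block.values()
    rt = block.ions["rt"].to_numpy()
    r, constant = _correlation_matrix(X, config.log_correlation)
    rr = np.abs(r) if config.absolute_correlation else r

    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(rt[i] - rt[j]) <= config.rt_tolerance and rr[i, j] >= config.r_threshold:
                uf.union(i, j)

    comps: dict[int, list] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)

    medians = np.median(X, axis=0)
    ion_ids = np.asarray(block.ion_ids)
    keep, removed_rows = [], []
    for members in comps.values():
        if len(members) == 1:
            keep.append(members[0])
            continue
        rep = min(members, key=lambda j: (-medians[j], ion_ids[j]))
        keep.append(rep)
        for j in members:
            if j != rep:
                removed_rows.append({"removed": ion_ids[j],
                                     "representative": ion_ids[rep],
                                     "r": float(r[j, rep])})
    keep_ids = [iid for iid in block.ion_ids if iid in set(ion_ids[keep])]
    log = pd.DataFrame(removed_rows, columns=["removed", "representative", "r"])
    if constant:
        log.attrs["constant_ions"] = [str(ion_ids[j]) for j in constant]
    return block.subset(keep_ids), log


def assemble_blocks(neg: FeatureBlock, pos: FeatureBlock, metadata: pd.DataFrame,
                    config: FilterConfig | None = None):
    """Full filter chain (rt -> intensity -> correlation) per block.

    Returns ``(neg_filtered, pos_filtered, provenance)`` where provenance
    holds stage-wise ion counts and the removal logs.
    """
    config = config or FilterConfig()
    config.validate()
    _check_alignment(neg, metadata)
    _check_alignment(pos, metadata)
    provenance: dict = {}
    out = {}
    for block in (neg, pos):
        counts = {"input": block.n_ions}
        b = restrict_rt(block, config)
        counts["rt_window"] = b.n_ions
        b = filter_by_intensity(b, metadata, config)
        counts["intensity"] = b.n_ions
        b, log = prune_correlated(b, config)
        counts["correlation"] = b.n_ions
        provenance[block.mode] = {"counts": counts, "removal_log": log}
        out[block.mode] = b
    return out["neg"], out["pos"], provenance
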