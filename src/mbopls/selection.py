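"""Selection of bioactivity-associated ions from predictive-component loadings.

Because the predictive score is oriented so that corr(t_pred, y) > 0, ions
with large *positive* predictive coordinates are the ones whose peak areas
rise with inhibition; selection is one-sided above a coordinate threshold.
The default threshold of 5 matches the loading-coordinate convention used by
:func:`mbopls.opls.back_project_loadings` (sqrt(n-1) x correlation under unit
variance scaling), and a percentile-based alternative is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class SelectionError(ValueError):
    pass


@dataclass
class SelectionResult:
    table: pd.DataFrame      # ion_id, block, predictive, rank, selected
    threshold: float
    selected_ids: list

    def __len__(self) -> int:
        return len(self.selected_ids)


def select_active_ions(loadings: pd.DataFrame, threshold: float = 5.0,
                       percentile: float | None = None) -> SelectionResult:
    """One-sided selection: ions with predictive coordinate > threshold.

    ``percentile`` (e.g. 98) replaces the absolute threshold with the given
    percentile of the coordinates.  Ranks are dense, descending in the
    coordinate; ties broken by ion_id.  An empty selection is a valid result.
    """
    if loadings.empty:
        raise SelectionError("loading table is empty")
    table = loadings[["ion_id", "block", "predictive"]].copy()
    if percentile is not None:
        threshold = float(np.percentile(table["predictive"].to_numpy(), percentile))
    table = table.sort_values(["predictive", "ion_id"],
                              ascending=[False, True], kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["selected"] = table["predictive"] > threshold
    selected = table.loc[table["selected"], "ion_id"].tolist()
    return SelectionResult(table=table, threshold=float(threshold), selected_ids=selected)


def enrichment_by_group(selected_ids, block, metadata: pd.DataFrame,
                        group_by=("organ", "site")) -> pd.DataFrame:
    """Mean peak area of each selected ion per group cell, plus the argmax cell.

    ``block`` is a FeatureBlock whose samples align with ``metadata``; ions in
    ``selected_ids`` absent from the block raise a data error (selections from
    the other ionization mode should be filtered out by the caller via the
    loading table's block column).
    """
    selected_ids = list(selected_ids)
    missing = [i for i in selected_ids if i not in block.intensities.columns]
    if missing:
        raise SelectionError(f"ions not in block {block.mode!r}: {missing[:5]}")
    key = metadata[list(group_by)].astype(str).agg("/".join, axis=1).to_numpy()
    sub = block.intensities[selected_ids]
    means = sub.groupby(key).mean().T   # ions x cells
    means.index.name = "ion_id"
    means.columns = [str(c) for c in means.columns]
    out = means.copy()
    out["max_cell"] = means.idxmax(axis=1)
    return out.reset_index()
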