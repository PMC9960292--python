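"""Enzyme-inhibition assay arithmetic: inhibition %, per-sample summaries, IC50.

Inhibition is computed from 405 nm absorbances as
``(A_negative_control - A_sample) / A_negative_control * 100``.  Negative
values (sample absorbing more than the uninhibited control) are retained,
not clipped: they carry information for the multivariate response.

IC50 is offered by two routes: assumption-free monotone interpolation
(default) and a four-parameter logistic fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit
from sklearn.isotonic import IsotonicRegression


class AssayError(ValueError):
    pass


class AssayDataError(AssayError):
    """Structurally invalid plate data (missing controls, missing doses)."""


def inhibition_percent(a_negative_control: float, a_sample: float) -> float:
    """(A_neg - A_sample) / A_neg * 100; strictly decreasing in A_sample."""
    if not np.isfinite(a_negative_control) or a_negative_control <= 0:
        raise AssayError(f"negative-control absorbance must be > 0, got {a_negative_control}")
    return (a_negative_control - a_sample) / a_negative_control * 100.0


def summarize_activity(plate: pd.DataFrame, reference_concentration: float = 10.0) -> pd.DataFrame:
    """Per-extract mean/sd inhibition % at the reference concentration.

    Replicate absorbances are converted against the mean negative-control
    absorbance of the plate.  Returns a table with sample_id,
    inhibition_percent, sd_percent, n_replicates.
    """
    controls = plate[plate["role"] == "negative_control"]
    if controls.empty:
        raise AssayDataError("plate has no negative-control records")
    a_neg = float(controls["absorbance_405"].mean())
    extracts = plate[plate["role"] == "extract"]
    rows = []
    for sample_id, sub in extracts.groupby("sample_id", sort=False):
        at_ref = sub[np.isclose(sub["concentration"], reference_concentration)]
        if at_ref.empty:
            raise AssayDataError(
                f"sample {sample_id!r} has no record at {reference_concentration} ug/mL")
        inh = np.array([inhibition_percent(a_neg, a) for a in at_ref["absorbance_405"]])
        rows.append({
            "sample_id": sample_id,
            "inhibition_percent": float(inh.mean()),
            "sd_percent": float(inh.std(ddof=1)) if len(inh) > 1 else 0.0,
            "n_replicates": int(len(inh)),
        })
    return pd.DataFrame(rows)


@dataclass
class Ic50Result:
    sample_id: str | None
    ic50: float | None
    method: str
    converged: bool
    reason: str = ""


def _four_param_logistic(c, bottom, top, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (ic50 / np.maximum(c, 1e-12)) ** hill)


def estimate_ic50(concentrations, inhibitions, method: str = "monotone_interpolation",
                  sample_id: str | None = None) -> Ic50Result:
    """Concentration at 50% inhibition.

    ``monotone_interpolation``: isotonic regression of inhibition on dose,
    then linear interpolation on the dose pair bracketing 50%.  Undefined
    (converged=False) when the smoothed curve never crosses 50%.

    ``four_param_logistic``: least-squares 4PL fit inverted at 50%.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(inhibitions, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise AssayError("concentrations and inhibitions must be equal-length 1-D")
    if not (np.isfinite(c).all() and np.isfinite(y).all()):
        raise AssayError("non-finite assay inputs")
    order = np.argsort(c, kind="stable")
    c, y = c[order], y[order]
    n_distinct = len(np.unique(c))

    if method == "monotone_interpolation":
        if n_distinct < 2:
            raise AssayError("interpolation needs >= 2 distinct concentrations")
        iso = IsotonicRegression(increasing=True)
        y_fit = iso.fit_transform(c, y)
        # collapse replicate doses to their fitted value
        cu, idx = np.unique(c, return_index=True)
        yu = y_fit[idx]
        if yu.max() < 50.0:
            return Ic50Result(sample_id, None, method, False, "50% inhibition never reached")
        if yu.min() > 50.0:
            return Ic50Result(sample_id, None, method, False, "all doses above 50% inhibition")
        k = int(np.searchsorted(yu, 50.0, side="left"))
        if yu[k] == 50.0:
            ic50 = float(cu[k])
        else:
            c0, c1, y0, y1 = cu[k - 1], cu[k], yu[k - 1], yu[k]
            ic50 = float(c0 + (50.0 - y0) * (c1 - c0) / (y1 - y0)) if y1 > y0 else float(c1)
        return Ic50Result(sample_id, ic50, method, True)

    if method == "four_param_logistic":
        if n_distinct < 4:
            raise AssayError("logistic fit needs >= 4 distinct concentrations")
        pos = c > 0
        if pos.sum() < 3:
            raise AssayError("logistic fit needs >= 3 positive concentrations")
        mid = np.interp(50.0, np.sort(y), c[np.argsort(y)]) if y.max() > 50 else np.median(c[pos])
        p0 = [float(y.min()), float(y.max()), max(float(mid), 1e-3), 1.0]
        try:
            with warnings.catch_warnings():
                # exact (noise-free) fits make the covariance singular; harmless
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(_four_param_logistic, c, y, p0=p0, maxfev=20000)
        except RuntimeError:
            return Ic50Result(sample_id, None, method, False, "fit did not converge")
        bottom, top, ic50, hill = popt
        if not (bottom < 50.0 < top) or ic50 <= 0:
            return Ic50Result(sample_id, None, method, False, "50% outside fitted range")
        return Ic50Result(sample_id, float(ic50), method, True)

    raise AssayError(f"unknown IC50 method {method!r}")


def ic50_per_sample(plate: pd.DataFrame, method: str = "monotone_interpolation") -> pd.DataFrame:
    """IC50 per extract from its full concentration series (replicate means)."""
    controls = plate[plate["role"] == "negative_control"]
    if controls.empty:
        raise AssayDataError("plate has no negative-control records")
    a_neg = float(controls["absorbance_405"].mean())
    rows = []
    for sample_id, sub in plate[plate["role"] == "extract"].groupby("sample_id", sort=False):
        series = sub.groupby("concentration")["absorbance_405"].mean()
        inh = np.array([inhibition_percent(a_neg, a) for a in series.to_numpy()])
        res = estimate_ic50(series.index.to_numpy(), inh, method=method, sample_id=sample_id)
        rows.append({"sample_id": sample_id, "ic50": res.ic50,
                     "method": res.method, "converged": res.converged})
    return pd.DataFrame(rows)
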