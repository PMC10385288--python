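"""QC-anchored drift correction for LC-MS feature tables (QC-RLSC style).

Pooled-plasma QC samples interleaved through the run trace the instrument's
sensitivity drift. Per metabolite, a low-order locally weighted regression
of QC intensity on injection order gives a correction curve; dividing every
injection by the curve (anchored at the median of its QC fitted values)
removes the drift while preserving the overall intensity scale. QC
coefficients of variation before and after correction quantify technical
variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .tables import FeatureTable

__all__ = [
    "CorrectionCurve",
    "fit_qc_correction",
    "apply_correction",
    "qc_cv",
    "correct_table",
    "ms_feature_table",
]

META_COLS = ("sample_id", "injection_order", "is_qc")


@dataclass
class CorrectionCurve:
    """Normalized drift curve evaluated at every injection order."""

    orders: np.ndarray
    values: np.ndarray  # normalized: curve / median(curve at QC orders)
    anchor: float  # median of fitted QC values (raw scale)
    flagged: bool = False
    reason: str = ""

    def at(self, orders: np.ndarray) -> np.ndarray:
        orders = np.atleast_1d(np.asarray(orders, dtype=float))
        known = set(self.orders.tolist())
        missing = [o for o in orders if o not in known]
        if missing:
            raise ValueError(f"curve not defined at injection order(s) {missing}")
        idx = {o: i for i, o in enumerate(self.orders)}
        return np.array([self.values[idx[o]] for o in orders])


def _local_constant(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Degree-0 smoother: tricube-weighted local mean (lowess is degree-1 only)."""
    n = len(x)
    k = max(2, int(np.ceil(span * n)))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.sort(d)[min(k, n) - 1]
        w = np.clip(1 - (d / max(h, 1e-12)) ** 3, 0, None) ** 3
        out[i] = np.sum(w * y) / np.sum(w)
    return out


def fit_qc_correction(
    orders: np.ndarray,
    intensities: np.ndarray,
    is_qc: np.ndarray,
    span: float = 0.75,
    degree: int = 1,
) -> CorrectionCurve:
    """Fit the QC drift curve for one metabolite.

    Locally weighted regression (degree 1 by default, "low-order") of QC
    intensity on injection order, evaluated at QC orders and linearly
    interpolated to every other injection order. The normalized curve is
    the fit divided by the median of its values at QC orders. Metabolites
    with fewer than 3 QC points, or whose fitted curve is not strictly
    positive, are flagged and pass through uncorrected.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if degree not in (0, 1):
        raise ValueError("degree must be 0 or 1 (low-order smoother)")
    orders = np.asarray(orders, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    is_qc = np.asarray(is_qc, dtype=bool)
    if len(np.unique(orders)) != len(orders):
        raise ValueError("injection orders must be unique")
    ones = np.ones_like(orders)
    qx, qy = orders[is_qc], intensities[is_qc]
    if is_qc.sum() < 3:
        warnings.warn("fewer than 3 QC points; metabolite passed through uncorrected")
        return CorrectionCurve(orders, ones, float("nan"), True, "insufficient_qc")
    srt = np.argsort(qx)
    qx, qy = qx[srt], qy[srt]
    if degree == 1:
        fit_qc = lowess(qy, qx, frac=span, it=0, return_sorted=False)
    else:
        fit_qc = _local_constant(qx, qy, span)
    anchor = float(np.median(fit_qc))
    curve = np.interp(orders, qx, fit_qc)
    # linear extrapolation beyond the first/last QC, using the edge slopes
    if len(qx) >= 2:
        lo = orders < qx[0]
        hi = orders > qx[-1]
        s0 = (fit_qc[1] - fit_qc[0]) / (qx[1] - qx[0])
        s1 = (fit_qc[-1] - fit_qc[-2]) / (qx[-1] - qx[-2])
        curve[lo] = fit_qc[0] + s0 * (orders[lo] - qx[0])
        curve[hi] = fit_qc[-1] + s1 * (orders[hi] - qx[-1])
    if np.any(curve <= 0) or anchor <= 0:
        warnings.warn("fitted drift curve not strictly positive; metabolite flagged")
        return CorrectionCurve(orders, ones, anchor, True, "nonpositive_curve")
    return CorrectionCurve(orders, curve / anchor, anchor)


def apply_correction(
    orders: np.ndarray, intensities: np.ndarray, curve: CorrectionCurve
) -> np.ndarray:
    """corrected = raw / normalized curve (QC and study injections alike)."""
    return np.asarray(intensities, dtype=float) / curve.at(np.asarray(orders))


def qc_cv(intensities: np.ndarray, is_qc: np.ndarray) -> float:
    """Technical variation: CV% = 100 x SD/mean over QC intensities."""
    q = np.asarray(intensities, dtype=float)[np.asarray(is_qc, dtype=bool)]
    if len(q) < 2:
        raise ValueError("need at least 2 QC points for a CV")
    m = q.mean()
    if m == 0:
        raise ValueError("QC mean is zero; CV undefined")
    return float(100.0 * q.std(ddof=1) / m)


def correct_table(
    ms_table: pd.DataFrame, span: float = 0.75, degree: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drift-correct every metabolite column of a tidy MS run table.

    ``ms_table`` columns: ``sample_id, injection_order, is_qc`` plus one
    column per metabolite. Returns ``(corrected table, report)`` where the
    report lists per-metabolite pre/post QC CV and flags.
    """
    for col in META_COLS:
        if col not in ms_table.columns:
            raise ValueError(f"MS table missing column {col!r}")
    orders = ms_table["injection_order"].to_numpy()
    is_qc = ms_table["is_qc"].to_numpy(dtype=bool)
    metabs = [c for c in ms_table.columns if c not in META_COLS]
    corrected = ms_table.copy()
    rows = []
    for m in metabs:
        raw = ms_table[m].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = fit_qc_correction(orders, raw, is_qc, span=span, degree=degree)
        fixed = raw if curve.flagged else apply_correction(orders, raw, curve)
        corrected[m] = fixed
        rows.append(
            {
                "metabolite": m,
                "cv_pre": qc_cv(raw, is_qc),
                "cv_post": qc_cv(fixed, is_qc),
                "flagged": curve.flagged,
                "flag_reason": curve.reason,
            }
        )
    return corrected, pd.DataFrame(rows).set_index("metabolite")


def ms_feature_table(
    ms_table: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    impute_floor: bool = True,
) -> FeatureTable:
    """Study-sample rows of a (corrected) MS run as a FeatureTable.

    QC rows are dropped; variables are renamed ``ms_<metabolite>``. Missing
    intensities are imputed at half the per-metabolite minimum (a standard
    detection-floor convention), unless ``impute_floor`` is off.
    """
    study = ms_table.loc[~ms_table["is_qc"].astype(bool)]
    data = study.drop(columns=list(META_COLS)).copy()
    data.index = study["sample_id"].tolist()
    if impute_floor and data.isna().any().any():
        floor = data.min() / 2.0
        data = data.fillna(floor)
    data.columns = [f"ms_{c}" for c in data.columns]
    blocks = pd.Series("MS", index=data.columns)
    meta = metadata.reindex(data.index) if metadata is not None else pd.DataFrame(index=data.index)
    return FeatureTable(data, blocks, meta)
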