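"""Plate normalization, 4PL dose-response fitting and drug sensitivity scores.

High-throughput screens measure viability at (here) five concentrations per
drug spanning a 10,000-fold range. Raw luminescence is normalized per plate
to negative (vehicle) and positive (toxic) controls, giving percent
inhibition. A four-parameter logistic (4PL) curve

    y(x) = b + (t - b) / (1 + 10^{s (m - x)})

in x = log10(concentration [M]) is fitted per drug x cell line, with bottom
``b``, top ``t``, log10 IC50 ``m`` and Hill slope ``s > 0``. The drug
sensitivity score (DSS) is the normalized area of the fitted curve above an
activity threshold over the tested window, computed in closed form. The
differential score dDSS = DSS(resistant) - DSS(parental) quantifies acquired
sensitivity (positive) or co-resistance (negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseCurve",
    "normalize_plate",
    "logistic4",
    "fit_logistic",
    "compute_dss",
    "fit_screen",
    "dss_matrix",
    "compute_ddss",
]

LN10 = np.log(10.0)

#: fitting bounds: bottom may dip below 0 to absorb growth stimulation
BOUNDS_BOTTOM = (-20.0, 100.0)
BOUNDS_TOP = (0.0, 100.0)
BOUNDS_SLOPE = (1e-3, 10.0)


@dataclass
class DoseResponseCurve:
    """Fitted 4PL parameters and diagnostics for one drug x cell line."""

    drug_id: str
    cell_line_id: str
    bottom: float
    top: float
    log10_ic50: float
    slope: float
    fit_converged: bool
    residual_sse: float
    window: tuple[float, float]  # tested [x1, x2] in log10 molar

    def predict(self, x):
        return logistic4(x, self.bottom, self.top, self.log10_ic50, self.slope)


def logistic4(x, bottom, top, log10_ic50, slope):
    """4PL response at log10 dose ``x`` (increasing in x for slope > 0)."""
    x = np.asarray(x, dtype=float)
    # 1/(1+10^{s(m-x)}) via expit-style stable form
    z = slope * (log10_ic50 - x) * LN10
    with np.errstate(over="ignore"):
        frac = 1.0 / (1.0 + np.exp(z))
    return bottom + (top - bottom) * frac


def normalize_plate(readout: pd.DataFrame, min_controls: int = 2):
    """Convert raw per-plate signals to percent inhibition.

    inhibition = 100 * (neg_mean - signal) / (neg_mean - pos_mean), per plate,
    where neg is the vehicle (e.g. DMSO) control and pos the full-kill
    control. 0% = fully viable, 100% = fully inhibited.

    Parameters
    ----------
    readout
        Columns ``plate_id, well, drug_id, concentration_M, signal,
        well_type`` with well_type in {drug, neg_ctrl, pos_ctrl}. Extra
        columns (e.g. cell_line_id) are carried through.

    Returns
    -------
    (inhibition, controls)
        ``inhibition``: drug wells with an added ``inhibition`` column;
        ``controls``: per-plate control means and CVs.
    """
    required = {"plate_id", "well", "drug_id", "concentration_M", "signal", "well_type"}
    missing = required - set(readout.columns)
    if missing:
        raise ValueError(f"readout is missing columns: {sorted(missing)}")

    out_frames = []
    ctrl_rows = []
    for plate_id, plate in readout.groupby("plate_id", sort=False):
        neg = plate.loc[plate.well_type == "neg_ctrl", "signal"].to_numpy(float)
        pos = plate.loc[plate.well_type == "pos_ctrl", "signal"].to_numpy(float)
        if len(neg) < min_controls or len(pos) < min_controls:
            raise ValueError(
                f"plate {plate_id}: needs >= {min_controls} negative and positive "
                f"control wells (got {len(neg)} neg, {len(pos)} pos)"
            )
        neg_mean, pos_mean = neg.mean(), pos.mean()
        if neg_mean <= pos_mean:
            raise ValueError(
                f"plate {plate_id}: negative-control mean ({neg_mean:.3g}) <= "
                f"positive-control mean ({pos_mean:.3g}); inverted or failed plate"
            )
        drugs = plate[plate.well_type == "drug"].copy()
        drugs["inhibition"] = 100.0 * (neg_mean - drugs["signal"]) / (neg_mean - pos_mean)
        out_frames.append(drugs)
        ctrl_rows.append(
            {
                "plate_id": plate_id,
                "neg_mean": neg_mean,
                "pos_mean": pos_mean,
                "neg_cv": neg.std(ddof=1) / neg_mean if neg_mean != 0 else np.nan,
                "pos_cv": pos.std(ddof=1) / pos_mean if pos_mean != 0 else np.nan,
                "n_neg": len(neg),
                "n_pos": len(pos),
            }
        )
    inhibition = pd.concat(out_frames, ignore_index=True)
    controls = pd.DataFrame(ctrl_rows)
    return inhibition, controls


def _residuals(params, x, y):
    b, t, m, s = params
    return logistic4(x, b, t, m, s) - y


def fit_logistic(
    doses,
    inhibitions,
    drug_id: str = "",
    cell_line_id: str = "",
) -> DoseResponseCurve:
    """Least-squares 4PL fit over log10 dose with multi-start initialization.

    Five starts place the midpoint at each tested log-dose; the best-SSE
    solution wins (ties broken by the smallest slope). Bounds:
    b in [-20, 100], t in [0, 100], m in [x1-2, x2+2], s in (0, 10].
    A run in which no start converges returns a flagged curve whose DSS is
    treated as 0 downstream.
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(inhibitions, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive (molar)")
    if not np.all(np.isfinite(y)):
        raise ValueError("inhibitions must be finite")
    if len(np.unique(doses)) < 4:
        raise ValueError("need >= 4 distinct doses to fit a 4PL curve")
    x = np.log10(doses)
    order = np.argsort(x)
    x, y = x[order], y[order]
    x1, x2 = float(x[0]), float(x[-1])

    if np.ptp(y) == 0.0:
        # flat response: t = b (within bounds), trivially converged
        bflat = float(np.clip(y[0], *BOUNDS_BOTTOM))
        tflat = float(np.clip(y[0], *BOUNDS_TOP))
        return DoseResponseCurve(
            drug_id, cell_line_id,
            bottom=bflat, top=tflat, log10_ic50=0.5 * (x1 + x2),
            slope=1.0, fit_converged=True,
            residual_sse=float(np.sum((y - tflat) ** 2)) if y[0] >= 0 else float(np.sum((y - bflat) ** 2)),
            window=(x1, x2),
        )

    lo = np.array([BOUNDS_BOTTOM[0], BOUNDS_TOP[0], x1 - 2.0, BOUNDS_SLOPE[0]])
    hi = np.array([BOUNDS_BOTTOM[1], BOUNDS_TOP[1], x2 + 2.0, BOUNDS_SLOPE[1]])
    b0 = float(np.clip(y.min(), *BOUNDS_BOTTOM))
    t0 = float(np.clip(y.max(), *BOUNDS_TOP))

    best = None
    for m0 in x:
        p0 = np.clip(np.array([b0, t0, m0, 1.0]), lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(
                _residuals, p0, args=(x, y), bounds=(lo, hi),
                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=5000,
            )
        except Exception:
            continue
        # status 0 (iteration cap) still carries a usable bounded solution:
        # near-flat noisy profiles zigzag at the slope bound without moving SSE
        if not np.all(np.isfinite(res.x)) or not np.isfinite(res.cost):
            continue
        sse = float(np.sum(res.fun**2))
        cand = (sse, float(res.x[3]), res.x)
        if best is None or cand[0] < best[0] - 1e-12 or (
            abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1]
        ):
            best = cand
    if best is None:
        return DoseResponseCurve(
            drug_id, cell_line_id, bottom=0.0, top=0.0, log10_ic50=0.5 * (x1 + x2),
            slope=1.0, fit_converged=False, residual_sse=float("inf"), window=(x1, x2),
        )
    sse, _, p = best
    b, t, m, s = (float(v) for v in p)
    if t < b:  # bounds allow b up to 100; enforce b <= t by collapsing
        b = t
    return DoseResponseCurve(
        drug_id, cell_line_id, bottom=b, top=t, log10_ic50=m, slope=s,
        fit_converged=True, residual_sse=sse, window=(x1, x2),
    )


def _log1p10(u):
    """ln(1 + 10^u), overflow-safe."""
    return np.logaddexp(0.0, u * LN10)


def compute_dss(curve: DoseResponseCurve, amin: float = 10.0) -> float:
    """Drug sensitivity score from fitted 4PL parameters, in closed form.

    DSS = 100 * I / ((100 - amin) * (x2 - x1)) with
    I = integral over [x1, x2] of max(y(x) - amin, 0) dx, using the 4PL
    antiderivative  (t-b)/(s ln10) * ln(1 + 10^{s(x-m)})  and the analytic
    threshold crossing x_A = m - (1/s) log10((t-b)/(amin-b) - 1).

    ``amin`` is the activity threshold in percent inhibition (default 10):
    response below it never contributes. Non-converged curves score 0 with a
    warning.
    """
    if not 0.0 < amin < 100.0:
        raise ValueError("amin must be in (0, 100)")
    if not curve.fit_converged:
        warnings.warn(
            f"curve {curve.drug_id}/{curve.cell_line_id} did not converge; DSS set to 0",
            stacklevel=2,
        )
        return 0.0
    b, t, m, s = curve.bottom, curve.top, curve.log10_ic50, curve.slope
    x1, x2 = curve.window
    t = min(t, 100.0)  # integration clamp; fitting bounds already enforce this
    if t <= amin:
        return 0.0
    if b >= amin:
        x_lo = x1
    else:
        # y increasing in x (s > 0); solve y(x_A) = amin
        x_a = m - np.log10((t - b) / (amin - b) - 1.0) / s
        if x_a >= x2:
            return 0.0
        x_lo = max(x1, x_a)
    width = x2 - x_lo
    integral = (b - amin) * width + (t - b) / (s * LN10) * (
        _log1p10(s * (x2 - m)) - _log1p10(s * (x_lo - m))
    )
    integral = max(float(integral), 0.0)
    return 100.0 * integral / ((100.0 - amin) * (x2 - x1))


def fit_screen(inhibition: pd.DataFrame, amin: float = 10.0) -> pd.DataFrame:
    """Fit every drug x cell line in a normalized screen and score DSS.

    Expects columns ``drug_id, cell_line_id, concentration_M, inhibition``.
    Returns one row per drug x cell line with the fitted parameters,
    diagnostics and DSS.
    """
    rows = []
    for (drug, line), grp in inhibition.groupby(["drug_id", "cell_line_id"], sort=True):
        curve = fit_logistic(
            grp["concentration_M"].to_numpy(), grp["inhibition"].to_numpy(),
            drug_id=str(drug), cell_line_id=str(line),
        )
        rows.append(
            {
                "drug_id": drug,
                "cell_line_id": line,
                "bottom": curve.bottom,
                "top": curve.top,
                "log10_ic50": curve.log10_ic50,
                "slope": curve.slope,
                "fit_converged": curve.fit_converged,
                "residual_sse": curve.residual_sse,
                "x1": curve.window[0],
                "x2": curve.window[1],
                "dss": compute_dss(curve, amin=amin),
            }
        )
    return pd.DataFrame(rows)


def dss_matrix(curves: pd.DataFrame) -> pd.DataFrame:
    """Pivot a fit_screen table to a drugs x cell-lines DSS matrix."""
    return curves.pivot(index="drug_id", columns="cell_line_id", values="dss")


def compute_ddss(dss: pd.DataFrame, pairs: dict[str, tuple[str, str]]) -> pd.DataFrame:
    """Differential DSS per resistant/parental pair.

    ``pairs`` maps pair_id -> (resistant_line, parental_line). Positive dDSS
    means the resistant line gained sensitivity; negative means
    co-resistance. A drug missing in either member yields NaN (excluded from
    downstream statistics).
    """
    cols = {}
    for pair_id, (res, par) in pairs.items():
        if res not in dss.columns or par not in dss.columns:
            raise KeyError(f"pair {pair_id}: cell line missing from DSS matrix")
        cols[pair_id] = dss[res] - dss[par]
    return pd.DataFrame(cols, index=dss.index)
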