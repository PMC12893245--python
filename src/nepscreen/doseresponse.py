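"""Enzymatic-inhibition analytics: progress-curve slopes, percent
inhibition, four-parameter-logistic (4PL) dose–response fits, viability.

The fluorometric assay reads product fluorescence at fixed intervals
(e.g. every 20 min over 60 min); the initial-rate estimate is the
ordinary-least-squares slope of RFU versus time.  Percent inhibition of
a test well relative to an uninhibited control is

    inhibition% = 100 * (slope_ctrl - slope_test) / slope_ctrl

and the potency (IC50) is the midpoint of a 4PL curve

    y(c) = bottom + (top - bottom) / (1 + (IC50 / c)**hill)

fitted to inhibition versus concentration by nonlinear least squares on
the log-concentration axis.  Inhibition values are never clamped:
values below 0% or above 100% (aggregation artifacts, activation) are
preserved and flagged by the caller's QC, not silently edited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KineticTrace",
    "InhibitionPoint",
    "progress_slope",
    "inhibition_percent",
    "viability_percent",
    "traces_to_inhibition",
    "DoseResponseModel",
    "DoseResponseResults",
    "fit_ic50",
]


@dataclass
class KineticTrace:
    """One well's fluorescence progress curve."""

    times: np.ndarray  # minutes
    rfu: np.ndarray
    well_id: str = ""
    condition: str = "test"  # "control" or "test"
    compound_id: str = ""
    concentration: float = np.nan  # µM

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.times.size < 2:
            raise ValueError("a kinetic trace needs at least 2 timepoints")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.shape != self.rfu.shape:
            raise ValueError("times and rfu must have the same length")


@dataclass(frozen=True)
class InhibitionPoint:
    compound_id: str
    concentration: float  # µM
    inhibition_pct: float
    out_of_range: bool = False  # <0% or >100%, preserved not clamped


def progress_slope(trace: KineticTrace) -> tuple[float, float]:
    """OLS slope (RFU/min) of the progress curve, with standard error.

    All timepoints are used; no linearity-window selection.
    """
    t, y = trace.times, trace.rfu
    res = stats.linregress(t, y)
    return float(res.slope), float(res.stderr)


def inhibition_percent(slope_control: float, slope_test: float) -> float:
    """Percent inhibition from paired control/test slopes."""
    if slope_control == 0:
        raise ValueError("control slope is zero: assay failure, cannot normalise")
    return 100.0 * (slope_control - slope_test) / slope_control


def viability_percent(od570_treated: float, od570_control: float) -> float:
    """Cell viability % = 100 * OD570(treated) / OD570(control).

    Values above 100% (growth promotion) are legitimate and returned
    as-is.
    """
    if od570_control <= 0:
        raise ValueError("control OD570 must be positive")
    return 100.0 * od570_treated / od570_control


def traces_to_inhibition(
    df: pd.DataFrame, control_label: str = "DMSO"
) -> pd.DataFrame:
    """Reduce a long-format trace table to per-well inhibition points.

    Expects columns well_id, compound_id, concentration_uM, time_min,
    rfu.  The control slope is the mean OLS slope over wells whose
    compound_id equals ``control_label``.
    """
    slopes = []
    for (well, cpd, conc), grp in df.groupby(
        ["well_id", "compound_id", "concentration_uM"], sort=False
    ):
        trace = KineticTrace(
            grp["time_min"].to_numpy(), grp["rfu"].to_numpy(), well_id=str(well)
        )
        s, _ = progress_slope(trace)
        slopes.append({"well_id": well, "compound_id": cpd,
                       "concentration_uM": conc, "slope": s})
    sl = pd.DataFrame(slopes)
    ctrl = sl[sl["compound_id"] == control_label]
    if ctrl.empty:
        raise ValueError(f"no control wells labelled {control_label!r}")
    slope_ctrl = ctrl["slope"].mean()
    out = sl[sl["compound_id"] != control_label].copy()
    out["inhibition_pct"] = [
        inhibition_percent(slope_ctrl, s) for s in out["slope"]
    ]
    out["out_of_range"] = (out["inhibition_pct"] < 0) | (out["inhibition_pct"] > 100)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# 4PL dose-response model
# ---------------------------------------------------------------------------

def _four_pl(logc: np.ndarray, bottom: float, top: float, log_ic50: float,
             hill: float) -> np.ndarray:
    # (IC50/c)**hill == 10**(hill*(logIC50 - logc))
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ic50 - logc)))


class DoseResponseModel:
    """Four-parameter logistic dose–response model.

    Parameters
    ----------
    concentration : array, µM (strictly positive; zero-dose points
        belong to the control normalisation, not the log-domain fit)
    response : array, percent inhibition
    fix_bottom, fix_top : optionally pin the lower/upper plateau
        (e.g. 0 and 100 for a constrained fit).
    """

    def __init__(
        self,
        concentration: Sequence[float],
        response: Sequence[float],
        compound_id: str = "",
        fix_bottom: float | None = None,
        fix_top: float | None = None,
    ) -> None:
        conc = np.asarray(concentration, dtype=float)
        resp = np.asarray(response, dtype=float)
        keep = conc > 0
        if not np.all(keep):
            warnings.warn(
                "zero/negative concentrations excluded from the log-domain fit",
                RuntimeWarning, stacklevel=2,
            )
        self.concentration = conc[keep]
        self.response = resp[keep]
        self.compound_id = compound_id
        self.fix_bottom = fix_bottom
        self.fix_top = fix_top
        if np.unique(self.concentration).size < 4:
            raise ValueError("need at least 4 distinct positive concentrations")
        if np.allclose(self.response, 0.0):
            raise ValueError("no inhibition signal: all responses are zero")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        conc_col: str = "concentration_uM",
        resp_col: str = "inhibition_pct",
        **kwargs,
    ) -> "DoseResponseModel":
        return cls(df[conc_col].to_numpy(), df[resp_col].to_numpy(), **kwargs)

    # parameter vector layout depends on which plateaus are fixed
    def _split(self, theta):
        i = 0
        if self.fix_bottom is None:
            bottom = theta[i]; i += 1
        else:
            bottom = self.fix_bottom
        if self.fix_top is None:
            top = theta[i]; i += 1
        else:
            top = self.fix_top
        log_ic50, hill = theta[i], theta[i + 1]
        return bottom, top, log_ic50, hill

    def _residuals(self, theta, logc, y):
        return _four_pl(logc, *self._split(theta)) - y

    def fit(self, n_starts: int = 5) -> "DoseResponseResults":
        """Nonlinear least squares with multi-start over the IC50 seed.

        ``n_starts`` log-spaced IC50 starting values spanning the
        concentration range; the best-residual solution is kept.
        """
        logc = np.log10(self.concentration)
        y = self.response
        lo, hi = logc.min(), logc.max()
        start_log_ic50 = np.linspace(lo, hi, n_starts)

        free_bottom = self.fix_bottom is None
        free_top = self.fix_top is None
        lower, upper, base = [], [], []
        if free_bottom:
            lower.append(-np.inf); upper.append(np.inf); base.append(min(y.min(), 0.0))
        if free_top:
            lower.append(-np.inf); upper.append(np.inf); base.append(max(y.max(), 100.0))
        lower += [lo - 3.0, 0.05]
        upper += [hi + 3.0, 10.0]

        best = None
        for s in start_log_ic50:
            x0 = np.array(base + [s, 1.0])
            try:
                sol = optimize.least_squares(
                    self._residuals, x0, bounds=(lower, upper), args=(logc, y)
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol

        if best is None or not best.success:
            return DoseResponseResults(self, best, converged=False)
        return DoseResponseResults(self, best, converged=True)


class DoseResponseResults:
    """Fitted 4PL parameters, asymptotic standard errors, diagnostics."""

    def __init__(self, model: DoseResponseModel, sol, converged: bool) -> None:
        self.model = model
        self.converged = converged
        if sol is None:
            self.bottom = self.top = self.ic50 = self.hill = np.nan
            self.bse = {}
            self.resid = np.full_like(model.response, np.nan)
            return
        bottom, top, log_ic50, hill = model._split(sol.x)
        self.bottom, self.top = float(bottom), float(top)
        self.ic50 = float(10.0 ** log_ic50)
        self.hill = float(hill)
        self.resid = sol.fun
        self.ssr = float(2.0 * sol.cost)

        names = []
        if model.fix_bottom is None:
            names.append("bottom")
        if model.fix_top is None:
            names.append("top")
        names += ["log_ic50", "hill"]
        self.bse = dict.fromkeys(names + ["ic50"], np.nan)
        if converged:
            dof = max(len(model.response) - len(sol.x), 1)
            s2 = self.ssr / dof
            try:
                cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
                se = np.sqrt(np.diag(cov))
                self.bse = dict(zip(names, map(float, se)))
                # delta method on ic50 = 10**log_ic50
                self.bse["ic50"] = float(
                    se[names.index("log_ic50")] * np.log(10.0) * self.ic50
                )
            except np.linalg.LinAlgError:
                self.bse = dict.fromkeys(names + ["ic50"], np.nan)

    def predict(self, concentration: Sequence[float]) -> np.ndarray:
        logc = np.log10(np.asarray(concentration, dtype=float))
        return _four_pl(logc, self.bottom, self.top, np.log10(self.ic50), self.hill)

    def conf_int_ic50(self, alpha: float = 0.05) -> tuple[float, float]:
        """Asymptotic CI on IC50, computed on the log scale."""
        se = self.bse.get("log_ic50", np.nan)
        if not np.isfinite(se):
            return (np.nan, np.nan)
        dof = max(len(self.model.response) - 4, 1)
        q = stats.t.ppf(1 - alpha / 2, dof)
        log_ic50 = np.log10(self.ic50)
        return (10.0 ** (log_ic50 - q * se), 10.0 ** (log_ic50 + q * se))

    def summary(self) -> str:
        lines = [
            "Dose-response fit (4PL)",
            "=" * 40,
            f"compound:      {self.model.compound_id or '-'}",
            f"n points:      {len(self.model.response)}",
            f"converged:     {self.converged}",
            f"IC50 (µM):     {self.ic50:.4g}  (SE {self.bse.get('ic50', np.nan):.3g})",
            f"Hill slope:    {self.hill:.4g}",
            f"bottom (%):    {self.bottom:.4g}"
            + ("  [fixed]" if self.model.fix_bottom is not None else ""),
            f"top (%):       {self.top:.4g}"
            + ("  [fixed]" if self.model.fix_top is not None else ""),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.concentration
        ax.semilogx(c, self.model.response, "o", label="data")
        grid = np.logspace(np.log10(c.min()) - 0.5, np.log10(c.max()) + 0.5, 200)
        ax.semilogx(grid, self.predict(grid), "-", label="4PL fit")
        ax.axvline(self.ic50, ls="--", color="grey", lw=0.8)
        ax.set_xlabel("concentration (µM)")
        ax.set_ylabel("inhibition (%)")
        ax.legend()
        return ax


def fit_ic50(
    points: Sequence[InhibitionPoint] | pd.DataFrame,
    fix_bottom: float | None = None,
    fix_top: float | None = None,
) -> DoseResponseResults:
    """Fit a 4PL dose–response curve to inhibition points."""
    if isinstance(points, pd.DataFrame):
        model = DoseResponseModel.from_dataframe(
            points, fix_bottom=fix_bottom, fix_top=fix_top,
            compound_id=str(points["compound_id"].iloc[0])
            if "compound_id" in points else "",
        )
    else:
        model = DoseResponseModel(
            [p.concentration for p in points],
            [p.inhibition_pct for p in points],
            compound_id=points[0].compound_id if points else "",
            fix_bottom=fix_bottom,
            fix_top=fix_top,
        )
    return model.fit()
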