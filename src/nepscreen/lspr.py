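"""1:1 Langmuir binding kinetics for LSPR/SPR sensorgrams.

The 1:1 model for an analyte at concentration ``C`` flowed over an
immobilised binding partner obeys

    dR/dt = kon * C * (Rmax - R) - koff * R

whose closed-form solution during association (analyte present,
``t <= injection_end``, with R(0) = 0) is

    R(t) = Req * (1 - exp(-(kon*C + koff) * t)),
    Req  = Rmax * C / (C + KD),   KD = koff / kon

and during dissociation (buffer only)

    R(t) = R(injection_end) * exp(-koff * (t - injection_end)).

``fit_1to1`` / ``BindingKineticsModel`` fit kon, koff and Rmax
*globally* across a concentration series, with one constant baseline
offset per curve as the only nuisance parameter; the reported KD is
always koff/kon by construction.  Units: C in µM, kon in 1/(µM·s)
(multiply by 1e6 for 1/(M·s)), koff in 1/s, KD in µM.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "Sensorgram",
    "model_response",
    "BindingKineticsModel",
    "BindingKineticsResults",
    "fit_1to1",
    "read_sensorgram_csv",
]


@dataclass
class Sensorgram:
    """One injection's response-versus-time record."""

    analyte_id: str
    concentration: float  # µM
    times: np.ndarray  # s, strictly increasing
    response: np.ndarray  # RU
    injection_end: float  # s, association/dissociation boundary

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (self.times[0] <= self.injection_end <= self.times[-1]):
            raise ValueError("injection_end must lie within the time range")
        if self.concentration <= 0:
            raise ValueError("analyte concentration must be positive")


def model_response(
    kon: float,
    koff: float,
    rmax: float,
    concentration: float,
    t: np.ndarray | float,
    injection_end: float,
) -> np.ndarray:
    """Closed-form 1:1 response at time(s) ``t`` (seconds from injection)."""
    if min(kon, koff, rmax) <= 0:
        raise ValueError("kon, koff and Rmax must be positive")
    t = np.asarray(t, dtype=float)
    kd = koff / kon
    req = rmax * concentration / (concentration + kd)
    kobs = kon * concentration + koff
    r_assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, injection_end)))
    r_end = req * (1.0 - np.exp(-kobs * injection_end))
    r_dissoc = r_end * np.exp(-koff * np.maximum(t - injection_end, 0.0))
    return np.where(t <= injection_end, r_assoc, r_dissoc)


class BindingKineticsModel:
    """Global 1:1 fit across a sensorgram concentration series.

    Shared parameters kon, koff, Rmax (log-parametrised for
    positivity) plus one constant offset per curve.  A single-curve
    fit is permitted but flagged ill-conditioned.
    """

    def __init__(self, sensorgrams: Sequence[Sensorgram]) -> None:
        if len(sensorgrams) == 0:
            raise ValueError("need at least one sensorgram")
        if all(np.allclose(s.response, 0.0) for s in sensorgrams):
            raise ValueError("no binding signal: all responses are zero")
        if any(s.response.max() < 0 for s in sensorgrams):
            warnings.warn("negative-going sensorgram data", RuntimeWarning,
                          stacklevel=2)
        self.sensorgrams = list(sensorgrams)
        self.ill_conditioned = len(sensorgrams) < 2
        if self.ill_conditioned:
            warnings.warn(
                "single-curve kinetic fit is ill-conditioned; supply a "
                "concentration series", RuntimeWarning, stacklevel=2,
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BindingKineticsModel":
        """Build from a long table (analyte_id, concentration_uM, time_s,
        response_RU, phase) where phase is 'association'/'dissociation'."""
        grams = []
        for (aid, conc), grp in df.groupby(["analyte_id", "concentration_uM"],
                                           sort=False):
            grp = grp.sort_values("time_s")
            assoc = grp[grp["phase"] == "association"]
            inj_end = float(assoc["time_s"].max()) if len(assoc) else float(
                grp["time_s"].iloc[0])
            grams.append(Sensorgram(str(aid), float(conc),
                                    grp["time_s"].to_numpy(),
                                    grp["response_RU"].to_numpy(), inj_end))
        return cls(grams)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        # clip keeps exploratory LM steps finite; bounds are far outside
        # any physically plausible rate or capacity
        log_kon, log_koff, log_rmax = np.clip(theta[:3], -30.0, 30.0)
        offsets = theta[3:]
        kon, koff, rmax = np.exp([log_kon, log_koff, log_rmax])
        out = []
        for s, off in zip(self.sensorgrams, offsets):
            pred = model_response(kon, koff, rmax, s.concentration, s.times,
                                  s.injection_end) + off
            out.append(pred - s.response)
        return np.concatenate(out)

    def fit(
        self,
        kon_starts: Sequence[float] = (1e-3, 1e-2, 1e-1),
        koff_starts: Sequence[float] = (1e-3, 1e-2, 1e-1),
    ) -> "BindingKineticsResults":
        """Global least squares with multi-start over a log-grid of
        (kon, koff); the lowest-residual solution is kept."""
        rmax0 = max(s.response.max() for s in self.sensorgrams)
        rmax0 = max(rmax0, 1e-6)
        n_off = len(self.sensorgrams)
        best = None
        for kon0, koff0 in itertools.product(kon_starts, koff_starts):
            x0 = np.concatenate(
                [np.log([kon0, koff0, rmax0]), np.zeros(n_off)]
            )
            try:
                sol = optimize.least_squares(self._residuals, x0, method="lm")
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        converged = best is not None and best.success
        return BindingKineticsResults(self, best, converged)


class BindingKineticsResults:
    """Fitted kinetic constants with asymptotic SEs; KD = koff/kon."""

    def __init__(self, model: BindingKineticsModel, sol, converged: bool) -> None:
        self.model = model
        self.converged = converged
        names = ["kon", "koff", "rmax"]
        if sol is None:
            self.kon = self.koff = self.rmax = self.kd = np.nan
            self.offsets = np.full(len(model.sensorgrams), np.nan)
            self.bse = dict.fromkeys(names + ["kd"], np.nan)
            return
        self.kon, self.koff, self.rmax = map(float, np.exp(sol.x[:3]))
        self.kd = self.koff / self.kon
        self.offsets = np.asarray(sol.x[3:], dtype=float)
        self.ssr = float(2.0 * sol.cost)
        self.bse = dict.fromkeys(names + ["kd"], np.nan)
        if converged:
            n = sum(len(s.times) for s in model.sensorgrams)
            dof = max(n - len(sol.x), 1)
            s2 = self.ssr / dof
            try:
                cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
                se_log = np.sqrt(np.diag(cov)[:3])
                # delta method: SE(exp(x)) = exp(x) * SE(x)
                self.bse = {
                    "kon": self.kon * se_log[0],
                    "koff": self.koff * se_log[1],
                    "rmax": self.rmax * se_log[2],
                    # KD = exp(log_koff - log_kon)
                    "kd": self.kd * float(np.sqrt(
                        cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])),
                }
            except np.linalg.LinAlgError:
                pass

    @property
    def kon_per_molar(self) -> float:
        """kon converted to 1/(M·s)."""
        return self.kon * 1e6

    def req(self, concentration: float) -> float:
        """Equilibrium response at a concentration: Rmax·C/(C+KD)."""
        return self.rmax * concentration / (concentration + self.kd)

    def predict(self, sensorgram: Sensorgram) -> np.ndarray:
        return model_response(self.kon, self.koff, self.rmax,
                              sensorgram.concentration, sensorgram.times,
                              sensorgram.injection_end)

    def summary(self) -> str:
        lines = [
            "1:1 binding kinetics (global fit)",
            "=" * 40,
            f"curves:     {len(self.model.sensorgrams)} "
            f"({', '.join(f'{s.concentration:g}' for s in self.model.sensorgrams)} µM)",
            f"converged:  {self.converged}"
            + ("  [ill-conditioned: single curve]"
               if self.model.ill_conditioned else ""),
            f"kon:   {self.kon:.4g} /(µM·s)  = {self.kon_per_molar:.4g} /(M·s)"
            f"  (SE {self.bse['kon']:.3g})",
            f"koff:  {self.koff:.4g} /s  (SE {self.bse['koff']:.3g})",
            f"KD:    {self.kd:.4g} µM  (SE {self.bse['kd']:.3g})",
            f"Rmax:  {self.rmax:.4g} RU  (SE {self.bse['rmax']:.3g})",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for s, off in zip(self.model.sensorgrams, self.offsets):
            ax.plot(s.times, s.response, ".", ms=2)
            ax.plot(s.times, self.predict(s) + off, "-", lw=1,
                    label=f"{s.concentration:g} µM")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("response (RU)")
        ax.legend(title="analyte")
        return ax


def fit_1to1(sensorgrams: Sequence[Sensorgram]) -> BindingKineticsResults:
    """Globally fit a 1:1 model to a sensorgram series."""
    return BindingKineticsModel(sensorgrams).fit()


def read_sensorgram_csv(path) -> BindingKineticsModel:
    """Read the long-format sensorgram CSV into a kinetics model."""
    return BindingKineticsModel.from_dataframe(pd.read_csv(path))
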