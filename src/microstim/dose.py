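"""Dose-response curves for fraction activated vs agonist concentration.

The model is a logistic in log10 dose with a fixed background rate b (the
calibration false-positive rate):

    p(C) = b + (1 - b) * logistic(k * (log10 C - log10 EC50))

fitted by maximum binomial likelihood over (log10 EC50, log k), with a
multi-start over a log-spaced EC50 grid to avoid local optima.  The
background is fixed rather than free because experimental panels rarely
carry more than half a dozen doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, xlogy

__all__ = ["DoseResponseModel", "DoseCurve", "fit_dose_curve", "threshold_crossing"]


@dataclass(frozen=True)
class DoseCurve:
    """Fitted activation curve: EC50 (nM), slope, fixed background, data and
    binomial deviance."""

    ec50_nM: float
    slope: float
    background: float
    data: pd.DataFrame
    deviance: float
    n_starts: int

    def predict(self, conc_nM):
        conc = np.asarray(conc_nM, dtype=float)
        with np.errstate(divide="ignore"):
            x = np.log10(conc)
        p = self.background + (1 - self.background) * expit(
            self.slope * (x - np.log10(self.ec50_nM))
        )
        return p if p.ndim else float(p)

    def threshold_crossing(self, level: float = 0.5) -> float:
        return threshold_crossing(self, level)

    def summary(self) -> str:
        lines = [
            "Dose-response fit (logistic in log10 dose, binomial likelihood)",
            f"  EC50        : {self.ec50_nM:.4g} nM",
            f"  slope       : {self.slope:.4g} per log10(nM)",
            f"  background  : {self.background:.3g} (fixed)",
            f"  deviance    : {self.deviance:.4g} on {len(self.data) - 2} df",
            f"  doses       : {len(self.data)}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out["fitted"] = self.predict(out["conc_nM"].to_numpy())
        return out


class DoseResponseModel:
    """Binomial dose-response model over (conc, n, n_activated) points.

    ``fit()`` returns a :class:`DoseCurve` results object.  The fit is
    deterministic: a fixed log-spaced grid of EC50 starting values
    (spanning the dosed range) and two slope starts feed L-BFGS-B, and the
    best converged optimum wins.
    """

    def __init__(self, points, fixed_background: float = 0.05):
        data = pd.DataFrame(points, columns=["conc_nM", "n", "n_activated"])
        if (data["conc_nM"] <= 0).any():
            raise ValueError("concentrations must be positive")
        if (data["n"] <= 0).any() or (data["n_activated"] < 0).any():
            raise ValueError("counts must be valid")
        if (data["n_activated"] > data["n"]).any():
            raise ValueError("n_activated cannot exceed n")
        if data["conc_nM"].nunique() < 3:
            raise ValueError("need at least 3 distinct concentrations")
        if not (0 <= fixed_background < 1):
            raise ValueError("fixed_background must be in [0, 1)")
        k = data["n_activated"].sum()
        if k == 0 or k == data["n"].sum():
            raise ValueError(
                "all-zero or all-one responses: activation threshold unidentifiable"
            )
        self.data = data
        self.background = fixed_background

    def _nll(self, theta: np.ndarray) -> float:
        log10_ec50, log_slope = theta
        slope = np.exp(log_slope)
        x = np.log10(self.data["conc_nM"].to_numpy())
        p = self.background + (1 - self.background) * expit(slope * (x - log10_ec50))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        k = self.data["n_activated"].to_numpy()
        n = self.data["n"].to_numpy()
        return float(-(xlogy(k, p) + xlogy(n - k, 1 - p)).sum())

    def fit(self, n_grid: int = 7) -> DoseCurve:
        conc = self.data["conc_nM"].to_numpy()
        lo, hi = np.log10(conc.min()), np.log10(conc.max())
        grid = np.linspace(lo, hi, n_grid)
        best = None
        for start_ec50 in grid:
            for start_slope in (1.0, 4.0):
                res = minimize(
                    self._nll,
                    x0=np.array([start_ec50, np.log(start_slope)]),
                    method="L-BFGS-B",
                    bounds=[(lo - 4, hi + 4), (np.log(1e-2), np.log(1e2))],
                )
                if best is None or res.fun < best.fun:
                    best = res
        log10_ec50, log_slope = best.x

        # saturated binomial log-likelihood for the deviance
        k = self.data["n_activated"].to_numpy().astype(float)
        n = self.data["n"].to_numpy().astype(float)
        phat = np.clip(k / n, 1e-12, 1 - 1e-12)
        ll_sat = float((xlogy(k, phat) + xlogy(n - k, 1 - phat)).sum())
        deviance = 2.0 * (best.fun + ll_sat)
        return DoseCurve(
            ec50_nM=float(10**log10_ec50),
            slope=float(np.exp(log_slope)),
            background=self.background,
            data=self.data.copy(),
            deviance=deviance,
            n_starts=n_grid * 2,
        )


def fit_dose_curve(points, fixed_background: float = 0.05) -> DoseCurve:
    """Fit the activation-vs-concentration curve; see :class:`DoseResponseModel`."""
    return DoseResponseModel(points, fixed_background=fixed_background).fit()


def threshold_crossing(curve: DoseCurve, level: float = 0.5) -> float:
    """Concentration (nM) at which the fitted curve crosses ``level``.

    Analytic inversion of the logistic; the level must lie strictly
    between the background and 1.
    """
    b = curve.background
    if not (b < level < 1):
        raise ValueError(f"level must lie strictly between background ({b}) and 1")
    u = (level - b) / (1 - b)
    return float(curve.ec50_nM * 10 ** (logit(u) / curve.slope))
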