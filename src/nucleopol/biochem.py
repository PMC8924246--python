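"""Enzyme-kinetics and circular-dichroism support calculations.

Steady-state actin-activated ATPase data (rate vs actin concentration) are
fitted to the Michaelis–Menten law with a basal offset,

    Rate([A]) = V0 + kcat·[A] / (K_actin + [A]),

where V0 (s⁻¹) is the basal ATPase activity, kcat (s⁻¹) the maximal
actin-activated rate and K_actin (µM) the actin concentration giving
half-maximal activation. Parameters are constrained non-negative (bounded
nonlinear least squares); units are fixed at µM / s⁻¹, conversions belong
at the I/O boundary.

CD spectrometer readings convert to mean residue ellipticity,

    [θ]_MRW = (MW / (n − 1)) · θ / (l · c · 10)

with θ in millidegrees, MW in g/mol, n residues, path length l in cm and
concentration c in mg/mL; the result is in deg·cm²·dmol⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .simulate import atpase_rate

__all__ = [
    "KineticsFit",
    "ActinActivatedATPase",
    "fit_atpase",
    "mean_residue_ellipticity",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge."""


@dataclass
class KineticsFit:
    V0: float
    kcat: float
    K_actin: float
    se_V0: float
    se_kcat: float
    se_K_actin: float
    rss: float
    converged: bool
    boundary_warning: bool


class ActinActivatedATPase(BaseEstimator, RegressorMixin):
    """Michaelis–Menten-with-offset regressor for ATPase titrations.

    ``fit(X, y)`` takes actin concentrations (µM) and observed rates (s⁻¹).
    Initial guesses: V0 = min rate, kcat = max − min rate, K_actin = the
    concentration nearest the half-rise.

    Attributes (after ``fit``)
    --------------------------
    V0_, kcat_, K_actin_ : floats
    se_ : dict of parameter standard errors
    rss_ : float
    result_ : KineticsFit
    """

    def fit(self, X, y):
        conc = np.asarray(X, float).ravel()
        rate = np.asarray(y, float).ravel()
        if conc.shape != rate.shape:
            raise ValueError("concentration and rate arrays differ in length")
        if len(np.unique(conc)) < 4:
            raise ValueError("need at least 4 distinct actin concentrations")

        v_min, v_max = float(rate.min()), float(rate.max())
        half = v_min + 0.5 * (v_max - v_min)
        p0 = [
            max(v_min, 1e-9),
            max(v_max - v_min, 1e-9),
            max(float(conc[np.argmin(np.abs(rate - half))]), 1e-3),
        ]
        try:
            popt, pcov = curve_fit(
                atpase_rate, conc, rate, p0=p0,
                bounds=(0.0, np.inf), maxfev=10000,
                ftol=1e-14, xtol=1e-14, gtol=1e-14,
            )
        except RuntimeError as exc:
            raise FitError(f"ATPase fit did not converge: {exc}") from exc
        self.V0_, self.kcat_, self.K_actin_ = map(float, popt)
        se = np.sqrt(np.diag(pcov))
        resid = rate - atpase_rate(conc, *popt)
        self.rss_ = float((resid**2).sum())
        boundary = bool(np.any(popt <= 1e-12))
        self.se_ = {"V0": float(se[0]), "kcat": float(se[1]), "K_actin": float(se[2])}
        self.result_ = KineticsFit(
            V0=self.V0_, kcat=self.kcat_, K_actin=self.K_actin_,
            se_V0=self.se_["V0"], se_kcat=self.se_["kcat"],
            se_K_actin=self.se_["K_actin"],
            rss=self.rss_, converged=True, boundary_warning=boundary,
        )
        return self

    def predict(self, X):
        return atpase_rate(np.asarray(X, float).ravel(), self.V0_, self.kcat_, self.K_actin_)


def fit_atpase(data) -> KineticsFit:
    """Fit an ATPase titration.

    *data* is a DataFrame with ``actin_uM`` and ``rate_per_s`` columns (the
    canonical kinetics schema) or a (conc, rate) pair of arrays.
    """
    if isinstance(data, pd.DataFrame):
        conc, rate = data["actin_uM"], data["rate_per_s"]
    else:
        conc, rate = data
    est = ActinActivatedATPase()
    est.fit(conc, rate)
    return est.result_


def mean_residue_ellipticity(
    theta: float, MW: float, n_residues: int, path_length: float, conc: float
) -> float:
    """Mean residue ellipticity [θ]_MRW in deg·cm²·dmol⁻¹.

    theta: ellipticity (millidegrees); MW: g/mol; n_residues: amino-acid
    count (≥ 2); path_length: cm; conc: mg/mL.
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    if path_length <= 0 or conc <= 0:
        raise ValueError("path length and concentration must be > 0")
    return (MW / (n_residues - 1)) * theta / (path_length * conc * 10.0)
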