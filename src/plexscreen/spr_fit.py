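"""Equilibrium surface-plasmon-resonance affinity fitting.

Orthogonal confirmation of screen hits: a titration of analyte
concentrations is flowed over a chip carrying the immobilised ligand and
the steady-state response at each concentration is fit to a one-site
Langmuir binding isotherm,

    R_eq(C) = R_max * C / (K_D + C),

yielding the dissociation constant ``K_D`` (same units as C, here µM)
and the saturation response ``R_max`` (response units).  Only the
equilibrium plateau is modelled; dissociation kinetics of weak adhesion
interactions are typically too fast to resolve, so no rate constants are
estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["TitrationSeries", "LangmuirFit", "langmuir", "fit_langmuir", "pool_fits"]

#: Minimum number of titration points for a two-parameter isotherm fit.
MIN_POINTS = 4


def langmuir(conc: np.ndarray, kd: float, rmax: float) -> np.ndarray:
    """One-site Langmuir isotherm R(C) = Rmax * C / (KD + C)."""
    conc = np.asarray(conc, dtype=float)
    return rmax * conc / (kd + conc)


@dataclass
class TitrationSeries:
    """Equilibrium responses of one analyte titrated over one ligand.

    Concentrations are in µM and must be strictly positive and pairwise
    distinct; responses are in instrument response units (RU), >= 0.
    """

    ligand: str
    analyte: str
    concentration: np.ndarray
    response: np.ndarray
    replicate: int = 1

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentration.ndim != 1 or self.concentration.shape != self.response.shape:
            raise ValueError("concentration and response must be 1-D arrays of equal length")
        if np.any(self.concentration <= 0):
            raise ValueError("analyte concentrations must be strictly positive")
        if len(np.unique(self.concentration)) != len(self.concentration):
            raise ValueError("analyte concentrations must be pairwise distinct")
        if np.any(self.response < 0):
            raise ValueError("equilibrium responses must be >= 0")

    @property
    def n_points(self) -> int:
        return len(self.concentration)

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.ligand, self.analyte))


@dataclass
class LangmuirFit:
    """Result of a least-squares Langmuir isotherm fit."""

    kd: float
    rmax: float
    se_kd: float
    se_rmax: float
    rss: float
    n_points: int
    converged: bool
    ligand: str = ""
    analyte: str = ""
    message: str = ""

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.ligand, self.analyte))

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return langmuir(conc, self.kd, self.rmax)


def _self_start(series: TitrationSeries) -> tuple[float, float]:
    # Rmax: slightly above the largest observed plateau; KD: the
    # concentration whose response is nearest half of that.  Robust for
    # both saturating and non-saturating series.
    rmax0 = 1.1 * float(np.max(series.response))
    if rmax0 <= 0:
        rmax0 = 1.0
    half = rmax0 / 2.0
    kd0 = float(series.concentration[np.argmin(np.abs(series.response - half))])
    return kd0, rmax0


def fit_langmuir(series: TitrationSeries, init: tuple[float, float] | None = None) -> LangmuirFit:
    """Fit a Langmuir isotherm to an equilibrium titration series.

    Ordinary (unweighted) nonlinear least squares with both parameters
    constrained positive.  Standard errors are the square roots of the
    diagonal of the parameter covariance at the optimum.  A fit is
    flagged not converged when the optimiser fails or when the K_D
    estimate falls outside ``[min(C)/100, max(C)*100]`` — far outside
    the titrated range the isotherm is not identifiable.

    Raises
    ------
    ValueError
        Fewer than 4 titration points.
    """
    if series.n_points < MIN_POINTS:
        raise ValueError(
            f"refusing to fit {series.n_points} points; a two-parameter "
            f"isotherm needs at least {MIN_POINTS}")
    conc, resp = series.concentration, series.response
    p0 = _self_start(series) if init is None else (float(init[0]), float(init[1]))
    try:
        popt, pcov = curve_fit(
            langmuir, conc, resp, p0=p0,
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000)
        kd, rmax = float(popt[0]), float(popt[1])
        se = np.sqrt(np.diag(pcov))
        rss = float(np.sum((resp - langmuir(conc, kd, rmax)) ** 2))
        in_range = conc.min() / 100.0 <= kd <= conc.max() * 100.0
        ok = bool(in_range and np.all(np.isfinite(popt)))
        msg = "" if ok else (
            f"K_D={kd:.4g} outside identifiable range "
            f"[{conc.min()/100:.4g}, {conc.max()*100:.4g}]")
        return LangmuirFit(kd, rmax, float(se[0]), float(se[1]), rss,
                           series.n_points, ok, series.ligand, series.analyte, msg)
    except RuntimeError as exc:  # optimiser did not converge
        return LangmuirFit(math.nan, math.nan, math.nan, math.nan, math.nan,
                           series.n_points, False, series.ligand, series.analyte,
                           f"optimizer failure: {exc}")


def pool_fits(fits: Sequence[LangmuirFit]) -> tuple[float, float]:
    """Pool replicate fits of one pair into (mean K_D, SEM).

    Requires at least two converged fits of the same ligand-analyte
    pair; for a single titration use the fit's own asymptotic standard
    error instead.
    """
    fits = [f for f in fits]
    if any(not f.converged for f in fits):
        raise ValueError("cannot pool non-converged fits")
    if len(fits) < 2:
        raise ValueError("need >= 2 converged fits to pool; for a single "
                         "series use its per-fit standard error (se_kd)")
    pairs = {f.pair for f in fits}
    if len(pairs) != 1:
        raise ValueError(f"fits mix different pairs: {sorted(tuple(sorted(p)) for p in pairs)}")
    kds = np.array([f.kd for f in fits], dtype=float)
    mean = float(kds.mean())
    sem = float(kds.std(ddof=1) / math.sqrt(len(kds)))
    return mean, sem
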