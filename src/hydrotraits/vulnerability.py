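"""Xylem vulnerability-curve fitting: Weibull model, P50, bootstrap CIs, HSM.

A vulnerability curve records stem hydraulic conductance ``kh`` at
increasing applied air-injection pressures (positive MPa of tension),
normalized by the flushed maximum ``kmax``.  Relative conductivity is
modelled with the two-parameter Weibull form

    K(P)/K_max = exp(−(P/b)^c),   b > 0 (scale, MPa), c > 0 (shape)

so the tension causing x% loss of conductivity is

    Px = b·(−ln(1 − x/100))^(1/c),   P50 = b·(ln 2)^(1/c).

Fitting is done on relative conductivity (not on PLC) to keep the error
structure simple.  Reported P50 carries the plant-side sign convention
(negative MPa).  Confidence intervals come from a case-resampling
bootstrap over (pressure, kh) observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, InvalidRecordError, logger
from .measurements import compute_plc

#: pressure steps (MPa) of the standard air-injection protocol
DEFAULT_PRESSURE_STEPS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 7.0)


@dataclass
class VulnerabilityCurve:
    """(pressure, conductance) measurements for one stem plus its flushed
    maximum; PLC per step is derived on construction."""

    stem_id: str
    pressures: np.ndarray   # positive MPa, strictly increasing
    kh: np.ndarray
    kmax: float
    cultivar: str = ""
    plc: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.kh = np.asarray(self.kh, dtype=float)
        if self.kmax <= 0:
            raise InvalidRecordError(f"kmax must be positive for stem {self.stem_id}")
        if np.any(np.diff(self.pressures) <= 0):
            raise InvalidRecordError(
                f"pressures must be strictly increasing for stem {self.stem_id}")
        self.plc = np.array([compute_plc(k, self.kmax) for k in self.kh])

    @property
    def relative_conductivity(self) -> np.ndarray:
        return 1.0 - self.plc / 100.0


def curves_from_frame(df: pd.DataFrame) -> list[VulnerabilityCurve]:
    """Build per-stem curves from a validated ``vulnerability`` table.

    ``kmax`` comes from a ``kmax`` column when present, otherwise from a
    row measured at pressure 0 (the flushed reading).
    """
    curves = []
    for stem_id, grp in df.groupby("stem_id", sort=True):
        grp = grp.sort_values("pressure_mpa")
        if "kmax" in grp.columns and grp["kmax"].notna().any():
            kmax = float(grp["kmax"].dropna().iloc[0])
        else:
            at_zero = grp[grp["pressure_mpa"] == 0.0]
            if at_zero.empty:
                raise InvalidRecordError(
                    f"stem {stem_id}: no kmax column and no pressure-0 row")
            kmax = float(at_zero["kh"].iloc[0])
        body = grp[grp["pressure_mpa"] > 0.0]
        cultivar = str(grp["cultivar"].iloc[0]) if "cultivar" in grp.columns else ""
        curves.append(VulnerabilityCurve(
            stem_id=str(stem_id),
            pressures=body["pressure_mpa"].to_numpy(),
            kh=body["kh"].to_numpy(),
            kmax=kmax, cultivar=cultivar))
    return curves


@dataclass
class WeibullFit:
    """Fitted Weibull vulnerability curve.

    ``p50`` is reported as negative MPa (plant sign convention); ``px``
    returns magnitudes in positive MPa of tension.
    """

    scale_b: float
    shape_c: float
    n: int
    rss: float
    ci_p50: tuple[float, float] | None = None   # magnitudes, (low, high)
    n_boot: int = 0
    seed: int | None = None
    ci_unstable: bool = False
    extrapolated: bool = False

    @property
    def p50(self) -> float:
        return -self.px(50.0)

    def px(self, x: float) -> float:
        """Tension (positive MPa) at x% loss of conductivity."""
        if not 0.0 < x < 100.0:
            raise ValueError("x must be in (0, 100)")
        return self.scale_b * (-np.log(1.0 - x / 100.0)) ** (1.0 / self.shape_c)

    def predict_plc(self, pressure) -> np.ndarray:
        p = np.asarray(pressure, dtype=float)
        return 100.0 * (1.0 - np.exp(-(p / self.scale_b) ** self.shape_c))

    def as_dict(self) -> dict:
        d = {"b": self.scale_b, "c": self.shape_c, "p50": self.p50,
             "n": self.n, "rss": self.rss}
        if self.ci_p50 is not None:
            d.update(ci_low=-self.ci_p50[1], ci_high=-self.ci_p50[0],
                     n_boot=self.n_boot, seed=self.seed,
                     ci_unstable=self.ci_unstable)
        return d


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _pool(curves) -> tuple[np.ndarray, np.ndarray]:
    """Pool stems after normalizing each by its own kmax."""
    if isinstance(curves, VulnerabilityCurve):
        curves = [curves]
    p = np.concatenate([c.pressures for c in curves])
    r = np.concatenate([c.relative_conductivity for c in curves])
    return p, r


def _fit_relk(pressures: np.ndarray, relk: np.ndarray,
              x0: tuple[float, float] | None = None) -> tuple[float, float, float]:
    """Nonlinear least squares of relk = exp(−(P/b)^c); returns (b, c, rss)."""

    def resid(theta):
        b, c = theta
        return np.exp(-(pressures / b) ** c) - relk

    starts = []
    if x0 is not None:
        starts.append(x0)
    else:
        # log-log linearization: ln(−ln r) = c·ln P − c·ln b (for 0 < r < 1)
        ok = (relk > 1e-6) & (relk < 1 - 1e-6) & (pressures > 0)
        if np.count_nonzero(ok) >= 2:
            lx = np.log(pressures[ok])
            ly = np.log(-np.log(relk[ok]))
            c0, i0 = np.polyfit(lx, ly, 1)
            if c0 > 0:
                starts.append((float(np.exp(-i0 / c0)), float(c0)))
        # deterministic multistart: shape × scale heuristics
        plc = 100.0 * (1.0 - relk)
        half = np.max(plc) / 2.0
        b_half = float(pressures[np.argmin(np.abs(plc - half))])
        b_med = float(np.median(pressures))
        for c0 in (1.0, 2.0, 4.0, 8.0):
            for b0 in (b_half, b_med):
                starts.append((max(b0, 1e-3), c0))

    best = None
    for b0, c0 in starts:
        try:
            sol = least_squares(resid, x0=(b0, c0), bounds=((1e-6, 1e-6), (np.inf, np.inf)))
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[2] - 1e-15:
            best = (float(sol.x[0]), float(sol.x[1]), rss)
    if best is None:
        raise FitError("Weibull fit failed from every starting point")
    return best


def fit_weibull(curves, warn_extrapolated: bool = True) -> WeibullFit:
    """Fit the Weibull vulnerability model to one stem or a pooled set.

    Requires at least 5 pressure steps.  When the observed PLC never
    exceeds 50%, the returned P50 is an extrapolation and the fit is
    flagged (``extrapolated=True``) with a logged warning.
    """
    p, r = _pool(curves)
    if len(p) < 5:
        raise FitError(f"need >= 5 pressure steps, have {len(p)}")
    b, c, rss = _fit_relk(p, r)
    fit = WeibullFit(scale_b=b, shape_c=c, n=len(p), rss=rss)
    if np.max(100.0 * (1.0 - r)) < 50.0:
        fit.extrapolated = True
        if warn_extrapolated:
            logger.warning("observed PLC never exceeds 50%%: P50 = %.2f MPa "
                           "is extrapolated", fit.p50)
    return fit


def bootstrap_p50(curves, n_boot: int = 1000, seed: int | None = None,
                  fit: WeibullFit | None = None) -> WeibullFit:
    """Percentile 95% bootstrap interval for P50 by case resampling.

    Observations (pressure, relative conductivity) pooled across stems are
    resampled with replacement; each replicate is refit warm-started from
    the point estimate.  Replicates whose fit fails or degenerates are
    dropped; more than 20% failures flags the interval unstable.
    Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    p, r = _pool(curves)
    if fit is None:
        fit = fit_weibull(curves, warn_extrapolated=False)
    rng = np.random.default_rng(seed)
    n = len(p)
    ln2 = np.log(2.0)
    p50s = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        pb, rb = p[idx], r[idx]
        if np.ptp(pb) == 0:
            failures += 1
            continue
        try:
            b, c, _ = _fit_relk(pb, rb, x0=(fit.scale_b, fit.shape_c))
        except FitError:
            failures += 1
            continue
        p50s.append(b * ln2 ** (1.0 / c))
    if not p50s:
        raise FitError("every bootstrap replicate failed")
    lo, hi = np.percentile(p50s, [2.5, 97.5])
    fit.ci_p50 = (float(lo), float(hi))
    fit.n_boot = n_boot
    fit.seed = seed
    fit.ci_unstable = failures > 0.2 * n_boot
    if fit.ci_unstable:
        logger.warning("bootstrap interval unstable: %d/%d replicate fits failed",
                       failures, n_boot)
    return fit


def safety_margin(psi_gs90: float, p50: float) -> float:
    """Hydraulic safety margin HSM = Ψ_gs90 − P50 (both negative MPa).

    Positive HSM means stomata reach 90% closure before the xylem loses
    half its conductivity — the cavitation-avoidance signature.
    """
    return psi_gs90 - p50
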