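"""Hydroscape metrics of stomatal-regulation stringency.

The hydroscape quantifies how tightly a plant clamps its midday water
potential while the soil dries.  Regressing Ψ_min on Ψ_pd gives a slope σ
(0 = perfectly isohydric, 1 = perfectly anisohydric) and an intercept *a*
(the most negative Ψ_min reached while the soil is still wet, Ψ_pd = 0).
The fitted line meets the 1:1 line at *b* = a / (1 − σ), the water
potential at which stomatal control is exhausted (Ψ_pd = Ψ_min), and the
triangle enclosed between the two lines has area

    H = |a·b| / 2 = a² / (2·(1 − σ))   [MPa²]

Larger areas indicate more anisohydric behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import FitError, InsufficientDataError, NoIntersectionError, logger
from .measurements import WaterPotentialRecord


@dataclass
class HydroscapeResult:
    """Fitted hydroscape metrics for one cultivar.

    ``sigma``  slope of Ψ_min on Ψ_pd (MPa MPa⁻¹)
    ``a``      intercept: most negative Ψ_min at Ψ_pd = 0 (MPa)
    ``b``      Ψ where the fit meets the 1:1 line (MPa); a/(1−σ)
    ``area``   hydroscape area (MPa²)
    """

    sigma: float
    a: float
    b: float
    area: float
    n: int
    r2: float
    n_excluded: int = 0

    def as_dict(self) -> dict:
        return {"sigma": self.sigma, "a": self.a, "b": self.b,
                "area": self.area, "n": self.n, "r2": self.r2,
                "n_excluded": self.n_excluded}


def fit_sigma(
    records: list[WaterPotentialRecord],
    include_well_watered: bool = False,
) -> HydroscapeResult:
    """Ordinary least-squares fit of Ψ_min (response) on Ψ_pd (predictor).

    Physically inconsistent records (Ψ_min > Ψ_pd) are excluded from the fit
    but counted in ``n_excluded``.  Well-watered (WW) records are excluded by
    default: the hydroscape is a drydown metric and WW points cluster at the
    wet end, diluting the slope.  The returned result has ``b`` and ``area``
    unset (nan) until :func:`hydroscape_area` is applied; for convenience the
    area is computed here too when σ < 1.
    """
    kept, dropped = [], 0
    for r in records:
        if "psi_min_above_psi_pd" in r.flags:
            dropped += 1
            continue
        if not include_well_watered and r.treatment == "WW":
            continue
        kept.append(r)
    if len(kept) < 3:
        raise InsufficientDataError(
            f"need >= 3 consistent drydown records, have {len(kept)}"
        )
    x = np.array([r.psi_pd for r in kept])
    y = np.array([r.psi_min for r in kept])
    if np.ptp(x) == 0:
        raise FitError("degenerate fit: no variance in psi_pd")
    res = stats.linregress(x, y)
    result = HydroscapeResult(
        sigma=float(res.slope), a=float(res.intercept),
        b=float("nan"), area=float("nan"),
        n=len(kept), r2=float(res.rvalue**2), n_excluded=dropped,
    )
    if result.sigma < 1.0:
        hydroscape_area(result)
    return result


def hydroscape_area(fit: HydroscapeResult) -> float:
    """Area (MPa²) between the fitted Ψ_pd–Ψ_min line and the 1:1 line.

    Updates ``fit.b`` and ``fit.area`` in place and returns the area.
    Requires σ < 1, otherwise the two lines never meet and the hydroscape
    is unbounded (reported as an error, not NaN).
    """
    if fit.sigma >= 1.0:
        raise NoIntersectionError(
            f"sigma = {fit.sigma:.4f} >= 1: regression never meets the 1:1 "
            "line; hydroscape is infinite"
        )
    fit.b = fit.a / (1.0 - fit.sigma)
    fit.area = abs(fit.a * fit.b) / 2.0
    return fit.area


def rank_cultivars(results: dict[str, HydroscapeResult]) -> list[str]:
    """Order cultivar labels from most isohydric to most anisohydric.

    Ascending hydroscape area; ties broken by σ (larger σ = more
    anisohydric), then alphabetically for determinism.
    """
    if len(results) < 2:
        if not results:
            raise InsufficientDataError("no cultivars to rank")
        return list(results)
    ranked = sorted(results, key=lambda c: (results[c].area, results[c].sigma, c))
    for a, b in zip(ranked, ranked[1:]):
        if results[a].area == results[b].area:
            logger.info("tie on area between %s and %s broken by sigma "
                        "(%.3f vs %.3f)", a, b, results[a].sigma, results[b].sigma)
    return ranked
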