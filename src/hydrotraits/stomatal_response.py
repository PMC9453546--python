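"""Stomatal-conductance decline against leaf water potential.

Two models of gs(Ψ_min) are provided:

* a first-order kinetic (exponential) decay ``gs = g₀·exp(k·Ψ)`` with
  k > 0 and Ψ ≤ 0, fitted by nonlinear least squares — under this model
  90% stomatal closure occurs at Ψ_gs90 = ln(0.1)/k;
* a weighted polynomial regression (default degree 2) with
  multiplicative-error variance weights (w ∝ 1/gs), from which Ψ_gs90 is
  the most negative closing-branch root of fitted(Ψ) = 0.1·gs_ref.

``gs_ref`` is the fitted conductance at the least negative observed Ψ —
the operational maximum of the fit — so the closure threshold is robust
to a single outlying high observation.  A three-parameter kinetic variant
with an additive floor ``g_min`` is available for data that plateau above
zero.  Cultivar differences between kinetic curves are tested with the
extra-sums-of-squares F principle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .errors import FitError, InsufficientDataError, logger

LN_01 = float(np.log(0.1))
#: closure threshold as a fraction of the reference conductance
CLOSURE_FRACTION = 0.1


@dataclass
class StomatalFit:
    """Fitted stomatal-response model.

    ``params`` holds (g0, k[, g_min]) for the kinetic model or polynomial
    coefficients (highest degree first) for the polynomial model.
    """

    model: str                       # "kinetic_exponential" | "weighted_polynomial"
    params: tuple[float, ...]
    gs_ref: float
    psi_gs90: float
    r2: float
    ci_psi_gs90: tuple[float, float] | None = None
    n_boot: int = 0
    seed: int | None = None
    flags: tuple[str, ...] = ()

    def predict(self, psi) -> np.ndarray:
        psi = np.asarray(psi, dtype=float)
        if self.model == "kinetic_exponential":
            g0, k = self.params[0], self.params[1]
            gmin = self.params[2] if len(self.params) > 2 else 0.0
            return gmin + g0 * np.exp(k * psi)
        return np.polyval(self.params, psi)

    def as_dict(self) -> dict:
        d = {"model": self.model, "params": list(self.params),
             "gs_ref": self.gs_ref, "psi_gs90": self.psi_gs90, "r2": self.r2}
        if self.ci_psi_gs90 is not None:
            d.update(ci_low=self.ci_psi_gs90[0], ci_high=self.ci_psi_gs90[1],
                     n_boot=self.n_boot, seed=self.seed)
        if self.flags:
            d["flags"] = list(self.flags)
        return d


def _extract(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, tuple) and len(records) == 2:
        psi, gs = records
    else:
        psi = [r[0] for r in records]
        gs = [r[1] for r in records]
    return np.asarray(psi, dtype=float), np.asarray(gs, dtype=float)


def _r2(y, yhat) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return float("nan")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


# ---------------------------------------------------------------------------
# kinetic model
# ---------------------------------------------------------------------------

def fit_gs_kinetic(records, with_floor: bool = False,
                   method: str = "nls") -> StomatalFit:
    """Fit gs = g₀·exp(k·Ψ) (optionally + g_min) by nonlinear least squares.

    Multistart over log-linearized and heuristic initial values; requires
    at least 6 (Ψ, gs) pairs spanning high and low conductance.  Data with
    no detectable decline return k ≈ 0 flagged ``no_stomatal_response``.

    ``method="log-linear"`` instead regresses ln(gs) on Ψ by ordinary
    least squares (positive gs only, no floor).  With multiplicative
    conductance noise the two are equivalent in expectation, but when Ψ
    itself carries measurement error the linear-scale NLS concentrates on
    the narrow wet end of a drydown and attenuates k, whereas the
    log-scale rate estimate is nearly unaffected.
    """
    psi, gs = _extract(records)
    if len(psi) < 6:
        raise InsufficientDataError(f"need >= 6 (psi, gs) pairs, have {len(psi)}")
    if np.any(psi > 1e-9):
        raise FitError("psi values must be <= 0")

    if method == "log-linear":
        if with_floor:
            raise FitError("the log-linear rate estimate has no floor variant")
        pos = gs > 0
        if np.count_nonzero(pos) < 6 or np.ptp(psi[pos]) == 0:
            raise FitError("too few positive-gs points for a log-linear fit")
        k, lg0 = np.polyfit(psi[pos], np.log(gs[pos]), 1)
        if k <= 0:
            flags = ("no_stomatal_response",)
            logger.warning("log-linear fit: k <= 0, no conductance decline")
            fit = StomatalFit(model="kinetic_exponential",
                              params=(float(np.exp(lg0)), 0.0),
                              gs_ref=float(np.exp(lg0)), psi_gs90=float("-inf"),
                              r2=float("nan"), flags=flags)
        else:
            fit = StomatalFit(model="kinetic_exponential",
                              params=(float(np.exp(lg0)), float(k)),
                              gs_ref=float(np.exp(lg0)), psi_gs90=LN_01 / float(k),
                              r2=float("nan"))
        fit.r2 = _r2(gs, fit.predict(psi))
        return fit
    if method != "nls":
        raise ValueError(f"unknown method {method!r}")

    gmax = float(np.max(gs))

    def resid(theta):
        if with_floor:
            g0, k, gmin = theta
            return gmin + g0 * np.exp(k * psi) - gs
        g0, k = theta
        return g0 * np.exp(k * psi) - gs

    starts = []
    pos = gs > 0
    if np.count_nonzero(pos) >= 2 and np.ptp(psi[pos]) > 0:
        k0, lg0 = np.polyfit(psi[pos], np.log(gs[pos]), 1)
        if k0 > 0:
            starts.append((float(np.exp(lg0)), float(k0)))
    for k0 in (0.5, 1.0, 2.0, 4.0):
        starts.append((gmax, k0))

    lb = (0.0, 0.0, 0.0) if with_floor else (0.0, 0.0)
    ub = (np.inf,) * (3 if with_floor else 2)
    best = None
    for s in starts:
        x0 = s + (0.0,) if with_floor else s
        try:
            sol = least_squares(resid, x0=x0, bounds=(lb, ub))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("kinetic gs fit failed from every starting point")

    params = tuple(float(v) for v in best.x)
    g0, k = params[0], params[1]
    flags = ()
    if k < 1e-6:
        flags = ("no_stomatal_response",)
        logger.warning("kinetic fit: k ~ 0, conductance shows no response to psi")
        psi_gs90 = float("-inf")
    else:
        psi_gs90 = LN_01 / k
    fit = StomatalFit(
        model="kinetic_exponential", params=params,
        gs_ref=g0 + (params[2] if with_floor else 0.0),
        psi_gs90=psi_gs90, r2=float("nan"), flags=flags)
    fit.r2 = _r2(gs, fit.predict(psi))
    return fit


# ---------------------------------------------------------------------------
# weighted polynomial model
# ---------------------------------------------------------------------------

def _wpolyfit(psi, gs, degree, weights):
    sw = np.sqrt(weights)
    V = np.vander(psi, degree + 1)
    coef, _, _, _ = np.linalg.lstsq(V * sw[:, None], gs * sw, rcond=None)
    return coef


def _solve_gs90(coef, gs_ref, psi_lo, psi_hi):
    """Root of poly(psi) = CLOSURE_FRACTION * gs_ref on the closing branch.

    Only crossings where the fitted conductance is *falling* as psi falls
    (dP/dpsi > 0) describe stomatal closure; a low-order polynomial fitted
    to a saturating decline also rises again beyond its minimum, and roots
    on that spurious branch are ignored.  Among closing-branch roots in or
    near [psi_lo, psi_hi] the most negative is returned, with an
    extrapolation flag when it lies beyond the observed range.
    """
    target = np.array(coef, dtype=float)
    target[-1] -= CLOSURE_FRACTION * gs_ref
    roots = np.roots(target)
    real = roots[np.abs(roots.imag) < 1e-9].real
    deriv = np.polyder(np.array(coef, dtype=float))
    closing = real[np.polyval(deriv, real) > 0]
    span = psi_hi - psi_lo
    near = closing[(closing >= psi_lo - 0.25 * max(span, 1.0))
                   & (closing <= psi_hi + 1e-9)]
    if near.size == 0:
        return None
    root = float(np.min(near))
    return root, root < psi_lo - 1e-12


def fit_psi_gs90(records, degree: int = 2, n_boot: int = 0,
                 seed: int | None = None, weights=None) -> StomatalFit:
    """Weighted polynomial fit of gs on Ψ_min and the Ψ_gs90 it implies.

    Default weights are variance weights for multiplicative conductance
    error, w ∝ 1/gs (a reading floored at 1% of the maximum so near-zero
    observations cannot dominate); equalizing the *relative* error this
    way is what lets a low-order polynomial track the crossing of a
    saturating decline — conductance-proportional weights concentrate the
    fit on the wet end and bias the root several tenths of an MPa wet.
    Pass an array for a custom scheme or equal weights.  Ψ_gs90 is the
    most negative closing-branch root of fitted(Ψ) = 0.1·gs_ref in or
    near the observed Ψ range; a root beyond the range is flagged
    ``extrapolated``.  If every observation already sits below the
    closure threshold the least negative observed Ψ is returned flagged
    ``saturated``.  A case-resampling bootstrap (``n_boot`` > 0) gives a
    percentile 95% interval for Ψ_gs90.
    """
    psi, gs = _extract(records)
    if len(psi) < degree + 3:
        raise InsufficientDataError(
            f"need >= degree+3 = {degree + 3} points, have {len(psi)}")
    if weights is None:
        w = 1.0 / np.maximum(gs, 0.01 * np.max(gs))
    else:
        w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not np.any(w > 0):
        raise FitError("weights must be non-negative with at least one positive")
    w = np.where(w <= 0, np.min(w[w > 0]) * 1e-3, w)  # keep zero-weight points, barely

    psi_lo, psi_hi = float(np.min(psi)), float(np.max(psi))
    coef = _wpolyfit(psi, gs, degree, w)
    gs_ref = float(np.polyval(coef, psi_hi))
    if gs_ref <= 0:
        raise FitError("fitted reference conductance is non-positive")

    flags = ()
    if np.max(gs) < CLOSURE_FRACTION * gs_ref:
        flags = ("saturated",)
        psi_gs90 = psi_hi
    else:
        sol = _solve_gs90(coef, gs_ref, psi_lo, psi_hi)
        if sol is None:
            raise FitError("no closure detected: fitted polynomial never "
                           "reaches 10% of the reference conductance near "
                           "the observed range")
        psi_gs90, extrap = sol
        if extrap:
            flags = ("extrapolated",)

    fit = StomatalFit(model="weighted_polynomial",
                      params=tuple(float(c) for c in coef),
                      gs_ref=gs_ref, psi_gs90=float(psi_gs90),
                      r2=_r2(gs, np.polyval(coef, psi)), flags=flags)

    if n_boot:
        rng = np.random.default_rng(seed)
        n = len(psi)
        vals = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                cb = _wpolyfit(psi[idx], gs[idx], degree, w[idx])
            except np.linalg.LinAlgError:
                continue
            hi_b = float(np.max(psi[idx]))
            ref_b = float(np.polyval(cb, hi_b))
            if ref_b <= 0:
                continue
            sol = _solve_gs90(cb, ref_b, float(np.min(psi[idx])), hi_b)
            if sol is not None:
                vals.append(sol[0])
        if vals:
            lo, hi = np.percentile(vals, [2.5, 97.5])
            fit.ci_psi_gs90 = (float(lo), float(hi))
            fit.n_boot = n_boot
            fit.seed = seed
    return fit


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def compare_models(groups: dict) -> dict:
    """Extra-sums-of-squares F test: one pooled kinetic curve vs per-group curves.

    ``groups`` maps label → (psi, gs) data.  The pooled model fits a single
    (g₀, k) to all observations; the full model fits each group separately.
    F = [(RSS_pooled − RSS_full)/(df_pooled − df_full)] / [RSS_full/df_full].
    """
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups to compare")
    all_psi, all_gs, rss_full, n_total = [], [], 0.0, 0
    for label, data in groups.items():
        psi, gs = _extract(data)
        fit = fit_gs_kinetic((psi, gs))
        rss_full += float(np.sum((gs - fit.predict(psi)) ** 2))
        all_psi.append(psi)
        all_gs.append(gs)
        n_total += len(psi)
    psi = np.concatenate(all_psi)
    gs = np.concatenate(all_gs)
    pooled = fit_gs_kinetic((psi, gs))
    rss_pooled = float(np.sum((gs - pooled.predict(psi)) ** 2))

    p_per = 2
    df_pooled = n_total - p_per
    df_full = n_total - p_per * len(groups)
    if df_full <= 0:
        raise InsufficientDataError("not enough observations for the full model")
    dfn = df_pooled - df_full
    f_stat = ((rss_pooled - rss_full) / dfn) / (rss_full / df_full)
    p_value = float(stats.f.sf(f_stat, dfn, df_full))
    return {"f": float(f_stat), "p_value": p_value,
            "df_num": dfn, "df_den": df_full,
            "rss_pooled": rss_pooled, "rss_full": rss_full,
            "n": n_total, "n_groups": len(groups)}
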