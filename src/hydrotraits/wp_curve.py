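"""Three-segment piecewise-linear modelling of the water-potential curve.

During a drydown, the relationship between pre-dawn (Ψ_pd) and midday
(Ψ_min) water potential is triphasic: a steep initial decline (phase I), a
buffered middle phase (II), and a final phase (III) approaching the limit
of stomatal control.  The model is a continuous piecewise-linear function
of Ψ_pd with two interior breakpoints Θ₁ > Θ₂ (both negative, on the Ψ_pd
axis) and slopes β₁, β₂, β₃.

Fitting uses iterative relinearization: for trial breakpoints θ the model

    y = c + β₁·x + Σ_j d_j·U_j + g_j·V_j,
    U_j = (x − θ_j)·1[x < θ_j],  V_j = −1[x < θ_j]

is linear, and the first-order update θ_j ← θ_j + g_j/d_j drives the gap
coefficients g_j to zero at a stationary point of the residual sum of
squares.  Because the algorithm is initialization-sensitive, it is started
from a deterministic 10×10 grid of breakpoint pairs spanning the inner 80%
of the observed Ψ_pd range.  Because the relinearization's stationary
points are not always the constrained global optimum (the profile RSS
surface has kinks at the data abscissae), the result is polished by a
deterministic coarse-to-fine profile-RSS scan plus Nelder-Mead descent;
the best valid solution wins.  Standard errors for Θ come from the final
linearization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (InsufficientDataError, NoIntersectionError,
                     UnidentifiableBreakpointError, logger)
from .measurements import WaterPotentialRecord

#: breakpoints closer than this to each other or to the data edge are
#: considered unidentifiable (MPa)
MIN_SEPARATION = 0.05
#: convergence tolerance on breakpoint updates (MPa)
BREAKPOINT_TOL = 1e-8
MAX_ITER = 100


@dataclass
class PiecewiseFit:
    """Continuous piecewise-linear fit of Ψ_min against Ψ_pd.

    ``theta1`` (phase I/II boundary) and ``theta2`` (II/III) satisfy
    theta2 < theta1 < 0.  ``intercept`` is the phase-I intercept at
    Ψ_pd = 0.  ``breakpoints``/``slopes`` generalize to other segment
    counts; theta1/theta2/beta1..3 are the 3-segment view.
    """

    breakpoints: tuple[float, ...]      # descending (least negative first)
    slopes: tuple[float, ...]           # per phase, wet to dry
    intercept: float
    rmse: float
    r2: float
    se_breakpoints: tuple[float, ...]
    n: int
    x_range: tuple[float, float]        # (most negative, least negative) observed
    converged: bool = True

    @property
    def theta1(self) -> float:
        return self.breakpoints[0]

    @property
    def theta2(self) -> float:
        return self.breakpoints[1] if len(self.breakpoints) > 1 else float("nan")

    @property
    def beta1(self) -> float:
        return self.slopes[0]

    @property
    def beta2(self) -> float:
        return self.slopes[1]

    @property
    def beta3(self) -> float:
        return self.slopes[2] if len(self.slopes) > 2 else float("nan")

    def segment_intercepts(self) -> tuple[float, ...]:
        """Intercept of each segment's line extended to Ψ_pd = 0."""
        cs = [self.intercept]
        for theta, b_prev, b_next in zip(self.breakpoints, self.slopes, self.slopes[1:]):
            cs.append(cs[-1] + (b_prev - b_next) * theta)
        return tuple(cs)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        cs = self.segment_intercepts()
        y = cs[0] + self.slopes[0] * x
        for theta, c, b in zip(self.breakpoints, cs[1:], self.slopes[1:]):
            mask = x < theta
            y = np.where(mask, c + b * x, y)
        return y

    def as_dict(self) -> dict:
        d = {"theta1": self.theta1, "theta2": self.theta2,
             "beta1": self.beta1, "beta2": self.beta2, "beta3": self.beta3,
             "intercept": self.intercept, "rmse": self.rmse, "r2": self.r2,
             "se_theta1": self.se_breakpoints[0],
             "se_theta2": self.se_breakpoints[1] if len(self.se_breakpoints) > 1 else float("nan"),
             "n": self.n}
        return d


@dataclass
class OneToOneIntersection:
    """Ψ where the fitted curve equals its argument (Ψ_pd = Ψ_min)."""

    psi: float
    extrapolated: bool
    segment: int  # 1-based phase index


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------

def _hinge_design(x: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for t in thetas:
        cols.append(np.minimum(x - t, 0.0))
    return np.column_stack(cols)


def _ols_rss(X: np.ndarray, y: np.ndarray):
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size and rank == X.shape[1]:
        rss = float(res[0])
    else:
        rss = float(np.sum((y - X @ coef) ** 2))
    return coef, rss


def fit_fixed_breakpoints(x: np.ndarray, y: np.ndarray, thetas) -> tuple[np.ndarray, float]:
    """Least-squares fit with the breakpoints held fixed.

    Returns ``(coef, rss)`` where ``coef = (intercept, beta1, d1, d2, ...)``
    and segment slopes are the cumulative sums ``beta1, beta1+d1, ...``.
    Exposed because it is the primitive an exhaustive breakpoint search
    (the independent check for the iterative fitter) is built from.
    """
    thetas = np.sort(np.asarray(thetas, dtype=float))[::-1]
    X = _hinge_design(np.asarray(x, float), thetas)
    return _ols_rss(X, np.asarray(y, float))


def _muggeo_iterate(x, y, theta0, lo, hi):
    """Iterative relinearization from one starting pair; returns
    (thetas, coef, rss, se_thetas, converged) or None if it degenerates."""
    thetas = np.sort(np.asarray(theta0, float))[::-1]
    n = len(x)
    converged = False
    for _ in range(MAX_ITER):
        U = [np.minimum(x - t, 0.0) for t in thetas]
        V = [-(x < t).astype(float) for t in thetas]
        X = np.column_stack([np.ones_like(x), x] + U + V)
        coef, _ = _ols_rss(X, y)
        k = len(thetas)
        d = coef[2:2 + k]
        g = coef[2 + k:2 + 2 * k]
        if np.any(np.abs(d) < 1e-12):
            return None
        step = g / d
        new = np.clip(thetas + step, lo, hi)
        shift = np.max(np.abs(new - thetas))
        thetas = np.sort(new)[::-1]
        if shift < BREAKPOINT_TOL:
            converged = True
            break
    coef, rss = fit_fixed_breakpoints(x, y, thetas)
    se = _linearized_se(x, y, thetas)
    return thetas, coef, rss, se, converged


def _linearized_se(x, y, thetas):
    """SE of each theta_j ~ SE(g_j)/|d_j| from the local linearization."""
    n = len(x)
    U = [np.minimum(x - t, 0.0) for t in thetas]
    V = [-(x < t).astype(float) for t in thetas]
    X = np.column_stack([np.ones_like(x), x] + U + V)
    p = X.shape[1]
    se = np.full(len(thetas), np.nan)
    if n > p:
        cfull, rss_lin = _ols_rss(X, y)
        sigma2 = rss_lin / (n - p)
        try:
            cov = sigma2 * np.linalg.inv(X.T @ X)
            k = len(thetas)
            d = cfull[2:2 + k]
            var_g = np.diag(cov)[2 + k:2 + 2 * k]
            se = np.sqrt(np.maximum(var_g, 0.0)) / np.abs(d)
        except np.linalg.LinAlgError:
            pass
    return se


def fit_piecewise(
    records,
    n_segments: int = 3,
    grid: int = 10,
) -> PiecewiseFit:
    """Fit a continuous piecewise-linear Ψ_pd–Ψ_min model with free breakpoints.

    ``records`` may be a list of :class:`WaterPotentialRecord` or a pair of
    arrays ``(psi_pd, psi_min)``.  Physically inconsistent records are
    excluded as in the hydroscape fit.  Raises
    :class:`UnidentifiableBreakpointError` when a breakpoint collapses onto
    the data edge, onto its neighbour (within 0.05 MPa), or when the data
    carry no detectable slope change.
    """
    if n_segments < 2:
        raise InsufficientDataError("need at least 2 segments for a piecewise fit")
    x, y = _extract_xy(records)
    if len(x) < 8:
        raise InsufficientDataError(f"need >= 8 records for a piecewise fit, have {len(x)}")
    n_break = n_segments - 1
    x_lo, x_hi = float(np.min(x)), float(np.max(x))
    span = x_hi - x_lo
    if span <= 0:
        raise InsufficientDataError("no variation in psi_pd")
    # inner 80% of the range for starting values and clipping bounds
    lo, hi = x_lo + 0.10 * span, x_hi - 0.10 * span

    grid_pts = np.linspace(lo, hi, grid)
    if n_break == 2:
        starts = [(t1, t2) for t1 in grid_pts for t2 in grid_pts if t2 < t1]
    else:
        # quantile-spread starting tuples jittered across the grid
        starts = []
        for shift in np.linspace(-0.05 * span, 0.05 * span, grid):
            qs = np.quantile(x, np.linspace(0.15, 0.85, n_break)) + shift
            starts.append(tuple(np.clip(np.sort(qs)[::-1], lo, hi)))

    def _invalid_reason(thetas):
        for j, t in enumerate(thetas, start=1):
            if t - x_lo < MIN_SEPARATION or x_hi - t < MIN_SEPARATION:
                return (f"theta{j} = {t:.3f} collapsed onto the data range "
                        "edge", f"theta{j}")
        for j in range(len(thetas) - 1):
            if thetas[j] - thetas[j + 1] < MIN_SEPARATION:
                return (f"theta{j+1} and theta{j+2} collapsed onto each "
                        f"other ({thetas[j]:.3f} vs {thetas[j+1]:.3f})",
                        f"theta{j+2}")
        return None

    # the RSS-optimal stationary point can be degenerate (coincident or
    # edge breakpoints) on weakly-phased data; prefer the best *valid*
    # solution and fall back to reporting why only degenerate ones exist
    best_valid = None
    best_any = None
    for theta0 in starts:
        out = _muggeo_iterate(x, y, theta0, lo, hi)
        if out is None:
            continue
        if best_any is None or out[2] < best_any[2] - 1e-15:
            best_any = out
        if _invalid_reason(out[0]) is None:
            if best_valid is None or out[2] < best_valid[2] - 1e-15:
                best_valid = out

    # the relinearization's stationary points are not always the global
    # profile-RSS minimum (the surface has kinks at the data abscissae), so
    # polish deterministically: a coarse exhaustive scan locates the basin
    # and Nelder-Mead descends the profile RSS from each candidate
    if n_break == 2:
        seeds_nm = []
        if best_valid is not None:
            seeds_nm.append(tuple(best_valid[0]))
        # coarse-to-fine profile-RSS scan: global at span/40, then two
        # zoom passes around the incumbent for ~0.001-MPa resolution
        step = (hi - lo) / 40.0
        scan = np.arange(lo, hi + step / 2, step)
        coarse = min(((t1, t2) for t1 in scan for t2 in scan
                      if t2 < t1 - MIN_SEPARATION / 2),
                     key=lambda t: fit_fixed_breakpoints(x, y, t)[1])
        for _ in range(2):
            step /= 10.0
            g1 = np.arange(coarse[0] - 5.5 * step, coarse[0] + 5.5 * step, step)
            g2 = np.arange(coarse[1] - 5.5 * step, coarse[1] + 5.5 * step, step)
            g1 = np.clip(g1, lo, hi)
            g2 = np.clip(g2, lo, hi)
            coarse = min(((t1, t2) for t1 in g1 for t2 in g2
                          if t2 < t1 - MIN_SEPARATION / 2),
                         key=lambda t: fit_fixed_breakpoints(x, y, t)[1])
        seeds_nm.append(coarse)

        def profile(theta):
            t1, t2 = max(theta), min(theta)
            if t1 - t2 < MIN_SEPARATION or t2 < x_lo or t1 > x_hi:
                return 1e12
            return fit_fixed_breakpoints(x, y, (t1, t2))[1]

        from scipy.optimize import minimize
        for s in seeds_nm:
            res = minimize(profile, x0=np.asarray(s), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 400})
            thetas_nm = np.sort(res.x)[::-1]
            if _invalid_reason(thetas_nm) is not None:
                continue
            coef_nm, rss_nm = fit_fixed_breakpoints(x, y, thetas_nm)
            if best_valid is None or rss_nm < best_valid[2] - 1e-12:
                refined = _muggeo_iterate(x, y, thetas_nm, lo, hi)
                if (refined is not None
                        and _invalid_reason(refined[0]) is None
                        and refined[2] <= rss_nm + 1e-12):
                    best_valid = refined
                else:
                    se = _linearized_se(x, y, thetas_nm)
                    best_valid = (thetas_nm, coef_nm, rss_nm, se, True)
    if best_valid is None:
        if best_any is None:
            raise UnidentifiableBreakpointError(
                "no breakpoint identifiable: data are consistent with a "
                "single line")
        reason, boundary = _invalid_reason(best_any[0])
        raise UnidentifiableBreakpointError(reason, boundary=boundary)
    thetas, coef, rss, se, converged = best_valid
    if not converged:
        logger.warning("piecewise fit: breakpoint iteration hit max_iter; "
                       "using best grid solution")

    slopes = tuple(np.cumsum(np.concatenate([[coef[1]], coef[2:2 + n_break]])))
    if all(abs(s2 - s1) < 1e-9 for s1, s2 in zip(slopes, slopes[1:])):
        raise UnidentifiableBreakpointError(
            "all segment slopes equal: data lie on a single line")

    n = len(x)
    rmse = float(np.sqrt(rss / n))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - rss / sst if sst > 0 else float("nan")
    return PiecewiseFit(
        breakpoints=tuple(float(t) for t in thetas),
        slopes=tuple(float(s) for s in slopes),
        intercept=float(coef[0]),
        rmse=rmse, r2=r2,
        se_breakpoints=tuple(float(s) for s in se),
        n=n, x_range=(x_lo, x_hi), converged=converged,
    )


def _extract_xy(records):
    if isinstance(records, tuple) and len(records) == 2:
        return np.asarray(records[0], float), np.asarray(records[1], float)
    kept = [r for r in records if "psi_min_above_psi_pd" not in r.flags]
    return (np.array([r.psi_pd for r in kept]),
            np.array([r.psi_min for r in kept]))


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def intersect_one_to_one(fit: PiecewiseFit, phase3_only: bool = False) -> OneToOneIntersection:
    """Ψ where the piecewise model crosses the 1:1 line (Ψ_pd = Ψ_min).

    Each segment's line ``c + β·x`` crosses the 1:1 line at ``c/(1 − β)``;
    the crossing counts when it falls inside that segment's domain (phase
    III's domain extends to −∞, so its leftward extension is automatic).
    With ``phase3_only`` the driest segment's line is intersected regardless
    of the breakpoints.  A crossing beyond the observed Ψ_pd range is
    returned with ``extrapolated=True``.
    """
    cs = fit.segment_intercepts()
    k = len(fit.slopes)
    # domains, wet to dry: [theta1, 0], [theta2, theta1), ..., (-inf, theta_last);
    # water potentials are non-positive, so the wettest segment stops at 0
    bounds = []
    bps = list(fit.breakpoints)
    for i in range(k):
        hi = 0.0 if i == 0 else bps[i - 1]
        lo = -np.inf if i == k - 1 else bps[i]
        bounds.append((lo, hi))

    candidates = []
    for i, (c, b, (lo, hi)) in enumerate(zip(cs, fit.slopes, bounds), start=1):
        if phase3_only and i != k:
            continue
        if abs(1.0 - b) < 1e-12:
            if abs(c) < 1e-12:
                # segment coincides with the 1:1 line: boundary of domain
                candidates.append((max(lo, fit.x_range[0]), i))
            continue
        x_star = c / (1.0 - b)
        if phase3_only or (lo - 1e-9 <= x_star < hi + 1e-9):
            candidates.append((x_star, i))
    if not candidates:
        raise NoIntersectionError(
            "piecewise model never meets the 1:1 line "
            "(driest-phase slope 1 with nonzero offset)")
    # the physiologically meaningful crossing is the driest (most negative)
    psi, seg = min(candidates, key=lambda t: t[0])
    extrapolated = psi < fit.x_range[0] - 1e-12
    if extrapolated:
        logger.info("1:1 intersection at %.3f MPa lies beyond the observed "
                    "range (%.3f MPa): extrapolated", psi, fit.x_range[0])
    return OneToOneIntersection(psi=float(psi), extrapolated=extrapolated, segment=seg)


def phase_report(fit: PiecewiseFit, thresholds: dict) -> list[dict]:
    """Order breakpoints and physiological thresholds from wet to dry.

    ``thresholds`` supplies ``psi_gs90``, ``psi_tlp`` and ``p50`` (all
    negative MPa).  The returned rows are sorted least → most negative and
    carry the avoidance-strategy checks Ψ_gs90 > Ψ_TLP and Ψ_gs90 > P50
    (stomata close before turgor loss and before half the xylem cavitates).
    Ties are reported explicitly and fail the strict checks.
    """
    events = {"theta1": fit.theta1, "theta2": fit.theta2,
              "psi_gs90": thresholds["psi_gs90"],
              "psi_tlp": thresholds["psi_tlp"],
              "p50": thresholds["p50"]}
    ordered = sorted(events.items(), key=lambda kv: -kv[1])
    gs90, tlp, p50 = events["psi_gs90"], events["psi_tlp"], events["p50"]
    rows = []
    for rank, (name, value) in enumerate(ordered, start=1):
        tied_with = [n for n, v in events.items() if n != name and v == value]
        rows.append({"rank": rank, "event": name, "psi_mpa": value,
                     "tied_with": ",".join(tied_with)})
    checks = {"gs90_above_tlp": gs90 > tlp, "gs90_above_p50": gs90 > p50}
    for row in rows:
        row.update(checks)
    return rows
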