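"""Pressure–volume curve analysis: turgor loss point and derived traits.

A PV curve follows leaf water potential (Ψ_L) and fresh mass while an
excised leaf slowly dehydrates on the bench.  Past the turgor loss point
(TLP) the pressure component vanishes and Ψ_L equals the osmotic
potential, so 1/Ψ_L is linear in (100 − RWC).  The analysis locates the
TLP as the inflection of the 1/Ψ_L vs RWC curve, then extracts

    π_o       osmotic potential at full turgor (reported as a positive
              magnitude, while Ψ_TLP keeps its negative sign)
    Ψ_TLP     water potential at turgor loss
    RWC_TLP   relative water content at turgor loss (%)
    ε         bulk modulus of elasticity: slope of turgor pressure vs
              RWC/100 between full turgor and the TLP (MPa)
    C_FT      capacitance at full turgor, slope of RWC/100 vs Ψ_L over the
              supra-TLP region normalized by leaf water mass per area
              (mol m⁻² MPa⁻¹)
    SWC       saturated water content, (sat − dry)/dry (g g⁻¹)

The osmotic model assumes zero apoplastic water (Ψ_π = −π_o·100/RWC);
the apoplastic fraction is exposed as an optional parameter but defaults
to 0 because bench protocols rarely estimate it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (InsufficientDataError, InvalidRecordError,
                     NoTurgorLossError, logger)
from .measurements import MOLAR_MASS_WATER, compute_rwc

#: linearity criterion for the post-TLP tail of 1/Ψ vs (100 − RWC)
TAIL_R2_ACCEPT = 0.99
TAIL_R2_MINIMUM = 0.98


@dataclass
class PVCurve:
    """Bench-drying series for one leaf.

    ``psi`` are signed MPa (< 0 except possibly the first, fully turgid
    reading); points may arrive in any order and are sorted wettest-first.
    A fresh-mass increase along the drying sequence is flagged.
    """

    leaf_id: str
    psi: np.ndarray
    fresh_mass: np.ndarray
    dry_mass: float
    sat_mass: float
    leaf_area: float | None = None
    cultivar: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.fresh_mass = np.asarray(self.fresh_mass, dtype=float)
        if self.dry_mass >= self.sat_mass:
            raise InvalidRecordError(
                f"leaf {self.leaf_id}: dry mass must be below saturated mass")
        if np.any(np.diff(self.fresh_mass) > 0):
            self.flags = self.flags + ("fresh_mass_not_monotonic",)
        order = np.argsort(self.fresh_mass)[::-1]  # wettest first
        self.psi = self.psi[order]
        self.fresh_mass = self.fresh_mass[order]

    @property
    def rwc(self) -> np.ndarray:
        return compute_rwc(self.fresh_mass, self.dry_mass, self.sat_mass)

    @property
    def swc(self) -> float:
        return (self.sat_mass - self.dry_mass) / self.dry_mass


def curves_from_frame(df: pd.DataFrame) -> list[PVCurve]:
    """Build per-leaf curves from a validated ``pv_curve`` table."""
    curves = []
    for leaf_id, grp in df.groupby("leaf_id", sort=True):
        area = None
        if "leaf_area_m2" in grp.columns and grp["leaf_area_m2"].notna().any():
            area = float(grp["leaf_area_m2"].dropna().iloc[0])
        cultivar = str(grp["cultivar"].iloc[0]) if "cultivar" in grp.columns else ""
        curves.append(PVCurve(
            leaf_id=str(leaf_id),
            psi=grp["psi_mpa"].to_numpy(),
            fresh_mass=grp["fresh_mass_g"].to_numpy(),
            dry_mass=float(grp["dry_mass_g"].iloc[0]),
            sat_mass=float(grp["sat_mass_g"].iloc[0]),
            leaf_area=area, cultivar=cultivar))
    return curves


@dataclass
class TLPResult:
    """Turgor-loss-point location plus the post-TLP osmotic line."""

    psi_tlp: float
    rwc_tlp: float
    pi_o: float            # positive magnitude
    tail_start: int        # index (wettest-first order) of first tail point
    tail_r2: float
    degenerate: bool = False


@dataclass
class PVTraits:
    """Full trait set extracted from one PV curve."""

    leaf_id: str
    pi_o: float
    psi_tlp: float
    rwc_tlp: float
    epsilon: float
    c_ft: float
    swc: float
    cultivar: str = ""
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {"leaf_id": self.leaf_id, "cultivar": self.cultivar,
                "pi_o": self.pi_o, "psi_tlp": self.psi_tlp,
                "rwc_tlp": self.rwc_tlp, "epsilon": self.epsilon,
                "c_ft": self.c_ft, "swc": self.swc}


def _linfit(x: np.ndarray, y: np.ndarray):
    """Least-squares line; returns (slope, intercept, r2, rmse)."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return float(coef[0]), float(coef[1]), r2, float(np.sqrt(sse / len(x)))


def find_tlp(curve: PVCurve) -> TLPResult:
    """Locate the turgor loss point from the linear post-TLP tail.

    Working driest-first on z = 1/Ψ against u = 100 − RWC, candidate tails
    grow from the driest 3 points and the longest tail whose linear fit
    keeps R² ≥ 0.99 sets the search region.  Its wet boundary is then
    refined against the line fitted to the driest half of that region
    (clean even when the global R² criterion admits shoulder points):
    points are accepted while their one-sided residual — still-turgid
    points always fall below the osmotic line in 1/Ψ — stays above a
    threshold of 3× the core RMSE, inflated towards the wet end by the
    local Ψ² ratio because 1/Ψ noise scales as σ_Ψ/Ψ².  π_o is
    −1/intercept of the tail line at u = 0 (full saturation); Ψ_TLP and
    RWC_TLP are read at the tail's wettest point.
    """
    if len(curve.psi) < 8:
        raise InsufficientDataError(
            f"leaf {curve.leaf_id}: need >= 8 PV points, have {len(curve.psi)}")
    if np.any(curve.psi[1:] >= 0):
        raise InvalidRecordError(
            f"leaf {curve.leaf_id}: non-negative psi beyond the first point")
    # readings at (or numerically indistinguishable from) full turgor have
    # no usable 1/psi; drop them from the tail search (they still belong
    # to the supra-TLP regressions)
    neg = curve.psi < -0.01
    rwc = curve.rwc[neg]
    psi = curve.psi[neg]
    n = len(psi)
    # driest-first views (curve is stored wettest-first)
    u = (100.0 - rwc)[::-1]
    z = (1.0 / psi)[::-1]

    best_m = None
    best_r2 = -np.inf
    for m in range(3, n + 1):
        _, _, r2, _ = _linfit(u[:m], z[:m])
        if r2 > best_r2:
            best_r2 = r2
        if r2 >= TAIL_R2_ACCEPT:
            best_m = m
    if best_m is None:
        raise NoTurgorLossError(
            f"leaf {curve.leaf_id}: no linear post-TLP tail "
            f"(best tail R² = {best_r2:.4f} < {TAIL_R2_MINIMUM})")

    # refine the wet boundary.  A still-turgid point lies *below* the
    # osmotic line in 1/psi (its psi is less negative than the osmotic
    # component alone), so the test is one-sided; the residual scale comes
    # from the driest core of the tail so that shoulder points admitted by
    # the global R² criterion cannot inflate their own acceptance threshold.
    zscale = max(np.ptp(z), abs(np.mean(z)))
    # the driest half of the R²-selected tail is clean even when the global
    # criterion admitted a contiguous run of shoulder points at its wet end
    core = max(3, best_m // 2)
    slope, icpt, _, rmse_core = _linfit(u[:core], z[:core])
    # 1/psi noise is heteroskedastic (sd ≈ sd_psi/psi²): the residual
    # scale estimated on the dry core must be inflated towards the wet
    # end by the local psi ratio before testing each candidate point
    psi_dry_first = psi[::-1]
    psi_core = float(np.median(psi_dry_first[:core]))
    m = core
    while m < n:
        local = rmse_core * (psi_core / psi_dry_first[m]) ** 2
        if z[m] - (slope * u[m] + icpt) < -max(3.0 * local, 1e-7 * zscale):
            break
        m += 1

    slope, icpt, r2, _ = _linfit(u[:m], z[:m])
    if icpt >= 0:
        raise NoTurgorLossError(
            f"leaf {curve.leaf_id}: osmotic line extrapolates to a "
            "non-negative 1/psi at full saturation")
    degenerate = m >= n
    if degenerate:
        logger.warning("leaf %s: whole series linear in 1/psi; turgid phase "
                       "empty (degenerate PV curve)", curve.leaf_id)
    # index of tail boundary in wettest-first order (within the psi<0 subset)
    tail_start = n - m
    return TLPResult(
        psi_tlp=float(psi[tail_start]),
        rwc_tlp=float(rwc[tail_start]),
        pi_o=float(-1.0 / icpt),
        tail_start=tail_start,
        tail_r2=r2,
        degenerate=degenerate,
    )


def _supra_tlp(curve: PVCurve, tlp: TLPResult):
    """Supra-TLP points (full turgor down to and including the boundary)."""
    mask = curve.rwc >= tlp.rwc_tlp - 1e-12
    return curve.rwc[mask], curve.psi[mask]


def compute_elasticity(curve: PVCurve, tlp: TLPResult,
                       apoplastic_fraction: float = 0.0) -> float:
    """Bulk modulus of elasticity ε (MPa) over the supra-TLP phase.

    Turgor pressure is Ψ_p = Ψ − Ψ_π with the osmotic component
    Ψ_π = −π_o·(100 − a_f·100)/(RWC − a_f·100) (a_f = apoplastic water
    fraction, default 0); ε is the least-squares slope of Ψ_p against
    RWC/100 between full turgor and the TLP.
    """
    rwc, psi = _supra_tlp(curve, tlp)
    if len(rwc) < 3:
        raise InsufficientDataError(
            f"leaf {curve.leaf_id}: need >= 3 supra-TLP points, have {len(rwc)}")
    af = apoplastic_fraction * 100.0
    psi_pi = -tlp.pi_o * (100.0 - af) / (rwc - af)
    psi_p = psi - psi_pi
    slope, _, _, _ = _linfit(rwc / 100.0, psi_p)
    if slope <= 0:
        logger.warning("leaf %s: nonphysical elasticity %.3f MPa (no turgor "
                       "decline with dehydration)", curve.leaf_id, slope)
    return slope


def compute_capacitance(curve: PVCurve, tlp: TLPResult) -> float:
    """Leaf capacitance at full turgor, C_FT (mol m⁻² MPa⁻¹).

    C_FT = slope(RWC/100 vs Ψ_L over the supra-TLP region)
           × (sat − dry) / (M_w · leaf_area),  M_w = 18.015 g mol⁻¹.
    The mass term converts the dimensionless relative slope into moles of
    exchangeable water per unit leaf area and pressure.
    """
    rwc, psi = _supra_tlp(curve, tlp)
    if len(rwc) < 3:
        raise InsufficientDataError(
            f"leaf {curve.leaf_id}: need >= 3 supra-TLP points, have {len(rwc)}")
    slope, _, _, _ = _linfit(psi, rwc / 100.0)
    water_mass = curve.sat_mass - curve.dry_mass
    if curve.leaf_area is None or not np.isfinite(curve.leaf_area):
        unnorm = slope * water_mass / MOLAR_MASS_WATER
        raise InvalidRecordError(
            f"leaf {curve.leaf_id}: leaf_area missing; cannot normalize "
            f"capacitance (unnormalized value {unnorm:.6g} mol MPa⁻¹)")
    c_ft = slope * water_mass / (MOLAR_MASS_WATER * curve.leaf_area)
    if c_ft <= 0:
        logger.warning("leaf %s: nonphysical capacitance %.3g", curve.leaf_id, c_ft)
    return c_ft


def analyze_pv(curve: PVCurve, apoplastic_fraction: float = 0.0) -> PVTraits:
    """Extract the full PV trait set (π_o, Ψ_TLP, RWC_TLP, ε, C_FT, SWC)."""
    tlp = find_tlp(curve)
    try:
        eps = compute_elasticity(curve, tlp, apoplastic_fraction)
        c_ft = compute_capacitance(curve, tlp)
    except InsufficientDataError as exc:
        # degenerate curve with an empty turgid phase: tail-only traits
        logger.warning(str(exc))
        eps = c_ft = float("nan")
    except InvalidRecordError as exc:
        logger.warning(str(exc))
        c_ft = float("nan")
    flags = curve.flags
    if tlp.degenerate:
        flags = flags + ("degenerate_pv_curve",)
    return PVTraits(
        leaf_id=curve.leaf_id, pi_o=tlp.pi_o, psi_tlp=tlp.psi_tlp,
        rwc_tlp=tlp.rwc_tlp, epsilon=eps, c_ft=c_ft, swc=curve.swc,
        cultivar=curve.cultivar, flags=flags)
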