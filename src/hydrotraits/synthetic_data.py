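"""Synthetic pot-desiccation data with known ground truth.

Generates every input the analysis consumes — drydown water-potential and
gas-exchange trajectories, pot weights, Weibull-shaped vulnerability
curves measured at the standard air-injection pressure steps, and ideal
pressure–volume curves — from cultivar presets with known parameters, so
each fitting module can be verified by parameter recovery.

The drydown is a minimal daily water-balance model, not mechanistic soil
physics.  Each day, for a potted plant under the desiccation (PD)
treatment:

1. substrate water potential (≈ pre-dawn leaf water potential) follows a
   two-constant retention curve  Ψ_pd = −a·(100/GWC − 1)^n;
2. midday water potential satisfies the steady-state supply balance
   Ψ_min = Ψ_pd − E / (K_plant·(1 − PLC(Ψ_min)/100)), solved by damped
   fixed-point iteration, where transpiration E tracks stomatal
   conductance gs = gs_max·exp(k·Ψ_min) and PLC follows the preset's
   Weibull curve;
3. the transpired mass is withdrawn from the substrate, so cumulative
   transpiration equals the substrate water deficit exactly.

Well-watered (WW) plants hold GWC at 100.  Gaussian observation noise is
applied per channel from independent substreams of one global seed, so
adding noise to one channel never shifts another.  The three shipped
presets are *patterned on* published almond cultivar traits (they encode
printed trait values as generator targets); they are labelled "-like" and
never claim to reproduce the measured data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidRecordError, logger
from .pressure_volume import PVCurve
from .vulnerability import DEFAULT_PRESSURE_STEPS, VulnerabilityCurve

LN2 = float(np.log(2.0))

#: channel name -> substream index (stable across releases)
_CHANNELS = {"plants": 0, "psi_pd": 1, "psi_min": 2, "gs": 3, "a_n": 4,
             "e": 5, "gwc": 6, "kh": 7, "pv_psi": 8, "stems": 9, "leaves": 10}


def _rng(seed: int, channel: str) -> np.random.Generator:
    return np.random.default_rng([_CHANNELS[channel], seed])


@dataclass
class CultivarPreset:
    """Generator parameter bundle for one virtual cultivar.

    ``weibull_b``/``weibull_c`` give the vulnerability curve (P50 magnitude
    = b·(ln 2)^(1/c)); ``k_stomatal`` sets the kinetic gs decline (Ψ_gs90 =
    ln(0.1)/k); ``pi_o``/``epsilon`` define the ideal PV curve (Ψ_TLP =
    −π_o·ε/(ε − π_o) under zero apoplast).  ``retention_a`` (MPa) and
    ``retention_n`` shape the substrate water-retention curve, and
    ``plant_conductance`` (mmol m⁻² s⁻¹ MPa⁻¹) the soil-to-leaf supply
    path.  ``noise_sd`` holds per-channel observation noise (absolute MPa
    for water potentials, relative fractions for flux channels).
    """

    label: str
    gs_max: float                  # mmol m-2 s-1
    k_stomatal: float              # MPa-1
    a_max: float                   # µmol CO2 m-2 s-1
    e_per_gs: float                # E/gs ratio (mol/mol)
    pi_o: float                    # MPa, positive magnitude
    epsilon: float                 # MPa
    weibull_b: float               # MPa
    weibull_c: float
    retention_a: float             # MPa
    retention_n: float
    plant_conductance: float       # mmol m-2 s-1 MPa-1
    transp_kg_per_e: float = 0.08   # kg water lost per day per unit E
    water_capacity_kg: float = 2.0
    pot_dry_kg: float = 4.0
    leaf_dry_mass_g: float = 0.20
    leaf_sat_mass_g: float = 0.60
    leaf_area_m2: float = 0.0012
    noise_sd: dict = field(default_factory=lambda: {
        "psi_pd": 0.08, "psi_min": 0.15, "gs": 0.08, "a_n": 0.08,
        "e": 0.08, "gwc": 1.0, "kh": 0.05, "pv_psi": 0.01})

    @property
    def p50(self) -> float:
        """P50 implied by the Weibull parameters (negative MPa)."""
        return -self.weibull_b * LN2 ** (1.0 / self.weibull_c)

    @property
    def psi_gs90(self) -> float:
        return float(np.log(0.1)) / self.k_stomatal

    @property
    def psi_tlp(self) -> float:
        return -self.pi_o * self.epsilon / (self.epsilon - self.pi_o)

    def plc(self, psi: float) -> float:
        return 100.0 * (1.0 - np.exp(-(abs(psi) / self.weibull_b) ** self.weibull_c))


def _b_for_p50(p50_magnitude: float, c: float) -> float:
    return p50_magnitude / LN2 ** (1.0 / c)


def _pi_o_for_tlp(tlp_magnitude: float, epsilon: float) -> float:
    # invert psi_tlp = -pi_o*eps/(eps - pi_o)
    return tlp_magnitude * epsilon / (epsilon + tlp_magnitude)


# Presets patterned on published almond cultivar trait tables (maximum
# gas exchange, PV traits, P50, stomatal-closure thresholds).  pi_o is
# back-computed from the target turgor-loss point and elasticity so the
# zero-apoplast PV model lands on the target Ψ_TLP; weibull_b is
# back-computed from the target P50 at shape c = 3.  plant_conductance is
# set so the early-drydown midday offset E/K matches each cultivar's
# stomatal-regulation stringency (largest for the most anisohydric
# virtual cultivar, smallest for the most isohydric), and together with
# the per-pot drying rate it fixes the generator's design target: the
# hydroscape-area ordering isabelona-like < avijor-like < soleta-like.
PRESETS: dict[str, CultivarPreset] = {
    "avijor-like": CultivarPreset(
        label="avijor-like", gs_max=363.32, k_stomatal=np.log(10.0) / 1.72,
        a_max=12.24, e_per_gs=5.18 / 363.32,
        pi_o=_pi_o_for_tlp(2.01, 12.91), epsilon=12.91,
        weibull_b=_b_for_p50(2.97, 3.0), weibull_c=3.0,
        retention_a=1.00, retention_n=1.5, plant_conductance=0.929,
        transp_kg_per_e=0.12),
    "isabelona-like": CultivarPreset(
        label="isabelona-like", gs_max=517.39, k_stomatal=np.log(10.0) / 2.25,
        a_max=11.24, e_per_gs=6.31 / 517.39,
        pi_o=_pi_o_for_tlp(2.31, 11.38), epsilon=11.38,
        weibull_b=_b_for_p50(3.80, 3.0), weibull_c=3.0,
        retention_a=1.00, retention_n=1.5, plant_conductance=3.48,
        transp_kg_per_e=0.04),
    "soleta-like": CultivarPreset(
        label="soleta-like", gs_max=623.36, k_stomatal=np.log(10.0) / 2.14,
        a_max=13.22, e_per_gs=6.83 / 623.36,
        pi_o=_pi_o_for_tlp(2.87, 11.85), epsilon=11.85,
        weibull_b=_b_for_p50(3.73, 3.0), weibull_c=3.0,
        retention_a=1.00, retention_n=1.5, plant_conductance=0.807,
        transp_kg_per_e=0.12),
}


@dataclass
class DrydownTrajectory:
    """Simulated daily records plus the hidden true state and water ledger."""

    frame: pd.DataFrame
    ground_truth: dict

    def water_balance_residual(self) -> float:
        """Cumulative transpiration minus substrate water deficit (kg);
        zero up to floating point under the model's conservation law."""
        gt = self.ground_truth
        return abs(gt["cum_transpiration_kg"]
                   - (gt["initial_water_kg"] - gt["final_water_kg"]))


def _solve_psi_min(preset: CultivarPreset, psi_pd: float,
                   max_iter: int = 50, tol: float = 1e-10) -> float:
    """Damped fixed point of Ψ = Ψ_pd − E(Ψ)/(K·(1 − PLC(Ψ)/100))."""
    psi = psi_pd - 0.5
    for _ in range(max_iter):
        gs = preset.gs_max * np.exp(preset.k_stomatal * psi)
        e = preset.e_per_gs * gs
        k_eff = preset.plant_conductance * (1.0 - preset.plc(psi) / 100.0)
        if k_eff <= 1e-9:
            raise InvalidRecordError("hydraulic pathway fully cavitated")
        target = psi_pd - e / k_eff
        new = 0.5 * psi + 0.5 * target
        if abs(new - psi) < tol:
            return float(new)
        psi = new
    raise InvalidRecordError(
        f"midday water-potential fixed point did not converge at psi_pd={psi_pd:.3f}")


#: measurement occasions (days since treatment start) of the emulated
#: pot-desiccation protocol: water potentials and gas exchange are read on
#: nine days spread over the 50-day drydown, not every day
PROTOCOL_SAMPLE_DAYS = (1, 9, 15, 20, 23, 27, 35, 44, 50)


def simulate_drydown(preset: CultivarPreset, days: int = 50,
                     treatment: str = "PD", n_plants: int = 8,
                     seed: int = 0, sample_days=None) -> DrydownTrajectory:
    """Simulate a pot-desiccation (or well-watered) trajectory.

    The substrate water balance advances daily, but observations (with
    noise) are recorded only on ``sample_days`` — by default the nine
    measurement occasions of the emulated protocol, clipped to ``days``
    (pass ``"all"`` for daily records).  Plants differ by a small
    multiplicative random effect on gs_max drawn from the plant
    substream.  Deterministic given all arguments.
    """
    if treatment not in ("WW", "PD"):
        raise InvalidRecordError(f"treatment must be WW or PD, got {treatment!r}")
    if sample_days is None:
        observed = {d for d in PROTOCOL_SAMPLE_DAYS if d <= days} | {days}
    elif sample_days == "all":
        observed = set(range(1, days + 1))
    else:
        observed = {int(d) for d in sample_days}
    plant_rng = _rng(seed, "plants")
    noise = {ch: _rng(seed, ch) for ch in ("psi_pd", "psi_min", "gs", "a_n", "e", "gwc")}
    sd = preset.noise_sd

    rows = []
    cum_transp = 0.0
    init_water = preset.water_capacity_kg * n_plants
    final_water = 0.0
    for p in range(n_plants):
        gs_scale = float(np.exp(plant_rng.normal(0.0, 0.06)))
        water = preset.water_capacity_kg
        plant_id = f"{preset.label}-{treatment}-{p + 1:02d}"
        for day in range(1, days + 1):
            gwc = 100.0 * water / preset.water_capacity_kg
            psi_pd = -preset.retention_a * (100.0 / gwc - 1.0) ** preset.retention_n
            pl = replace(preset, gs_max=preset.gs_max * gs_scale)
            psi_min = _solve_psi_min(pl, psi_pd)
            gs = pl.gs_max * np.exp(pl.k_stomatal * psi_min)
            e = pl.e_per_gs * gs
            a_n = pl.a_max * (gs / pl.gs_max) ** 0.8
            ci = 400.0 * (0.50 + 0.25 * gs / pl.gs_max)
            if day in observed:
                rows.append({
                    "plant_id": plant_id, "cultivar": preset.label,
                    "treatment": treatment, "day": day,
                    "gwc_true": gwc, "psi_pd_true": psi_pd,
                    "psi_min_true": psi_min,
                    "gs_true": gs, "a_n_true": a_n, "e_true": e,
                    "gwc": gwc + noise["gwc"].normal(0.0, sd["gwc"]),
                    "psi_pd": min(psi_pd + noise["psi_pd"].normal(0.0, sd["psi_pd"]), 0.0),
                    "psi_min": psi_min + noise["psi_min"].normal(0.0, sd["psi_min"]),
                    "gs": gs * (1.0 + noise["gs"].normal(0.0, sd["gs"])),
                    "a_n": a_n * (1.0 + noise["a_n"].normal(0.0, sd["a_n"])),
                    "e": e * (1.0 + noise["e"].normal(0.0, sd["e"])),
                    "ci": ci,
                    "pot_dry": preset.pot_dry_kg,
                    "pot_wet": preset.pot_dry_kg + preset.water_capacity_kg,
                    "pot": preset.pot_dry_kg + water,
                })
            if treatment == "PD":
                loss = min(preset.transp_kg_per_e * e, water * 0.5)
                water -= loss
                cum_transp += loss
        final_water += water

    frame = pd.DataFrame(rows)
    # enforce the paired-measurement invariant on the noisy channel too
    bad = frame["psi_min"] > frame["psi_pd"]
    frame.loc[bad, "psi_min"] = frame.loc[bad, "psi_pd"]
    gt = {"preset": {k: v for k, v in asdict(preset).items() if k != "noise_sd"},
          "treatment": treatment, "days": days, "n_plants": n_plants, "seed": seed,
          "p50": preset.p50, "psi_gs90": preset.psi_gs90, "psi_tlp": preset.psi_tlp,
          "initial_water_kg": init_water,
          "final_water_kg": final_water if treatment == "PD" else init_water,
          "cum_transpiration_kg": cum_transp}
    return DrydownTrajectory(frame=frame, ground_truth=gt)


def simulate_vulnerability(preset: CultivarPreset,
                           pressure_steps=DEFAULT_PRESSURE_STEPS,
                           n_stems: int = 3, seed: int = 0,
                           noise_sd: float | None = None) -> list[VulnerabilityCurve]:
    """Weibull-shaped vulnerability curves at the standard pressure steps.

    kh = kmax·exp(−(P/b)^c)·(1 + ε_noise) with multiplicative Gaussian
    noise (preset default 5%); stem kmax varies by a lognormal factor.
    """
    if preset.weibull_b <= 0 or preset.weibull_c <= 0:
        raise InvalidRecordError("Weibull parameters must be positive")
    p = np.asarray(pressure_steps, dtype=float)
    sd = preset.noise_sd["kh"] if noise_sd is None else noise_sd
    stem_rng = _rng(seed, "stems")
    kh_rng = _rng(seed, "kh")
    curves = []
    for s in range(n_stems):
        kmax = float(np.exp(stem_rng.normal(0.0, 0.10)))
        kh = kmax * np.exp(-(p / preset.weibull_b) ** preset.weibull_c)
        if sd > 0:
            kh = kh * (1.0 + kh_rng.normal(0.0, sd, size=len(p)))
        kh = np.clip(kh, 0.0, None)
        curves.append(VulnerabilityCurve(
            stem_id=f"{preset.label}-stem-{s + 1}",
            pressures=p, kh=kh, kmax=kmax, cultivar=preset.label))
    return curves


def simulate_pv_curve(preset: CultivarPreset, n_points: int = 81,
                      seed: int = 0, leaf_id: str | None = None,
                      noise_sd: float | None = None,
                      rwc_min: float = 60.0) -> PVCurve:
    """Ideal zero-apoplast PV curve sampled over RWC ∈ [rwc_min, 100].

    Ψ_π = −π_o·100/RWC;  Ψ_p = max(0, π_o − ε·(1 − RWC/100));
    Ψ = Ψ_π + Ψ_p; fresh masses are back-computed from RWC.  Below the
    turgor loss point 1/Ψ is exactly linear in (100 − RWC) by
    construction.
    """
    if preset.pi_o >= preset.epsilon:
        raise InvalidRecordError(
            f"degenerate preset: pi_o ({preset.pi_o}) >= epsilon "
            f"({preset.epsilon}) puts the TLP above the data range")
    rwc = np.linspace(100.0, rwc_min, n_points)
    psi_pi = -preset.pi_o * 100.0 / rwc
    psi_p = np.maximum(0.0, preset.pi_o - preset.epsilon * (1.0 - rwc / 100.0))
    psi = psi_pi + psi_p
    sd = preset.noise_sd["pv_psi"] if noise_sd is None else noise_sd
    if sd > 0:
        psi = psi + _rng(seed, "pv_psi").normal(0.0, sd, size=n_points)
        psi = np.minimum(psi, -1e-6)
    fresh = preset.leaf_dry_mass_g + rwc / 100.0 * (
        preset.leaf_sat_mass_g - preset.leaf_dry_mass_g)
    return PVCurve(
        leaf_id=leaf_id or f"{preset.label}-leaf-1",
        psi=psi, fresh_mass=fresh,
        dry_mass=preset.leaf_dry_mass_g, sat_mass=preset.leaf_sat_mass_g,
        leaf_area=preset.leaf_area_m2, cultivar=preset.label)


# ---------------------------------------------------------------------------
# CSV bundle
# ---------------------------------------------------------------------------

def write_input_bundle(outdir: str | Path, presets=None, days: int = 50,
                       n_plants: int = 8, n_stems: int = 3, n_leaves: int = 4,
                       seed: int = 0) -> dict:
    """Write the five input CSV schemas plus ground_truth.json.

    Simulates each preset under both treatments and emits
    ``water_potential.csv``, ``gas_exchange.csv``, ``pot_weights.csv``,
    ``vulnerability.csv`` and ``pv_curve.csv`` in ``outdir``.  Byte-
    deterministic given the same presets and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if presets is None:
        presets = list(PRESETS.values())

    wp, gx, pw, vc_rows, pv_rows = [], [], [], [], []
    truth = {}
    for i, preset in enumerate(presets):
        pseed = seed + 1000 * i
        for treatment in ("PD", "WW"):
            traj = simulate_drydown(preset, days=days, treatment=treatment,
                                    n_plants=n_plants, seed=pseed)
            f = traj.frame
            wp.append(f[["plant_id", "day", "psi_pd", "psi_min",
                         "cultivar", "treatment"]])
            gx.append(f[["plant_id", "day", "a_n", "gs", "e", "ci",
                         "cultivar", "treatment"]])
            pw.append(f[["plant_id", "day", "pot", "pot_dry", "pot_wet",
                         "cultivar", "treatment"]])
            if treatment == "PD":
                truth[preset.label] = traj.ground_truth
        for curve in simulate_vulnerability(preset, n_stems=n_stems, seed=pseed):
            vc_rows.append(pd.DataFrame({
                "stem_id": curve.stem_id, "pressure_mpa": curve.pressures,
                "kh": curve.kh, "kmax": curve.kmax, "cultivar": curve.cultivar}))
        leaf_rng = _rng(pseed, "leaves")
        for leaf in range(n_leaves):
            scale = float(np.exp(leaf_rng.normal(0.0, 0.05)))
            p_leaf = replace(preset,
                             leaf_dry_mass_g=preset.leaf_dry_mass_g * scale,
                             leaf_sat_mass_g=preset.leaf_sat_mass_g * scale)
            curve = simulate_pv_curve(p_leaf, seed=pseed + leaf,
                                      leaf_id=f"{preset.label}-leaf-{leaf + 1}")
            pv_rows.append(pd.DataFrame({
                "leaf_id": curve.leaf_id, "psi_mpa": curve.psi,
                "fresh_mass_g": curve.fresh_mass, "dry_mass_g": curve.dry_mass,
                "sat_mass_g": curve.sat_mass, "leaf_area_m2": curve.leaf_area,
                "cultivar": curve.cultivar}))

    paths = {}
    for name, frames in (("water_potential", wp), ("gas_exchange", gx),
                         ("pot_weights", pw), ("vulnerability", vc_rows),
                         ("pv_curve", pv_rows)):
        path = outdir / f"{name}.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        paths[name] = str(path)
    gt_path = outdir / "ground_truth.json"
    gt_path.write_text(json.dumps(truth, indent=2, default=float))
    paths["ground_truth"] = str(gt_path)
    logger.info("wrote synthetic input bundle to %s (seed=%d)", outdir, seed)
    return paths
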