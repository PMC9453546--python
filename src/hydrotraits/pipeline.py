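"""End-to-end orchestration: config, staged analysis, report bundle.

``run_all`` executes measurements → hydroscape → water-potential curve →
vulnerability → pressure–volume → stomatal response on the five input
CSVs and emits a per-cultivar trait table (σ, hydroscape, SWC, π_o,
Ψ_TLP, RWC_TLP, ε, C_FT, Ψ_gs90, P50, HSM), the piecewise-fit table with
the 1:1-line intersection, the wet-to-dry phase ordering with the
avoidance-strategy checks, and a machine-readable JSON-lines ledger of
every fit's diagnostics and seed.  Outputs are a pure function of
(input files, config, seeds): rerunning the same config reproduces them
byte for byte.

A stage whose input file is absent is skipped with a warning; a stage
that errors halts the run naming the stage, with the outputs of earlier
stages already written.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (hydroscape, measurements, pressure_volume, stomatal_response,
               vulnerability, wp_curve)
from .errors import HydrotraitsError, logger


@dataclass
class RunConfig:
    """Declarative run description; CLI flags override these values."""

    water_potential: str | None = None
    gas_exchange: str | None = None
    pot_weights: str | None = None
    vulnerability: str | None = None
    pv_curve: str | None = None
    outdir: str = "hydrotraits_out"
    seed: int = 0
    n_boot: int = 1000
    degree: int = 2
    segments: int = 3
    include_well_watered: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise HydrotraitsError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def input_paths(self) -> dict:
        return {"water_potential": self.water_potential,
                "gas_exchange": self.gas_exchange,
                "pot_weights": self.pot_weights,
                "vulnerability": self.vulnerability,
                "pv_curve": self.pv_curve}


class _FitLog:
    """JSON-lines ledger of every fit with its diagnostics and seed."""

    def __init__(self, path: Path):
        self.path = path
        self.entries: list[dict] = []

    def record(self, stage: str, cultivar: str, **payload) -> None:
        entry = {"stage": stage, "cultivar": cultivar, **payload}
        self.entries.append(entry)

    def flush(self) -> None:
        with open(self.path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps(e, default=float) + "\n")


def _by_cultivar(records):
    out: dict[str, list] = {}
    for r in records:
        out.setdefault(r.cultivar or "all", []).append(r)
    return out


def run_all(config: RunConfig) -> dict:
    """Run every available stage; returns {cultivar: {trait: value}}.

    See the module docstring for the emitted files (written to
    ``config.outdir``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _FitLog(outdir / "fit_log.jsonl")
    results: dict[str, dict] = {}
    piecewise_rows, phase_rows = [], []
    stage = "measurements"
    try:
        paths = config.input_paths()
        wp_records = None
        if paths["water_potential"] and Path(paths["water_potential"]).exists():
            wp_records = measurements.read_table(paths["water_potential"],
                                                 "water_potential")
        gx_records = None
        if paths["gas_exchange"] and Path(paths["gas_exchange"]).exists():
            gx_records = measurements.read_table(paths["gas_exchange"],
                                                 "gas_exchange")

        stage = "hydroscape"
        if wp_records:
            for cultivar, recs in _by_cultivar(wp_records).items():
                fit = hydroscape.fit_sigma(
                    recs, include_well_watered=config.include_well_watered)
                results.setdefault(cultivar, {}).update(
                    sigma=fit.sigma, hydroscape=fit.area, hydroscape_a=fit.a,
                    hydroscape_b=fit.b)
                log.record(stage, cultivar, **fit.as_dict())
        else:
            logger.warning("hydroscape stage skipped: no water_potential input")

        stage = "wp_curve"
        if wp_records:
            for cultivar, recs in _by_cultivar(wp_records).items():
                pd_recs = [r for r in recs if r.treatment != "WW"]
                try:
                    fit = wp_curve.fit_piecewise(pd_recs,
                                                 n_segments=config.segments)
                except wp_curve.UnidentifiableBreakpointError as exc:
                    # weakly-phased cultivar: record and carry on
                    logger.warning("%s: piecewise fit unidentifiable (%s)",
                                   cultivar, exc)
                    log.record(stage, cultivar, error=str(exc))
                    continue
                try:
                    inter = wp_curve.intersect_one_to_one(fit)
                    psi_eq, extrap = inter.psi, inter.extrapolated
                except wp_curve.NoIntersectionError as exc:
                    logger.warning("%s: %s", cultivar, exc)
                    psi_eq, extrap = float("nan"), False
                row = {**fit.as_dict(), "psi_equal": psi_eq,
                       "extrapolated": extrap}
                piecewise_rows.append({"cultivar": cultivar, **row})
                results.setdefault(cultivar, {}).update(
                    theta1=fit.theta1, theta2=fit.theta2, psi_equal=psi_eq)
                log.record(stage, cultivar, **row)
        else:
            logger.warning("wp_curve stage skipped: no water_potential input")

        stage = "vulnerability"
        if paths["vulnerability"] and Path(paths["vulnerability"]).exists():
            frame = measurements.read_table(paths["vulnerability"], "vulnerability")
            if isinstance(frame, pd.DataFrame):
                curves = vulnerability.curves_from_frame(frame)
                groups: dict[str, list] = {}
                for c in curves:
                    groups.setdefault(c.cultivar or "all", []).append(c)
                for cultivar, cc in groups.items():
                    fit = vulnerability.fit_weibull(cc)
                    vulnerability.bootstrap_p50(cc, n_boot=config.n_boot,
                                                seed=config.seed, fit=fit)
                    results.setdefault(cultivar, {}).update(p50=fit.p50)
                    log.record(stage, cultivar, **fit.as_dict())
        else:
            logger.warning("vulnerability stage skipped: no input file")

        stage = "pressure_volume"
        if paths["pv_curve"] and Path(paths["pv_curve"]).exists():
            frame = measurements.read_table(paths["pv_curve"], "pv_curve")
            if isinstance(frame, pd.DataFrame):
                traits = [pressure_volume.analyze_pv(c)
                          for c in pressure_volume.curves_from_frame(frame)]
                tf = pd.DataFrame([t.as_dict() for t in traits])
                for cultivar, grp in tf.groupby(
                        tf["cultivar"].replace("", "all")):
                    means = grp[["pi_o", "psi_tlp", "rwc_tlp", "epsilon",
                                 "c_ft", "swc"]].mean()
                    results.setdefault(cultivar, {}).update(means.to_dict())
                    log.record(stage, cultivar, n_leaves=len(grp),
                               **means.to_dict())
        else:
            logger.warning("pressure_volume stage skipped: no input file")

        stage = "stomatal_response"
        if wp_records and gx_records:
            wp_df = pd.DataFrame([{"plant_id": r.plant_id, "day": r.day,
                                   "cultivar": r.cultivar or "all",
                                   "treatment": r.treatment,
                                   "psi_min": r.psi_min} for r in wp_records])
            gx_df = pd.DataFrame([{"plant_id": r.plant_id, "day": r.day,
                                   "gs": r.gs} for r in gx_records])
            merged = wp_df.merge(gx_df, on=["plant_id", "day"])
            merged = merged[merged["treatment"] != "WW"]
            for cultivar, grp in merged.groupby("cultivar"):
                data = (grp["psi_min"].to_numpy(), grp["gs"].to_numpy())
                kin = stomatal_response.fit_gs_kinetic(data)
                rate = stomatal_response.fit_gs_kinetic(data, method="log-linear")
                poly = stomatal_response.fit_psi_gs90(
                    data, degree=config.degree, n_boot=config.n_boot,
                    seed=config.seed)
                # the trait table carries the log-scale kinetic closure
                # point (robust to water-potential measurement error); the
                # linear-scale NLS and polynomial estimates, each with a
                # known dry-ward bias on this data shape, ride alongside
                results.setdefault(cultivar, {}).update(
                    psi_gs90=rate.psi_gs90, psi_gs90_nls=kin.psi_gs90,
                    psi_gs90_poly=poly.psi_gs90,
                    gs_ref=rate.gs_ref, k_stomatal=rate.params[1])
                log.record(stage, cultivar, kinetic=kin.as_dict(),
                           kinetic_log=rate.as_dict(),
                           polynomial=poly.as_dict())
        else:
            logger.warning("stomatal stage skipped: needs water_potential "
                           "and gas_exchange inputs")

        stage = "report"
        for cultivar, res in results.items():
            if "psi_gs90" in res and "p50" in res:
                res["hsm"] = vulnerability.safety_margin(res["psi_gs90"], res["p50"])
            if all(k in res for k in ("theta1", "psi_gs90", "psi_tlp", "p50")):
                fit = next((r for r in piecewise_rows if r["cultivar"] == cultivar),
                           None)
                if fit is not None:
                    pw = wp_curve.PiecewiseFit(
                        breakpoints=(fit["theta1"], fit["theta2"]),
                        slopes=(fit["beta1"], fit["beta2"], fit["beta3"]),
                        intercept=fit["intercept"], rmse=fit["rmse"],
                        r2=fit["r2"], se_breakpoints=(np.nan, np.nan),
                        n=fit["n"], x_range=(-10.0, 0.0))
                    for row in wp_curve.phase_report(pw, {
                            "psi_gs90": res["psi_gs90"],
                            "psi_tlp": res["psi_tlp"], "p50": res["p50"]}):
                        phase_rows.append({"cultivar": cultivar, **row})
    except HydrotraitsError as exc:
        _write_outputs(outdir, results, piecewise_rows, phase_rows, log)
        raise HydrotraitsError(
            f"stage '{stage}' failed: {exc} (partial outputs in {outdir})"
        ) from exc

    _write_outputs(outdir, results, piecewise_rows, phase_rows, log)
    return results


_TRAIT_ORDER = ["sigma", "hydroscape", "swc", "pi_o", "psi_tlp", "rwc_tlp",
                "epsilon", "c_ft", "psi_gs90", "p50", "hsm",
                "theta1", "theta2", "psi_equal"]


def _write_outputs(outdir, results, piecewise_rows, phase_rows, log) -> None:
    if results:
        df = pd.DataFrame.from_dict(results, orient="index")
        cols = [c for c in _TRAIT_ORDER if c in df.columns]
        cols += [c for c in df.columns if c not in cols]
        df = df[cols].sort_index()
        df.index.name = "cultivar"
        df.to_csv(outdir / "traits.csv")
        (outdir / "traits.json").write_text(
            json.dumps(results, indent=2, default=float, sort_keys=True))
    if piecewise_rows:
        pd.DataFrame(piecewise_rows).to_csv(outdir / "piecewise.csv", index=False)
    if phase_rows:
        pd.DataFrame(phase_rows).to_csv(outdir / "phase_report.csv", index=False)
    log.flush()
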