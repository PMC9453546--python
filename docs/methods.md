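# Methods

This note records the models the package implements, the numerical
choices behind each estimator, what the synthetic generator does and
does not emulate, and the known limitations.

## Sign and unit conventions

Plant water potentials are signed MPa (≤ 0) everywhere; vulnerability-
curve applied pressures are positive MPa of tension, and P50/Px are
reported with the plant-side negative sign. π_o is reported as a
positive magnitude (field convention) while Ψ_TLP keeps its sign.
Conductance gs and transpiration E are mmol m⁻² s⁻¹; iWUE = A_N/E is
computed per record and averaged afterwards, never as a ratio of means.
CSV readers auto-negate a water-potential column only when every value
in it is positive, and refuse mixed signs.

## Hydroscape

σ and *a* come from ordinary least squares of Ψ_min on Ψ_pd (the
orientation the metric is defined in); no errors-in-variables
correction is applied, matching standard practice for this metric.
Records with Ψ_min > Ψ_pd are physically inconsistent under steady
drying and are excluded from the fit but counted in diagnostics;
well-watered records are excluded by default because the hydroscape is
a drydown metric. The area uses the closed form a²/(2(1 − σ)) and σ ≥ 1
is reported as an unbounded-hydroscape error rather than NaN. Ranking
is by ascending area with ties broken by σ, then label.

## Piecewise water-potential curve

The three-phase model is continuous piecewise-linear in Ψ_pd with
breakpoints Θ₁ > Θ₂, parameterized with negative-side hinge terms so
that, for fixed breakpoints, the fit is linear least squares.
Breakpoints are estimated by iterative relinearization (gap-term
update Θ ← Θ + g/d) started from a deterministic 10×10 grid over the
inner 80% of the Ψ_pd range (tolerance 1e−8, 100 iterations,
non-convergence falls back to the best visited solution with a logged
warning). Because the profile RSS surface has kinks at the data
abscissae and the relinearization's stationary points are not always
the constrained global optimum, the fit is polished by a deterministic
coarse-to-fine profile-RSS scan (span/40 grid, two ×10 zoom passes)
followed by Nelder–Mead descent; the best valid solution wins.
Validity means both breakpoints at least 0.05 MPa inside the data range
and 0.05 MPa apart; on weakly-phased data the best *valid* stationary
point is preferred over a degenerate lower-RSS one, and if only
degenerate solutions exist an unidentifiable-breakpoint error names the
offending boundary. Standard errors for Θ come from the final
linearization (SE(g)/|d|).

The 1:1-line intersection solves c + βΨ = Ψ segment by segment; the
wettest segment's domain is capped at Ψ = 0, the driest extends to −∞
(so the dry-phase extension is automatic), and a crossing beyond the
observed range is flagged extrapolated. A dry-phase slope of 1 with
nonzero offset has no crossing and raises an error.

At the residual scale of real drydown data (RMSE ≈ 0.27 MPa) the
phase-I/II boundary is intrinsically uncertain: an exhaustive
grid-search oracle achieves a median |Θ̂₁ − Θ₁| of ≈ 0.25 MPa on
60-point designs, and the fitter tracks that oracle; noiseless data are
recovered to better than 1e−3 MPa.

## Vulnerability curves

Fitting is on relative conductivity K/K_max (each stem normalized by
its own flushed maximum before pooling), not on PLC, keeping the error
structure simple. Initial values come from the log–log linearization
ln(−ln K/K_max) = c·ln P − c·ln b plus a deterministic multistart
(c ∈ {1, 2, 4, 8} × two scale heuristics); `scipy.optimize.least_squares`
with positivity bounds does the refinement. Curves whose observed PLC
never reaches 50% yield an extrapolated, flagged P50. The bootstrap is
case resampling of pooled (pressure, relative conductivity)
observations with percentile 95% intervals, warm-started from the point
estimate, deterministic given the seed; more than 20% replicate
failures flags the interval unstable.

## Pressure–volume analysis

The osmotic model assumes zero apoplastic water (exposed as an optional
parameter): Ψ_π = −π_o·100/RWC, so past turgor loss 1/Ψ is linear in
(100 − RWC) with π_o = −1/intercept at full saturation. TLP detection
proceeds in two stages working driest-first on (u, z) = (100 − RWC, 1/Ψ):

1. candidate tails grow from the driest 3 points; the longest tail with
   linear R² ≥ 0.99 sets the search region (no tail with R² ≥ 0.99 is a
   no-TLP error);
2. the wet boundary is then refined against the line fitted to the
   *driest half* of that tail (which stays clean even when the global
   R² criterion admits shoulder points): candidate points are accepted
   while their one-sided residual — still-turgid points always fall
   below the osmotic line in 1/Ψ — stays above −3·RMSE_core, with the
   core RMSE inflated towards the wet end by the local (Ψ_core/Ψ)²
   ratio because 1/Ψ noise scales as σ_Ψ/Ψ².

Readings wetter than −0.01 MPa are excluded from the tail search (1/Ψ
is unusable there) but retained for the supra-TLP regressions. ε is the
least-squares slope of turgor pressure Ψ_p = Ψ − Ψ_π against RWC/100
from full turgor to the TLP; C_FT is the supra-TLP slope of RWC/100 vs
Ψ times (sat − dry)/(18.015 g mol⁻¹ × leaf area) — the normalization
constant is a documented convention, chosen to produce mol m⁻² MPa⁻¹.
On noiseless ideal curves all four traits are exact to < 0.5%; under
1%-of-MPa bench noise the TLP is unbiased with sd ≈ 0.08 MPa and ε is
recovered within ~5%.

## Stomatal response

The first-order kinetic model is the two-parameter exponential
gs = g₀·exp(kΨ) fitted by bounded nonlinear least squares with
deterministic multistart (an optional additive floor g_min gives the
three-parameter variant); Ψ_gs90 = ln(0.1)/k. A `method="log-linear"`
variant regresses ln gs on Ψ by OLS: with multiplicative conductance
noise the two coincide in expectation, but when Ψ itself carries
measurement error the linear-scale NLS concentrates on the narrow wet
end of a drydown and attenuates k (≈ 13% at 0.15 MPa Ψ noise on the
simulated protocol), whereas the log-scale rate estimate is nearly
unaffected. The pipeline's trait table therefore reports the
log-linear closure point, with the NLS and polynomial estimates
alongside.

The polynomial route fits gs vs Ψ (default degree 2) with
multiplicative-error variance weights w ∝ 1/gs, floored at 1% of the
maximum reading. This choice matters: weights proportional to gs
concentrate the fit on the wet end and bias the recovered Ψ_gs90
+0.26…+0.31 MPa wet on exponential declines even without noise, while
variance weights track the kinetic estimate to within ~0.03 MPa on
designs that span the closure point. Ψ_gs90 is the most negative root
on the polynomial's *closing branch* (derivative positive in Ψ): a
low-order polynomial fitted to a saturating decline re-rises past its
vertex, and roots on that spurious branch are ignored. gs_ref is the
fitted value at the least negative observed Ψ, robust to a single
outlying reading. The polynomial estimate degrades on designs with a
long fully-closed tail (several MPa past closure) — the kinetic
estimate is preferred there.

The extra-sums-of-squares comparison fits one pooled kinetic curve and
per-group curves and forms
F = [(RSS_pooled − RSS_full)/Δdf]/[RSS_full/df_full]; it assumes
homoskedastic errors, so strongly multiplicative noise inflates its
type-I error.

## Synthetic drydown generator

The generator is a minimal daily water balance, not mechanistic soil
physics; it exists to give every fitter inputs with the right
qualitative structure and known truth. Per day and plant under the
desiccation treatment: Ψ_pd follows a two-constant substrate retention
curve −a·(100/GWC − 1)^n; Ψ_min solves the supply balance
Ψ_min = Ψ_pd − E/(K_plant·(1 − PLC(Ψ_min)/100)) by damped fixed-point
iteration (E tracks gs = gs_max·e^{kΨ_min}, PLC follows the preset's
Weibull curve); the transpired mass is withdrawn from the substrate, so
cumulative transpiration equals the water deficit exactly. Observations
are recorded on the nine measurement occasions of the emulated
protocol (days 1, 9, 15, 20, 23, 27, 35, 44, 50), with Gaussian noise
per channel drawn from independent substreams of one seed so silencing
one channel never shifts another. Channel noise defaults: 0.08 MPa
(Ψ_pd), 0.15 MPa (Ψ_min), 8% relative (gs, E, A_N), 1 GWC point, 5%
relative (conductance), 0.01 MPa (PV bench Ψ). Plants differ by a 6%
lognormal factor on gs_max.

The three shipped presets are *patterned on* published almond cultivar
traits: gs_max, E/gs and A_max from maximum gas exchange; k from the
published Ψ_gs90 (k = ln 10/|Ψ_gs90|); Weibull b from the published P50
at shape c = 3; π_o back-computed from the published Ψ_TLP and ε so the
zero-apoplast PV model lands on the target TLP. Plant conductance and
the per-pot drying rate were set so the drydown reaches realistic end
states (GWC ≈ 25–30%, Ψ_pd ≈ −3 to −5 MPa) and so the emergent
hydroscape-area ordering reproduces the qualitative published ranking
isabelona-like < avijor-like < soleta-like, which is the generator's
design target. Absolute hydroscape areas are *not* reproduced: the
generator's Ψ_pd–Ψ_min relation is curved (a saturating-exponential
offset), so the OLS line through it has a smaller intercept and area
(≈ 1.4–3.8 MPa²) than the published 8–9 MPa² values; passing tests
therefore demonstrate ordering recovery and per-module parameter
recovery, not reproduction of the field study's absolute metrics. Real
data also contain features the generator omits: leaf shedding, vapour-
pressure-deficit variation, blocking/position effects, open-vessel
artifacts and rehydration plateaus in PV curves.

## Pipeline

`run_all` is a pure function of (inputs, config, seeds): stages run
measurements → hydroscape → water-potential curve → vulnerability →
pressure–volume → stomatal response, every fit is appended to a
JSON-lines ledger with its diagnostics and seed, and reruns are
byte-identical. A stage whose input file is missing is skipped with a
warning; schema errors halt the run naming the stage. Per-cultivar
conditions a noisy drydown can legitimately produce — unidentifiable
breakpoints, no 1:1 crossing — are logged and skipped rather than
fatal. Exit codes: 0 success, 2 schema/input error, 3 fit failure.

## Problem sizes

Default study conditions: 3 presets × 2 treatments × 8 plants × 9
occasions (water potential and gas exchange), 3 stems × 11 pressure
steps (vulnerability), 4 leaves × 81 PV points. Bootstrap defaults:
1000 replicates (vulnerability and Ψ_gs90 intervals). Verification
suites use 40–100 seeded replicates for Monte-Carlo checks.
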