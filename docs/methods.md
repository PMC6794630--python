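# Methods

This note documents the models implemented in `bbbchip`, the parameters that
matter, the numerical choices, and what the synthetic-data validation does
and does not demonstrate about real assays.

## Device model

The device is represented in plan view as five parallel rectangular
microchannels tiling a rectangle, in cross-channel order: neural medium
channel (`ren_media_mc`), 3D neural culture (`ren_3d_mc`, Matrigel), collagen
bridge (`barrier_mc`, 2 mg mL⁻¹ collagen), collagen scaffold
(`collagen_scaffold_mc`), and the endothelialized luminal channel
(`bec_barrier_mc`, medium). Default widths are 1.0 / 1.0 / 0.5 / 1.0 / 1.0 mm
with 7.5 mm length and a uniform 150 µm height; the in-plane defaults are
documented conventions (the published channel dimensions appear only as
figure annotations) and every dimension is configurable, so nothing
downstream is allowed to depend on them — all validation is
geometry-parameterised. Post arrays and surface coatings are not modelled;
inter-channel interfaces are fully open except for the endothelial barrier.

The bEC monolayer lies on the scaffold|lumen shared edge. It is characterised
by a diffusion coefficient D_b = 2 × 10⁻¹⁵ m² s⁻¹ (amyloid-β) and a nominal
thickness h_b = 2 µm, and is imposed as a membrane conductance
K = D_b/h_b = 10⁻⁹ m s⁻¹ on that face (interface mode). A thin-region mode
that resolves the monolayer as a strip of `barrier` material exists for
verification; it requires dx ≤ h_b. For synthetic dextran assays the
conductance is set directly to the ground-truth permeability, K = P_true.

### Diffusion coefficients (m² s⁻¹)

| material | amyloid-β (4 kDa) | dextran 3 kDa | dextran 40 kDa |
|---|---|---|---|
| medium | 1.8e-10 | 2.0e-10 | 6.0e-11 |
| Matrigel | 1.24e-10 | 1.38e-10 | 4.1e-11 |
| collagen 2 mg/mL | 0.7e-10 | 0.78e-10 | 2.3e-11 |
| collagen scaffold | 0.62e-10 | 0.69e-10 | 2.1e-11 |

The amyloid-β column is the literature set the accumulation scenario is
defined with; the scaffold (cast at 4 mg mL⁻¹) is assigned the tabulated
5 mg mL⁻¹ collagen value as the nearest stated coefficient. Dextran
free-solution values are Stokes–Einstein estimates at 37 °C; gel values scale
the medium value by the same hindrance ratios the amyloid-β column implies
(0.689, 0.389, 0.344). All are configurable; none were adjusted after
validation.

## Transport solver

Cell-centred finite volumes on a uniform grid (default dx = 25 µm), zero-flux
outer boundaries. Interior face transfer coefficients use the harmonic mean
of adjacent cell diffusivities — the conservative discretisation for
discontinuous coefficients; the membrane face resistance is the series sum of
the two half-cell resistances and 1/K. Optional Dirichlet regions support
fixed-concentration verification problems.

Two time schemes:

* **explicit FTCS**, enforced stability bound dt ≤ dx²/(4 D_max);
* **backward Euler** (default for multi-hour runs): unconditionally stable,
  non-negativity preserving (M-matrix), one sparse LU factorisation reused
  across steps.

Both conserve mass to rounding error on sealed domains; they agree within 1%
on the assay scenarios (tested). Verification oracles: uniform-field
equilibrium; Gaussian spreading with variance σ₀² + 2Dt (matched to 0.06%);
two-material slab steady state against the series-resistance closed form
(matched to ~1e-12); the maximum principle; grid convergence (halving dx
moves the day-3 barrier-adjacent concentration by <2%).

Medium replacement is an instantaneous reset of the luminal channel to
solute-free medium (reset value 0) at every 24 h multiple; removed mass is
logged so the global balance M(t) = M₀ + ∫S dV dt − Σ removed closes (drift
~1e-12 over 7 days).

## Amyloid-β accumulation scenario

Constant distributed source S = 1.4 × 10⁻¹² mol m⁻³ s⁻¹ (equivalently
5 × 10⁻¹² M h⁻¹) in the 3D culture channel, which also starts at
1.65 × 10⁻⁷ mol m⁻³; all other channels start at zero; barrier K = 10⁻⁹ m s⁻¹;
daily luminal replacement; 7 days, backward Euler with dt = 600 s. Outputs:
daily cross-channel profiles and the barrier-adjacent gel concentration,
which rises monotonically between events while the lumen saw-tooths to zero
at each replacement. With the default geometry the 3D-culture concentration
stays ≥ ~17-fold above the luminal concentration at all times (consistent
with luminal amyloid-β being near detection limits experimentally; we assert
≥10-fold as the qualitative contrast check — with a thicker effective
monolayer the contrast grows in proportion to 1/K).

Two stated parameters deserve a caveat: the same coefficient
2 × 10⁻¹⁵ m² s⁻¹ is described both as the bEC-barrier value and as "diffusion
through cells"; we apply it to the monolayer only and leave the 3D-culture
channel at the Matrigel coefficient (configurable). The initial
1.65 × 10⁻⁷ mol m⁻³ is used verbatim.

## Synthetic influx assay and imaging model

The assay initialises the lumen at 10 µM (10⁻² mol m⁻³) tracer, zero
elsewhere, membrane K = P_true, frames every 300 s (25 frames by default,
covering the 2 h acquisition; validation uses the 3 frames that span the
0–600 s window). Rendering is linear: pixel = gain·C + background, optional
Poisson shot noise and additive Gaussian read noise, clipped to the detector
range. Defaults (gain 2 × 10⁵ per mol m⁻³ ≈ 2000 counts at the dosing
concentration, background 100, σ_read 20, 16-bit) are package choices — the
original acquisitions do not constrain them — and are always recorded with
results. No photobleaching, PSF blur, depth attenuation, or cell-scale
texture is modelled: linear intensity-in-concentration is exactly the regime
the CV equation presumes, so round-trip tests validate the estimator's
mathematics and its transport physics, not its robustness to optical
artefacts in real micrographs.

Cohorts draw per-device P_true log-normally with specified arithmetic group
mean and CV (default 0.25; permeabilities are positive and right-skewed, and
only means ± SEM are available to anchor dispersion). Group means default to
the measured 40 kDa values, 1.96 × 10⁻⁶ (control) and 6.45 × 10⁻⁶ cm s⁻¹
(disease-like), with n = 13/25. A master seed spawns per-device sub-seeds via
`numpy.random.SeedSequence`; every report is reproducible from (config,
master seed, version).

## Control-volume estimator

P = (V_g/A_v)·(1/ΔI_m)·d⟨I_g⟩/dt, with ΔI_m taken at t = 0 and V_g/A_v equal
to the CV depth perpendicular to the monolayer (the plan-view height
cancels; an explicit override exists for other CV shapes). The default CV
spans the full interface length; its depth defaults to 200 µm but pipelines
use the capture rule depth = 3·√(2 D_gel t_window) (derived a priori from the
diffusion length) so the CV holds essentially all tracer that crossed the
monolayer during the window — a shallow CV leaks tracer out of its far face
and biases P low. Saturated pixels are excluded from means and flagged above
5%. Slope modes: two-point at 0/600 s (default, the standard protocol) and
least-squares regression over a configurable window (equal to two-point for
evenly spaced frames spanning the window; provides a standard error).
Gain/offset invariance is exact by construction (gain cancels in
slope/ΔI_m; a uniform background subtracts out of ΔI_m).

### Finite-window bias of the two-point protocol

The package treats this as a first-class result. For a membrane between two
half-spaces (lumen diffusivity D_l, gel D_g), the exact solution gives the
cumulative influx M(t) = C_l P t · f(β√t) with β = P(D_l^{−1/2} + D_g^{−1/2})
and f(z) = (erfcx(z) − 1 + 2z/√π)/z². A capture-complete CV therefore
recovers the fraction f(β√t) ≤ 1 of the true permeability: ~0.99 at
P = 2 × 10⁻⁷ cm s⁻¹, but 0.89 / 0.70 (40 kDa control/disease means) and
0.79 / 0.66 (3 kDa) at the measured group values with the diffusivity table
above. The finite-volume round trip reproduces these fractions to <1%
(tested), which simultaneously verifies the solver, the renderer, and the
estimator, and demonstrates that the deficit is the protocol's back-diffusion
bias rather than an implementation artefact. Consequences: recovery-to-truth
checks at the measured operating range fail 5–10% tolerances *by physics*;
the estimator is unbiased only in the quasi-linear regime β√t ≪ 1 (small P,
fast gels, or short windows). Group *comparisons* survive — the bias is
monotone, so leakier barriers still rank leakier, and the measured cohort
separation is far larger than the bias — but absolute two-point CV
permeabilities are protocol-dependent quantities. `bbbchip.theory` exposes
the correction factor for users who wish to report debiased values; the
estimator itself reports the protocol value, by design.

## Group statistics

Student's pooled-variance two-sample t test, two-sided, no multiple-testing
correction (matching the original analysis); Welch's test behind a flag. At
the 40 kDa design (means above, CV 0.25, n = 13/25) the pooled t test on
drawn cohorts rejects at p < 10⁻⁴ in 100% of 200 draws (the separation
property is evaluated on the sampling layer; estimator noise, characterised
separately, is small compared with the 3.3× mean ratio).

## Problem sizes

The physics of every scenario here is homogeneous along the channel axis, so
simulations use a short channel section (100 µm; 1.5 mm where rendering noise
matters, giving control volumes a realistic pixel count) at dx = 25 µm —
cross-channel dynamics are identical to the full 7.5 mm device, and the grid
convergence and explicit/implicit agreement tests bound the discretisation
error. The full-size device runs in seconds with the implicit scheme if
needed.

## Known limitations

* No advection, aggregation/deposition kinetics, or receptor-mediated
  transport; amyloid-β vascular deposition is outside scope.
* The imaging model omits optics (PSF, vignetting) and photobleaching;
  estimator robustness to those is untested by construction.
* Channel in-plane dimensions and the CV geometry of the original assays are
  not published in machine-readable form; defaults are documented
  conventions.
* The two-point protocol's absolute values carry the finite-window bias
  quantified above; cross-study comparisons should match windows and gel
  diffusivities or use the theory-based correction.
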