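# bbbchip

Transport simulation and fluorescence-based permeability estimation for a
five-channel blood–brain-barrier (BBB) on-chip model.

Microfluidic BBB models probe how a brain endothelial cell (bEC) monolayer
controls solute exchange between a "blood" channel and neural tissue. The
device modelled here has five parallel microchannels in a plan view: a neural
medium channel, a 3D neural culture in Matrigel (which, in the Alzheimer's
disease variant, continually secretes amyloid-β), a collagen bridge, a
collagen scaffold, and an endothelialized luminal channel. The bEC monolayer
forms on the scaffold sidewall; its solute permeability `P` (cm s⁻¹) is the
central readout of barrier health, measured by dosing the lumen with
fluorescent dextran (3 or 40 kDa, 10 µM) and imaging tracer influx into the
gel.

`bbbchip` provides, for people building or analysing such assays:

* a **finite-volume solver** for Fick's second law, ∂C/∂t = ∇·(D∇C) + S, on
  the heterogeneous device (per-material diffusivities, an endothelial
  membrane of conductance K = D_b/h_b on the scaffold|lumen interface,
  distributed secretion, daily medium-replacement events);
* a **synthetic time-lapse generator** that simulates the dextran influx
  assay with a *known* true permeability and renders fluorescence frames with
  a configurable camera/noise model (ground truth for estimator validation);
* the **control-volume (CV) permeability estimator**

  P = (V_g / A_v) · (1/ΔI_m) · d⟨I_g⟩/dt,

  where ⟨I_g⟩(t) is the mean gel intensity in a CV against the monolayer,
  ΔI_m = I_lumen(0) − I_gel(0), and V_g/A_v reduces to the CV depth in a
  plan-view geometry — with the standard two-point 0–600 s protocol and a
  regression alternative, exposed statsmodels-style
  (`PermeabilityAssayModel.fit() → PermeabilityResult`);
* **end-to-end experiments**: the 7-day amyloid-β accumulation scenario,
  cohort round-trip recovery studies, and the pooled two-sample t test for
  group comparison;
* closed-form **transport theory** (`bbbchip.theory`) quantifying when the
  two-point protocol is unbiased and by how much back-diffusion degrades it.

## Worked example

Simulate a 40 kDa dextran assay on a 1.5 mm channel section at a true
permeability of 1.96 × 10⁻⁶ cm s⁻¹ (the healthy-control group mean), render
it with shot and read noise, and estimate `P` back:

```python
from bbbchip import build_default_layout, ImagingModel
from bbbchip.imaging import AssayGroundTruth, simulate_dextran_assay, render_timelapse
from bbbchip.permeability import (
    PermeabilityAssayModel, default_control_volume, recommended_cv_depth_um,
)

layout = build_default_layout(length_um=1500.0)
truth = AssayGroundTruth(p_true_cm_s=1.96e-6, solute="dextran_40kda",
                         layout=layout, n_frames=3)
history = simulate_dextran_assay(truth, dx_um=25.0)
stack = render_timelapse(history, ImagingModel(), seed=1)

d_gel = layout.materials["collagen_scaffold"].diffusivity["dextran_40kda"]
cv = default_control_volume(layout, stack.pixel_size_um,
                            depth_um=recommended_cv_depth_um(d_gel, 600.0))
print(PermeabilityAssayModel.from_timelapse(stack, cv).fit().summary())
```

```
Control-volume permeability estimate
============================================
P (cm/s)                     1.7654e-06
slope dIg/dt (int/s)         7.4311e-02
slope std err                nan
delta_Im (intensity)         1.9995e+03
Vg/Av (um)                   475.0
fit mode                    two_point
window (s)                  600
frames used                 2
flags                       none
============================================
```

The estimate (1.77 × 10⁻⁶ cm s⁻¹) sits at 90% of the true value. That is not
noise: the exact two-half-space membrane solution
(`bbbchip.theory.two_point_recovery_fraction`) predicts the 0–600 s two-point
protocol recovers the fraction f(β√t) = 0.887 of the true permeability at
these conditions, because tracer accumulating against the gel side of the
monolayer reduces the net influx over the fit window. The deficit grows with
`P` — about 30% at the leakiest conditions in the measured range — which is
worth keeping in mind whenever two-point CV permeabilities are compared
across very different barrier states.

A command-line interface mirrors the library
(`bbbchip simulate-abeta | simulate-assay | render | estimate | recover |
compare`), e.g.:

```bash
bbbchip recover --seed 1 --out out/ --set cohort.n_wt=13 --set cohort.n_ad=25
```

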