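# vortexflow

Quantitative two- and three-dimensional vortex-flow metrics for
time-resolved three-component velocity fields, such as those measured with
4D phase-contrast MRI of the thoracic aorta.

Complex secondary flow — the physiological right-handed systolic helix in
the aortic arch, or the pathologically altered swirl seen with dilated
aortas and aneurysms — is usually described visually from stream- and
pathline renderings. `vortexflow` instead computes objective numbers from
the velocity field `v = (vx, vy, vz)`:

* **Vorticity fields** `ω = ∇ × v` (s⁻¹) by three discretisations extended
  to 3D and anisotropic voxels: two-point central differences, the
  smoothing 8-point circulation method (recommended for noisy in-vivo
  data), and the five-point higher-order stencil.
* **λ₂ vortex criterion**: with the velocity Jacobian `J` split into the
  strain-rate tensor `S = (J + Jᵀ)/2` and the rotation tensor
  `Ω = (J − Jᵀ)/2`, a point is inside a vortex when the middle eigenvalue
  λ₂ of the symmetric matrix `S² + Ω²` is negative.
* **2D ROI quantification**: heatmaps of through-plane vorticity `ω · n̂` on
  analysis planes perpendicular to the vessel, per-phase min/max/mean
  curves, and the fractions of lumen samples rotating clockwise /
  counter-clockwise beyond a ±10 s⁻¹ noise threshold.
* **3D vortex-core extraction**: a predictor-corrector march — RK4
  prediction along the vorticity vector, derivative-free pattern-search
  correction onto the in-plane λ₂ minimum — yielding per-phase core length,
  min/max/mean vorticity along the core, and the maximal cross-section
  area π r² from 8-ray radial sampling at a 150 s⁻¹ threshold.
* **Analytic phantom**: a Poiseuille tube carrying an axially tapered
  Lamb-Oseen vortex, with closed-form oracles for every quantity above, so
  the whole pipeline can be validated against exact values at any
  resolution.

Velocity data travel as one 4D NIfTI per component plus a small JSON
sidecar (`spacing_mm`, `phase_times`, `velocity_unit`); ROI geometry comes
from a YAML/JSON config. All lengths are mm and velocities mm/s, so
vorticity is s⁻¹ and λ₂ is s⁻² with no hidden unit factors.

## Worked example

Generate the canonical phantom at 1 mm, then validate the whole pipeline
against the closed forms:

```sh
vortexflow phantom-generate --spacing 1.0 --out-dir phantom/
vortexflow validate --resolutions 1.0
```

which prints

```
           quantity unit      exact       1 mm     1 mm %
  roi_max_vorticity  1/s      397.9      330.0       17.1
 core_max_vorticity  1/s      397.9      372.5        6.4
 core_min_vorticity  1/s       50.0       50.5        1.0
core_mean_vorticity  1/s      253.5      238.4        6.0
        core_length   mm       76.9       76.0        1.2
```

Reading the table: the analytic peak vorticity of the canonical vortex is
`ω₀ = Γ/(π rc²) = 397.9 s⁻¹`, but a 1 mm central-difference lattice can only
see `ω₀ (rc²/h²)(1 − e^(−h²/rc²)) = 330.0 s⁻¹` — a 17% discretisation loss
that shrinks to ~1% at 0.1 mm. The tracked core stops where the tapered
axis vorticity falls below the 50 s⁻¹ threshold, giving a length within
1–2% of the closed form `2 (l/π) arccos(2 ω_stop/ω₀ − 1) = 76.9 mm`; the
along-core minimum sits at the stop threshold by construction.

The same computations are available as a library:

```python
import vortexflow as vf
from vortexflow.phantom import canonical_spec, build_phantom_field

field = build_phantom_field(canonical_spec(spacing=1.0))
vort  = vf.vorticity_field(field, t=0, scheme="central2")
l2    = vf.lambda2_field(field, t=0)
seeds = vf.find_seed_points(l2)
core  = vf.track_core(field, 0, seeds[0])
print(core.length(), core.omega_mag.mean())   # 76.0 mm, ~238 1/s at 1 mm
```

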