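# Methods

## Model overview and assumptions

The package propagates a single physiological mechanism to an imaging
observable. During conduction, sodium influx through open channels drags
water into the axon; potassium efflux (with its own water) restores charge,
and mass balance forces the outward water flow to equal the inward one.
The water exchange is perpendicular to the fiber axis, so in tensor terms
it perturbs only `λ₂ = λ₃ ≡ D_⊥`, leaving `λ₁ ≡ D_∥` fixed to first
approximation. Glial buffering is treated as isotropic and therefore
invisible to the anisotropy change. Transmembrane equilibration is assumed
fast relative to the diffusion time, so the exchanged water behaves as a
distinct fast pool for exactly one diffusion time per acquisition.

Key simplifications, deliberately retained: no electro-diffusion or channel
gating kinetics, no osmotic swelling dynamics, no time-dependent diffusion
equations, no BOLD or vascular contribution, and a two-compartment
slow-exchange picture of resting white matter.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `rho_node` | 10 000 | channels μm⁻² | Na⁺ channel density at nodes of Ranvier |
| `rho_unmyelinated` | 200 | channels μm⁻² | density over unmyelinated membrane |
| `ion_flux_per_channel` | 8.8 × 10³ | ions ms⁻¹ | open-channel Na⁺ flux |
| `waters_per_na` | 2.5 | — | water molecules co-transported per Na⁺ |
| `node_length_um` | 2 | μm | node of Ranvier length |
| `internodal_ratio` | 100 | — | internodal distance / axon diameter |
| `interaxonal_space_fraction` | 0.17 | — | void fraction of square-lattice packing |
| `sample_length_mm` | 3.5 | mm | cube edge of the sample volume |
| `diffusion_time_ms` | 35 | ms | Δ, fast-water accumulation window |
| `d_parallel` | 1 × 10⁻⁹ | m² s⁻¹ | λ₁ at rest |
| `anisotropy_ratio` | 5 | — | D_∥ / D_⊥ at rest |
| `d_free` | 3 × 10⁻⁹ | m² s⁻¹ | free-water diffusivity at 37 °C |
| `water_fraction` | 0.9 | — | white-matter water content |
| `firing_rate_hz`, `repetition_time_s` | 15, 2.5 | Hz, s | stimulation context (see duty cycle) |
| `duty_cycle` | 1 | — | fraction of Δ the tract is treated as conducting |

The default bundle is a corticospinal-tract composition: four myelinated
diameter classes (2/5/8/11 μm; 567k/105k/28k/30k axons) plus 300k
unmyelinated axons at 3 μm. `waters_per_k` (≈0.9–1.4) is stored for
reference but never enters the arithmetic: mass balance fixes the outward
water flow regardless of its carrier, hence the flat factor 2.

## Numerical and design choices

- **Class fractions.** The optional per-class fractions are informational;
  their sum is validated against 1 with slack of 5 × 10⁻⁴ per class, since
  published composition tables round each fraction to three decimals.
- **Fractional node counts.** `nodes_per_axon` is a population average and
  is not rounded; rounding would break the per-class channel totals the
  composition is calibrated against.
- **Node membrane as open cylinder.** `π·d·l`, no end caps — the geometry
  consistent with the published per-class areas.
- **Dilute-fraction default.** `d_perp_active(mode="paper")` uses
  `f·D_free + D_⊥`. The exact mixture `f·D_free + (1−f)·D_⊥` is available
  as `mode="exact"`; the two differ by exactly `f·D_⊥` (property-tested).
  The dilute form is the default because it is the form the published
  worked example evaluates; at `f ≈ 4.3 × 10⁻³` the difference is ~0.9 μm²/s
  in `D_⊥*` (6.4% vs 6.0% relative change).
- **Duty cycle.** The default applies the flux for the full diffusion time
  (duty_cycle = 1), matching the worked example's `35 ms × F_w`
  accumulation. A 15 Hz firing rate could motivate a smaller duty cycle;
  this is exposed as an explicit parameter rather than silently applied,
  because the intended treatment is ambiguous (67 ms is an inter-spike
  interval, not an action-potential duration).
- **Resident water mass.** `f_w*` divides by the unrounded water mass of
  the 3.5 mm cube (0.038 59 g, not the rounded 0.039 g); the unrounded value
  is what reproduces `f_w* = 4.28 × 10⁻³`.
- **Known bookkeeping inconsistencies in the reference chain.** The
  published in-text node total (1.28 × 10⁷) is not consistent with the
  per-class channel table under the stated internodal rule (which implies
  ≈1.09 × 10⁷); the table-consistent arithmetic is used, and the channel
  totals — which are internally consistent — are the tested quantities.
  Similarly the printed bidirectional mass rate (4.71 × 10⁻⁶ g ms⁻¹)
  reflects intermediate rounding; the comparison tolerance in
  `idti.reference` is therefore one unit in the last printed digit.
- **Detection rule.** A fractional signal drop is called detectable when it
  exceeds `z/SNR` with `z = 3` by default. This is an interpretation of
  "just above the detection limit at SNR 400": the predicted 0.77% drop vs
  the 0.75% threshold. `z` is configurable.
- **Tensor fit.** Ordinary (unweighted) least squares on log-signals, no
  positivity constraint; eigenvalues floored at 10⁻¹⁶ m² s⁻¹ and ordered.
  Adequate at the SNRs simulated here (≥50); at very low SNR a weighted or
  constrained fit would be preferable. The grid-scale fitter clips
  non-positive signals to 10⁻¹² before the log instead of masking per
  voxel; at SNR ≥ 50 with A₀ = 1 such signals essentially never occur.
- **Gradient scheme.** 30 golden-ratio hemisphere directions + 1 b=0 at
  b = 600 s mm⁻², the b-value of the detectability argument. Directions are
  deterministic; schemes round-trip through bval/bvec and four-column text
  files.
- **Phantom.** Fiber axis along z, cylindrical tract mask (radius 3 voxels
  in a 16³ grid → 512 tract voxels), isotropic background at the tract's
  resting mean diffusivity (a free choice; background voxels never enter
  tract statistics). Rician noise is the default, as appropriate for
  magnitude MRI; per-repetition seeds derive deterministically from the
  master seed (`seed + rep`, active state offset by a large constant so the
  paired acquisitions carry independent noise).

## What the synthetic phantom does and does not show

The phantom emulates thermal (Rician) noise on an otherwise ideal
acquisition of a perfectly straight, uniformly activated tract. It shows
that at SNR 400 the predicted −2.1% tract-mean FA change is recovered
essentially always over 512 tract voxels (null detection rate ≈ 0.5, as it
must be by symmetry), and that tract-mean dispersion scales ~1/√(voxels).
It does **not** model partial volume, crossing fibers, physiological noise,
BOLD contamination, motion, eddy currents, or heterogeneous activation —
so a pass here bounds detectability from above; real data are strictly
harder.

## Problem sizes

Default simulations are sized to run interactively: 16³ voxels × 31 volumes
per state, 25–50 Monte-Carlo repetitions (a full 50-repetition paired
experiment runs in about a second). The forward chain itself is
closed-form and instantaneous.

## Limitations

The model is a first-order plausibility calculation: every flux parameter
is a literature point estimate with substantial uncertainty, the fast-pool
treatment ignores exchange during the encoding itself, and the predicted
effect (≈2% FA, ≈0.8% signal) sits at the edge of achievable SNR. The
package's purpose is to make those numbers — and their sensitivity to each
assumption — explicit and reproducible, not to claim the effect has been
measured.
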