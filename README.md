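# idti — activity-dependent water flux and its diffusion-MRI signature

`idti` implements a biophysical forward model of *dynamic* diffusion tensor
imaging: the hypothesis that action-potential conduction in a white-matter
tract transiently increases water exchange across axonal membranes —
through sodium channels at nodes of Ranvier (myelinated axons) and over the
whole membrane (unmyelinated axons) — and that this exchange, being
perpendicular to the fiber axis, measurably lowers the tract's fractional
anisotropy (FA). The package is aimed at diffusion-MRI methodologists who
want to reason quantitatively about whether such an effect is detectable,
and under what acquisition conditions.

## The model

For a cubic sample volume containing the tract, the bidirectional molecular
water flow during conduction is

```
F_w = 2 (N_MA · N_NR · S_NR · ρ_NR + N_nMA · S_nMA · ρ_nMA) · N_w · J / t
```

where `N_MA`, `N_nMA` are myelinated/unmyelinated axon counts, `N_NR` the
nodes of Ranvier per axon (sample length over 100× the diameter), `S` the
membrane areas, `ρ` the sodium-channel densities (10⁴ μm⁻² at nodes,
200 μm⁻² unmyelinated), `J = 8.8 × 10³` ions ms⁻¹ per channel and
`N_w = 2.5` water molecules per sodium ion; the factor 2 is the
mass-balancing outward flow. Accumulated over the diffusion time Δ and
divided by the resident water mass this gives the fast-water fraction
`f_w*`, which perturbs the perpendicular diffusivity,

```
D_⊥* = f_w* D_free + D_⊥          (dilute-fraction form, default)
D_⊥* = f_w* D_free + (1 − f_w*) D_⊥   (exact two-pool mixture)
```

with `λ₁ ≡ D_∥` held fixed. Mean diffusivity `D_app = (λ₁+λ₂+λ₃)/3` and

```
FA = √(3/2) · √( Σᵢ(λᵢ − D_app)² / Σᵢλᵢ² )
```

follow for the inactive and active states. The measurement side is the
Stejskal–Tanner attenuation `A = A₀ exp(−b ĝᵀD ĝ)` with
`b = (γgδ)²(Δ − δ/3)`, a z/SNR detection rule, and a voxel-grid phantom
with Rician noise and log-linear tensor refitting.

## Worked example

```
python examples/worked_example.py
```

builds the default corticospinal-tract bundle (~10⁶ axons, 70% myelinated
across four diameter classes) and prints, among others:

```
Fast-water fraction f_w* = 4.276e-03
FA (inactive) = 0.770, FA* (active) = 0.754
Relative FA change = -2.08%  (negative: conduction lowers anisotropy)
```

i.e. roughly 0.4% of the voxel's water is rendered fast-moving per 35 ms
diffusion time, which raises the perpendicular diffusivity by ~6.4%, the
mean diffusivity by ~1.8%, and lowers FA by ~2.1%. The corresponding echo
drop at b = 600 s mm⁻² is ~0.77% — just above the 3/SNR noise floor at
SNR 400. The other examples sweep acquisition parameters
(`examples/detectability_sweep.py`) and run the noisy phantom
(`examples/phantom_experiment.py`).

The same computations are available from a shell:

```
idti reproduce                    # full chain vs reference values
idti sweep --param diffusion_time_ms --values 20,35,70
idti phantom --out out/ --snr 400 --repetitions 50 --seed 1
```

`idti reproduce` exits non-zero if any computed quantity deviates from its
published reference value beyond printed precision.

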