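"""Synthetic DWI phantom: recovering the FA decrease from noisy images.

Embeds an active tract (tensors from the forward model) in a 16^3 voxel
grid, synthesizes 31 diffusion-weighted volumes, adds Rician noise at
SNR 400, refits tensors voxelwise, and reports how often the tract-mean FA
decrease is recovered — alongside a null experiment (no activation) as the
false-positive control.
"""

from idti import PhantomConfig, run_experiment
from idti.phantom import default_states

inactive, active = default_states()
REPS, SNR, SEED = 25, 400.0, 42

effect = run_experiment(
    PhantomConfig(inactive=inactive, active=active, snr=SNR,
                  repetitions=REPS, seed=SEED)
)
null = run_experiment(
    PhantomConfig(inactive=inactive, active=inactive, snr=SNR,
                  repetitions=REPS, seed=SEED)
)

print(f"{REPS} repetitions at SNR {SNR:.0f}, "
      f"{int(effect.config.tract_mask.sum())} tract voxels\n")
for name, res in (("activation", effect), ("null", null)):
    s = res.summary()
    print(f"{name:>10}: tract-mean dFA/FA = {s['mean_tract_rel_delta_fa']:+.4f}"
          f" +/- {s['std_tract_rel_delta_fa']:.4f},"
          f" detection rate = {s['detection_rate']:.2f}")

print("\nThe activation run should sit near the forward-model prediction of"
      "\n-2.1% with a detection rate near 1; the null run should hover near"
      "\nzero with a detection rate near 0.5 (a coin flip).")
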