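"""How experiment settings move the predicted signal change across the
noise floor.

Sweeps the diffusion time (longer accumulation -> larger fast-water
fraction -> larger FA drop) and the SNR (the z/SNR detection threshold) at
the default b = 600 s/mm^2.
"""

from idti import (
    ActivationParams,
    ChannelBiophysics,
    activation_summary,
    corticospinal_bundle,
    detectable,
    relative_signal_drop,
)

bundle = corticospinal_bundle()
chans = ChannelBiophysics()
b = 600.0  # s/mm^2

print("diffusion time sweep:")
print(f"{'Delta_ms':>9} {'f_w*':>10} {'dFA %':>8} {'echo drop %':>12}")
for dt in (20.0, 35.0, 50.0, 70.0):
    res = activation_summary(bundle, chans, ActivationParams(diffusion_time_ms=dt))
    drop = relative_signal_drop(b, res.inactive.lambda2, res.active.lambda2)
    print(f"{dt:9.0f} {res.f_w_star:10.2e} {100 * res.rel_change_fa:8.2f} "
          f"{100 * drop:12.3f}")

res = activation_summary(bundle, chans, ActivationParams())
drop = relative_signal_drop(b, res.inactive.lambda2, res.active.lambda2)
print(f"\ndefault-condition echo drop: {100 * drop:.2f}%")
print("SNR sweep (z = 3 detection rule):")
for snr in (100.0, 400.0, 1000.0):
    ok, margin = detectable(drop, snr)
    print(f"  SNR {snr:6.0f}: detectable={ok}  margin={margin:+.4f}")
print("The ~0.77% drop clears the threshold only around SNR 400 and above —"
      "\nthe effect sits just at the edge of what a careful acquisition sees.")
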