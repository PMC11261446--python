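"""Stabilize and segment a shaky synthetic video, then check the truth.

Runs the full imaging chain — cross-correlation stabilization, the
Phansalkar local threshold with the close/dilate/blur refine steps —
on a rendered dropwise scene and reports how well the wet-area series
and the injected camera shake are recovered.
"""

from perspire.experiments import dropwise_recovery_experiment

result = dropwise_recovery_experiment(
    seed=3, width_px=160, height_px=160, duration_s=30.0
)
print(f"stabilization RMS error: {result['stabilization_rms_px']:.2f} px "
      "(injected ±3 px sinusoidal shake)")
print(f"wet-area recovery error: {100 * result['omega_mae_rel']:.1f}% "
      "(mean |ω_est − ω_true| relative to mean ω_true)")
series = result["wet_series"]
truth = result["truth"]
print(f"final wet fraction: estimated {series.omega[-1]:.4f}, "
      f"truth {truth.omega[-1]:.4f}")
# Sub-half-pixel registration and a few-percent wet-area error are what
# the quantitative mass-transfer analysis downstream relies on.
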