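"""Exposure indices for a stimulation pulse and the threshold-vs-frequency fit.

Computes MI, I_SPPA, I_SPTA and TI for a typical retinal stimulus (2.83 MPa,
4.5 MHz, 10 ms pulse every 6 s), the radiation body force it exerts, and
fits a power law to synthetic activation-threshold data.
"""

import numpy as np

from sonoretina import (
    PulseParams, arf_force, db_cm_to_np_m, exposure_metrics, fit_threshold_curve,
)

pulse = PulseParams(npp=2.83, f=4.5, duration_ms=10.0, period_s=6.0)
m = exposure_metrics(pulse, power_mw=10.0)
for k, v in m.as_dict().items():
    print(f"{k:>22s}: {v:.4g}")
print("MI < 1.9 and TI < 1 place this pulse inside diagnostic-range limits;")
print("the low I_SPTA reflects the 1/600 duty cycle.")

alpha = db_cm_to_np_m(0.5)  # retinal-tissue attenuation, 0.5 dB/cm/MHz
force = arf_force(p_pa=2.83e6, alpha_np_m=alpha, f=4.5)
print(f"\nradiation body force at the focus: {force / 1000:.1f} kN/m³")

rng = np.random.default_rng(0)
f = np.array([1.0, 2.0, 3.0, 4.5, 6.0, 9.0, 12.0, 20.0])
thresholds = 6.0 / f + rng.normal(0, 0.05, f.size)
fit = fit_threshold_curve(f, np.abs(thresholds), model="free")
print(f"threshold fit: p = {fit.a:.2f}·f^{fit.b:.2f}  (RMSE {fit.rmse:.3f} MPa)")
print("An exponent near -1 (inverse proportionality) argues against cavitation,")
print("whose efficiency would fall with frequency; constant radiation force")
print("would predict an exponent of -1/2 instead.")
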