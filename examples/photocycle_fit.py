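"""Photocycle simulation and global lifetime fitting.

Simulates flash-photolysis transient absorption for a KR2-like sequential
K -> K/L -> L/M -> O photocycle at realistic noise, denoises by SVD, and
recovers the four lifetimes by a variable-projection global fit. The slowest
lifetime is the turnover time; the wild-type/double-mutant ratio shows the
red-shifted pump cycles less than a factor of two slower.
"""

import numpy as np

import rhodotune as rt

data = rt.make_ta(turnover_s=4.8e-3, seed=1)
denoised, singular_values = rt.svd_denoise(data, 4)
print("leading singular values:", np.round(singular_values[:6], 4))
# four values stand clearly above the noise floor: four kinetic components

fit = rt.global_fit(denoised, 4)
for tau, se in zip(fit.lifetimes, fit.stderr):
    print(f"  tau = {tau * 1e3:8.4f} ms +- {se * 1e3:.4f} ms")
print(f"turnover time: {fit.turnover_time * 1e3:.2f} ms "
      f"(generated with 4.8 ms ground-state recovery)")

# compare wild-type-like and slower double-mutant-like cycles
w = np.linspace(420, 680, 25)
t = np.geomspace(1e-6, 0.3, 120)
wt = rt.global_fit(rt.simulate_ta(rt.PhotocycleScheme.kr2_like(4.8e-3), w, t, 0.0), 4)
mut = rt.global_fit(rt.simulate_ta(rt.PhotocycleScheme.kr2_like(8.2e-3), w, t, 0.0), 4)
ratio = rt.turnover_ratio(wt, mut)
print(f"turnover ratio mutant/WT: {ratio:.2f} (< 2: transport-compatible slowdown)")
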