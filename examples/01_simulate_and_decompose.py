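"""Simulate the canonical bleach stack and decompose it with DMD.

Three regions share the same initial intensity (mean 190 over a mean-10
background) but bleach at 0.01, 0.05 and 0.15 per second, so only the
kinetics can tell them apart.  DMD recovers one spatial mode per
kinetic component; the real part of each continuous eigenvalue is that
component's bleach rate.
"""

import numpy as np

from bleachdmd import SimConfig, fit_dmd, reconstruct, simulate_stack

config = SimConfig(seed=0)
stack, truth = simulate_stack(config)
print(f"stack: {stack.n_frames} frames of {stack.frame_shape}, dt = {stack.dt} s")

model = fit_dmd(stack)  # rank chosen by the optimal hard threshold
print(f"automatically selected rank: {model.rank}")
print("continuous eigenvalues (1/s), slowest decay first:")
for j, om in enumerate(model.omegas):
    print(f"  mode {j}: omega = {om.real:+.4f} {om.imag:+.4f}i")

rec = reconstruct(model)
err = np.linalg.norm(rec.frames - stack.frames) / np.linalg.norm(stack.frames)
print(f"relative reconstruction error: {err:.3f}")
print(
    "The three rates should sit near -0.01, -0.05 and -0.15 /s (the"
    " simulated bleach rates); the residual is dominated by shot noise,"
    " which the rank truncation removes."
)
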