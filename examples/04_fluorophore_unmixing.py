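"""Separate two spectrally identical fluorophores by bleaching kinetics.

Two regions emit at the same wavelength and intensity but bleach at
0.01 /s ("autofluorescence") and 0.2 /s ("probe").  Grouping DMD modes
and reconstructing each group unmixes the two species; a red/green
overlay shows the fast species fading while the slow one persists.
"""

import numpy as np

from bleachdmd import (
    RegionSpec,
    SimConfig,
    default_mode_groups,
    fit_dmd,
    group_reconstruct,
    render_overlay,
    simulate_stack,
)

config = SimConfig(
    width=96,
    height=64,
    n_frames=80,
    regions=[
        RegionSpec("circle", (32, 24, 14), 180.0, 0.01, label="autofluorescence"),
        RegionSpec("circle", (32, 68, 14), 180.0, 0.20, label="probe"),
    ],
    seed=1,
)
stack, truth = simulate_stack(config)
model = fit_dmd(stack, rank=2)

groups = default_mode_groups(model)
print("mode groups:", {g.label: g.mode_indices for g in groups})
stacks = group_reconstruct(model, groups, n_frames=stack.n_frames)

# the "background" group is the slow species (the autofluorescence here)
region_for_group = {"background": "autofluorescence", "probe": "probe"}
for label, gstack in stacks.items():
    mask = truth.masks[region_for_group[label]]
    first = gstack.frames[0][mask].mean()
    last = gstack.frames[-1][mask].mean()
    print(f"  {label:12s} mean intensity in its region {first:6.1f} -> {last:6.1f}")

overlay_first = render_overlay(stacks["background"], stacks["probe"], 0)
overlay_last = render_overlay(stacks["background"], stacks["probe"], stack.n_frames - 1)
probe_px = truth.masks["probe"]
slow_px = truth.masks["autofluorescence"]
print(f"probe channel over its region: {overlay_first[..., 1][probe_px].mean():.3f}"
      f" (first frame) -> {overlay_last[..., 1][probe_px].mean():.3f} (last frame)")
print(f"slow channel over its region:  {overlay_first[..., 0][slow_px].mean():.3f}"
      f" (first frame) -> {overlay_last[..., 0][slow_px].mean():.3f} (last frame)")
print(
    "The probe group bleaches away completely within the movie while"
    " the slow (autofluorescence-like) group only partially fades: the"
    " two species are unmixed without any spectral difference."
)
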