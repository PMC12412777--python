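"""Build the 90/91-channel network inputs for one synthetic patient.

The primary head sees the adaptive session (44 OAR masks + 44 distance maps
+ PTV prescription map + CT = 90 channels); the secondary head sees the
pre-treatment session plus its approved dose (91 channels).
"""

from adaptdose import PhantomConfig, assemble_channels, generate_plan_pair
import numpy as np

pair = generate_plan_pair(PhantomConfig(grid_shape=(48, 48, 32)),
                          np.random.default_rng(3), "P000")

primary = assemble_channels(pair.adaptive, "primary")
secondary = assemble_channels(pair.pre, "secondary")

print(f"primary assembly:   {primary.tensor.shape}  ({len(primary.manifest)} channels)")
print(f"secondary assembly: {secondary.tensor.shape}  ({len(secondary.manifest)} channels)")
print("first channels: ", primary.manifest[:3], "...")
print("last channels:  ", primary.manifest[-2:], "| secondary adds:", secondary.manifest[-1])

nonzero = [m for m, ch in zip(primary.manifest, primary.tensor) if ch.any()]
print(f"{len(nonzero)} of 90 channels are non-zero (absent roster structures are zero-filled)")

# The channel order is fixed by the canonical 44-structure roster, so every
# patient's tensor lines up channel-for-channel regardless of which organs
# were contoured.
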