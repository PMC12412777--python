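"""Audit the dual-head network's feature-map shapes at the full configuration.

Builds the real model (base width 64, four resolution levels, dual max/avg
pooling) and walks its layer graph in shape-propagation mode for a
96 x 96 x 64 input patch.
"""

from adaptdose import NetworkConfig, build_mhunet

model = build_mhunet(NetworkConfig())
for name, shape in model.summarize((96, 96, 64)).items():
    print(f"{name:20s} {list(shape)}")

print()
print(f"trainable parameters: {model.n_parameters():,}")

# Landmarks: the first encoder block produces [1, 64, 96, 96, 64]; the dual
# max/avg pooling doubles channels to [1, 128, 48, 48, 32]; the merged
# bottleneck is [1, 512, 12, 12, 8]; the 1x1x1 head restores [1, 1, 96, 96, 64].
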