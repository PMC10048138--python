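"""Inspect the three model variants: taps, parameters, DSC cost accounting.

Builds each published variant, verifies the encoder contract (low-level
features at 1/4 resolution, high-level at 1/16) and prints the depthwise-
separable-convolution multiply count in both conventions: the two-term
printed form (kernel size folded out) and the kernel-corrected count for the
3x3 depthwise filters actually used.
"""

import numpy as np

from myinet import VARIANTS, build_variant, dsc_cost

x = np.zeros((1, 1, 256, 256))
for name in ("MI-MobileNet-AC", "MI-ResNet18-AC", "MI-ResNet50-AC"):
    model = build_variant(name, seed=0)
    model.eval()
    low, high = model.backbone(x)
    print(f"{name:<16} params={model.n_parameters():>12,}  "
          f"low tap {low.data.shape[-2]}x{low.data.shape[-1]}"
          f" ({low.data.shape[1]} ch)  high tap"
          f" {high.data.shape[-2]}x{high.data.shape[-1]}"
          f" ({high.data.shape[1]} ch)  ASPP rates {model.aspp.spec.rates}")

print("\nDSC cost for D_I=32, D_O=64 on a 16x16 map, width multiplier 1:")
print(f"  printed form (D_k=1)   : {dsc_cost(32, 64, 16, 1):>12,.0f} multiplies")
print(f"  kernel-corrected (D_k=3): {dsc_cost(32, 64, 16, 3):>12,.0f} multiplies")
print("Halving the width multiplier scales the depthwise term linearly and")
print(f"the pointwise term quadratically: {dsc_cost(32, 64, 16, 3, 0.5):>12,.0f}")
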