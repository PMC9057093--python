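"""The decomposed 4D convolution against its brute-force oracle.

The 4D layer applies one 3D convolution per temporal kernel tap and sums
over taps per output frame (l_out = floor((l - kl)/st) + 1 frames).  The
same operation recomputed with explicit loops over every output position
must agree to floating-point precision.
"""

import numpy as np

from fmriatt.conv4d import (
    Conv4DSpec,
    Kernel4D,
    conv4d_decomposed,
    conv4d_naive,
    squeeze_flatten_time,
)

rng = np.random.default_rng(0)
x = rng.normal(size=(7, 10, 10, 10, 2))          # 7 frames, 2 channels
k = Kernel4D.init(kl=3, spatial=3, c_in=2, c_out=4, rng=rng, dtype=np.float64)
spec = Conv4DSpec(st=2, spatial_stride=2)

out = conv4d_decomposed(x, k, spec)
ref = conv4d_naive(x, k, spec)
err = np.max(np.abs(out - ref)) / np.max(np.abs(ref))
print(f"input  (l,h,w,d,c) = {x.shape}")
print(f"output (l,h,w,d,c) = {out.shape}   # (7-3)//2+1 = 3 frames, grid halved")
print(f"max relative deviation from the brute-force oracle: {err:.2e}")

flat = squeeze_flatten_time(out)
print(f"after temporal squeeze-and-flatten: {flat.shape}  "
      f"# {out.shape[0]} frames x {out.shape[-1]} channels -> "
      f"{flat.shape[-1]} channels for the 3D stages")
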