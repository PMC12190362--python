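"""Register a pair with the NMI-driven affine backend.

The ONH view starts shifted 50% of the image width to the right of the
macula view; a coarse translation sweep plus Powell search then maximizes
normalized mutual information over the six affine parameters on a
three-level pyramid.
"""

import numpy as np

import fundusmosaic as fm
from fundusmosaic.affine_backend import init_shift, register_affine_nmi

pair = fm.default_pair(seed=1, transform_kind="translation", overlap_target=0.5)
init = init_shift(pair.macula_image, pair.onh_image)
tf = register_affine_nmi(pair.macula_image, pair.onh_image, init)

true_tx, true_ty = pair.true_homography[0, 2], pair.true_homography[1, 2]
print(f"init shift            : tx={init.params.tx:.0f} px")
print(f"true translation      : ({true_tx:.1f}, {true_ty:.1f}) px")
print(f"recovered translation : ({tf.params.tx:.1f}, {tf.params.ty:.1f}) px")
print(f"translation error     : {np.hypot(tf.params.tx - true_tx, tf.params.ty - true_ty):.2f} px")
print(f"rotation / skew       : {tf.params.rotation:.2f} deg / {tf.params.skew:.4f}")
print(f"NMI at optimum        : {tf.nmi:.3f}   overlap {100 * tf.overlap_pct:.1f} %")
# NMI lives in [1, 2]; ~1.15 over a half-frame overlap of vascular images
# indicates a locked-in registration, and the translation error is the
# distance to the planted ground truth.
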