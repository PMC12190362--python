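"""Generate a synthetic SLO fundus pair with known ground truth.

Builds a master retina scene (vessel tree, optic disc, macula), crops a
macula-centered and an ONH-centered 768x768 view with ~50% overlap and a
small similarity perturbation, and prints the exact homography relating
them.  The two TIFFs plus a JSON sidecar land in ./scratch_example_01/.
"""

import json
from pathlib import Path

import fundusmosaic as fm

pair = fm.default_pair(seed=1, transform_kind="similarity", overlap_target=0.5)

outdir = Path("scratch_example_01")
outdir.mkdir(exist_ok=True)
fm.write_gray_tiff(pair.macula_image, outdir / "macula.tif")
fm.write_gray_tiff(pair.onh_image, outdir / "onh.tif")
(outdir / "ground_truth.json").write_text(json.dumps({
    "true_homography": pair.true_homography.ravel().tolist(),
    "true_overlap": pair.true_overlap,
}))

print("true homography (ONH -> macula coordinates):")
print(pair.true_homography.round(4))
print(f"true overlap fraction: {pair.true_overlap:.3f}")
print(f"planted matched centerline points: {len(pair.planted_points_macula)}")
# The homography's right column is the translation between the two views in
# pixels; the overlap is the share of ONH pixels visible in the macula view.
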