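"""Generate CT-like phantom slices with lesion masks and save them as PNGs.

Each phantom is a 12-bit-range slice containing an elliptical textured
organ and one or more darker lesions; the paired binary mask marks the
lesion pixels.  Phantoms make the whole pipeline runnable without any
patient data.
"""

import json
import os

import maskgan as mg

OUT_DIR = "scratch/phantoms"
COUNT = 5
SEED = 7

spec = mg.PhantomSpec().scaled(128)
dataset = mg.generate_dataset(spec, COUNT, seed=SEED)

os.makedirs(OUT_DIR, exist_ok=True)
manifest = {"seed": SEED, "size": spec.size, "items": []}
for i, (slc, mask) in enumerate(dataset):
    img_path = os.path.join(OUT_DIR, f"phantom_{i:03d}.png")
    mask_path = os.path.join(OUT_DIR, f"phantom_{i:03d}_mask.png")
    mg.write_slice(slc, img_path)
    mg.write_slice(mg.CtSlice(mask.pixels * 4095.0), mask_path)
    manifest["items"].append({"image": img_path, "mask": mask_path,
                              "lesion_pixels": mask.count})
    print(f"{img_path}: intensities [{slc.pixels.min():.0f}, "
          f"{slc.pixels.max():.0f}], {mask.count} lesion pixels")

with open(os.path.join(OUT_DIR, "manifest.json"), "w") as fh:
    json.dump(manifest, fh, indent=2)
print(f"\nWrote {COUNT} image/mask pairs and a manifest to {OUT_DIR}/.")
print("Intensities span the 12-bit CT-like range; lesion counts vary per seed.")
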