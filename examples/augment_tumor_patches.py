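"""Harvest lesion patches, expand them by flip/rotate/scale, implant one.

This is the dataset-enlargement workflow: lesions are cut out of labeled
slices, multiplied to a target count with random symmetries, and their
masks are later stamped (whitened) onto healthy slices for the generator
to fill.
"""

import numpy as np

import maskgan as mg

spec = mg.PhantomSpec().scaled(64)
dataset = mg.generate_dataset(spec, 10, seed=21)

patches = []
for slc, mask in dataset:
    patches.extend(mg.harvest_patches(slc, mask, margin=2))
print(f"harvested {len(patches)} lesion patches from {len(dataset)} slices")

augmented, manifest = mg.augment_patches(patches, target_count=200, seed=3)
n_flips = sum(r.hflip or r.vflip for r in manifest)
print(f"augmented to {len(augmented)} patches "
      f"({n_flips} involve a flip; angles are uniform in [0, 360))")

# implant two augmented lesion masks onto a lesion-free phantom
healthy, _ = mg.generate_phantom(
    mg.PhantomSpec(size=64, lesion_count_range=(0, 0),
                   lesion_radius_range=(2.0, 4.0), texture_scale=1.0, seed=9))
stencils = [p for p in augmented if max(p.shape) < 16][:2]
am, implanted = None, None
for stencil, loc in zip(stencils, [(18, 18), (38, 34)]):
    am, implanted = mg.implant_mask(healthy, stencil.mask, loc,
                                    existing_mask=implanted)
print(f"implanted {len(stencils)} masks: {implanted.count} whitened pixels "
      f"(value {mg.WHITE_VALUE}) now mark regions for the generator to fill")
assert np.all(am.pixels[implanted.pixels == 1] == mg.WHITE_VALUE)
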