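"""Fill whitened regions of a slice with synthesized lesion texture.

Loads the checkpoint written by train_inpainting_gan.py (or trains a
quick one), whitens a lesion-shaped region on a healthy phantom and runs
the generator to inpaint it.
"""

import os

import numpy as np

import maskgan as mg

CKPT = "scratch/training_run/final.npz"

if os.path.exists(CKPT):
    gen, _ = mg.load_checkpoint(CKPT)
    print(f"loaded {CKPT}")
else:
    print("no checkpoint found; training a quick model first (~1 min)")
    spec = mg.PhantomSpec().scaled(64)
    ds = mg.generate_dataset(spec, 30, seed=5)
    gen, _, _ = mg.train(ds, mg.GeneratorConfig.toy(64),
                         mg.DiscriminatorConfig.toy(64),
                         mg.TrainingConfig(epochs=2, seed=5))

# healthy slice + a donor lesion mask from another phantom
healthy, _ = mg.generate_phantom(
    mg.PhantomSpec(size=64, lesion_count_range=(0, 0),
                   lesion_radius_range=(2.0, 4.0), texture_scale=1.0, seed=77))
donor_slice, donor_mask = mg.generate_phantom(mg.PhantomSpec().scaled(64))
(donor_patch, *_) = mg.harvest_patches(donor_slice, donor_mask, margin=1)

attention, implanted = mg.implant_mask(healthy, donor_patch.mask, (24, 24))
synth = mg.synthesize(gen, attention)

inside = implanted.pixels == 1
print(f"whitened {implanted.count} pixels at value {mg.WHITE_VALUE}")
print(f"synthesized fill: mean {synth.pixels[inside].mean():.0f}, "
      f"rest-of-slice mean {healthy.pixels[~inside].mean():.0f}")
print("a plausible fill sits well below the white value and near the organ/"
      "lesion intensity range rather than at 4096")

os.makedirs("scratch", exist_ok=True)
mg.write_slice(synth, "scratch/synthesized.png")
mg.write_slice(mg.CtSlice(np.clip(attention.pixels, 0, 4096)),
               "scratch/whitened_input.png")
print("wrote scratch/whitened_input.png and scratch/synthesized.png")
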