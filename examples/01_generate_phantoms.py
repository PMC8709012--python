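"""Generate the eight-class retinal phantom set and save it as PNGs.

Each class gets a dark circular fundus field with an optic disc and vessel
arcs, plus a class-specific structure (drusen, haze, exudates, an enlarged
disc, tortuous vessels, a crescent, a grey lesion).  The same spec + seed
always renders bit-identical pixels.
"""

import numpy as np

from fundusnet import SynthImageSpec, generate_phantom_images
from fundusnet.synthdata import save_image_set

spec = SynthImageSpec(n_per_class=5, image_size=64, seed=0)
images, labels = generate_phantom_images(spec)

names, counts = np.unique(labels, return_counts=True)
print(f"rendered {len(images)} images of shape {images.shape[1:]} in [0, 1]")
for name, count in zip(names, counts):
    print(f"  {name:<14}{count} images")

save_image_set("scratch/phantoms", images, labels)
print("saved under scratch/phantoms/<class>/<index>.png")
# The printed counts are balanced by construction: every listed class gets
# exactly n_per_class images, so a classifier trained on them sees no prior.
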