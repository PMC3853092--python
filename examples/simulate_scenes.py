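"""Render a synthetic multi-neuron scene and compare truth to extraction.

Builds one noiseless scene from explicit geometry (two somata, three
neurites, one branch), prints the spec-derived ground truth next to the
features recovered by the segmentation chain.  Counts should agree
exactly; length/area carry a small skeletonization bias.
"""

import numpy as np

from hcsneurons import NeuriteSpec, SomaSpec, extract_nfd, generate_scene

somata = [SomaSpec((128, 110), 10), SomaSpec((320, 360), 12)]
neurites = [
    NeuriteSpec(0, np.array([[128.0, 120.0], [128.0, 200.0], [160.0, 260.0]])),
    NeuriteSpec(
        0,
        np.array([[118.0, 110.0], [80.0, 110.0], [50.0, 110.0]]),
        branches=[(1, np.array([[80.0, 110.0], [55.0, 140.0]]))],
    ),
    NeuriteSpec(1, np.array([[320.0, 348.0], [320.0, 250.0]])),
]

image, truth = generate_scene(somata, neurites, shape=(512, 512), noise_sd=0.0, seed=0)
nfd = extract_nfd(image)

print("ground truth:", truth.as_dict())
print("extracted   :", {k: round(v, 1) for k, v in nfd.to_dict().items()})
print(
    "\nsoma/attachment/ending/branch counts are exact; neuriteLength is the"
    "\nskeleton pixel count, a few percent under the true arc length."
)
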