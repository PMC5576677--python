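"""Extract the 22-element feature vector from one phantom image.

The vector concatenates five echointensity features (mean/SD per tissue and
the muscle/fat mean ratio), the Nakagami shape and scale of each tissue, and
the 13 Haralick texture statistics of the muscle region's gray-level
co-occurrence matrices.
"""

import numpy as np

from myosono import TissueParams, assemble_feature_vector, generate_phantom
from myosono.dataset_io import Diagnosis, ImageRecord, MuscleGroup, Side

fat = TissueParams.from_mean(m=1.2, mean=120.0, thickness_fraction=0.25)
muscle = TissueParams.from_mean(m=0.8, mean=110.0)  # bright, heavy-tailed

image, mask = generate_phantom(fat, muscle, 256, 256, np.random.default_rng(1))
record = ImageRecord(
    subject_id="demo", diagnosis=Diagnosis.IBM, muscle_group=MuscleGroup.BICEPS,
    side=Side.LEFT, view_index=1, depth_cm=4.0,
    image_path="demo.png", mask_path="demo_mask.png",
)

vector = assemble_feature_vector(record, image, mask)
for name, value in vector.items():
    print(f"{name:32s} {value:12.4f}")

# echo_mean_muscle reads back ~109, close to the generating 110, and the
# ratio feature ~0.9 says muscle is nearly as bright as fat — the pattern of
# chronic myopathic change.  nakagami_m_muscle comes back ~0.95 rather than
# the generating 0.8: at this brightness the heavy upper tail is clipped by
# the 8-bit display range, which thins the tail and biases the shape
# estimate upward.  Darker regions (see the generator tests at mean 60)
# recover the shape within a few percent.
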