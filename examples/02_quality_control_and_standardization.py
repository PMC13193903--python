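"""Quality-filter frames by size and standardize them for the classifier.

Frames whose shorter edge is below 50 px carry no usable morphology and are
discarded (the boundary value 50 survives). Kept frames are center-cropped
to a square, resized to 224 x 224, normalized, and replicated to 3 channels.
"""

import numpy as np
import pandas as pd

from ifcmorph import center_crop_square, qc_filter, to_model_input

sizes = [(49, 120), (50, 50), (200, 48), (96, 96)]
manifest = pd.DataFrame(
    {
        "image_id": range(len(sizes)),
        "height": [s[0] for s in sizes],
        "width": [s[1] for s in sizes],
    }
)
kept, rejected = qc_filter(manifest)
print(f"QC on sizes {sizes}: kept {len(kept)}, rejected {rejected}")
print("kept image_ids:", kept.image_id.tolist(), " (shorter edge >= 50)")

rng = np.random.default_rng(0)
frame = rng.integers(0, 255, size=(60, 100)).astype(np.uint8)
square = center_crop_square(frame)
x = to_model_input(square)
print(f"\n60x100 frame -> center crop {square.shape} -> model input {x.shape}")
print(
    "channels identical:",
    bool(np.array_equal(x[:, :, 0], x[:, :, 1]) and np.array_equal(x[:, :, 1], x[:, :, 2])),
)
print(f"normalized intensity range: [{x.min():.2f}, {x.max():.2f}]")
# The crop keeps columns 20..79 (centered short-edge square); normalization
# is (v/255 - 0.5) / 0.25, identical at train and test time.
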