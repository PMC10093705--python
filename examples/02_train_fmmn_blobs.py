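"""Train the fuzzy min-max net on synthetic unit-square blobs.

Shows the two hyperbox-count laws (theta = 0 and theta = 1) and held-out
accuracy for moderate theta on two well-separated Gaussian classes.
"""

import numpy as np
from sklearn.model_selection import train_test_split

from cytofmm import BlobSpec, generate_blobs, predict, train

spec = BlobSpec(
    n_per_class=200,
    n_features=2,
    class_centers=((0.3, 0.3), (0.58, 0.58)),
    spread=0.05,
    seed=42,
)
features, labels = generate_blobs(spec)
tr, te = train_test_split(
    np.arange(len(labels)), train_size=0.7, random_state=0, stratify=labels
)

# theta = 0: one point hyperbox per distinct training pattern
m0 = train(features.values[tr], labels[tr], theta=0.0)
print(f"theta=0.0 -> {m0.n_hyperboxes} hyperboxes ({len(tr)} training samples)")

# theta = 1: a single hyperbox per class
m1 = train(features.values[tr], labels[tr], theta=1.0)
print(f"theta=1.0 -> {m1.n_hyperboxes} hyperboxes (2 classes)")

# moderate theta: few boxes, high held-out accuracy
for theta in (0.1, 0.2, 0.3):
    model = train(features.values[tr], labels[tr], theta=theta)
    acc = float(np.mean(predict(model, features.values[te]) == labels[te]))
    print(f"theta={theta} -> {model.n_hyperboxes:3d} boxes, held-out accuracy {acc:.3f}")

# Small theta memorizes (many boxes), large theta compresses to one box
# per class; in between the net generalizes from a handful of boxes.
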