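"""Binary label maps for the Herlev and Sipakmed directory layouts.

Builds a placeholder Herlev-style tree (seven cell categories with the
published per-category counts) and shows the normal/abnormal binary
mapping a screening experiment uses.  Point ``build_manifest`` at a real
dataset download to do the same on actual images.
"""

import tempfile
from pathlib import Path

from cytofmm import build_manifest

HERLEV_COUNTS = {
    "normal_squamous": 74,
    "intermediate_squamous": 70,
    "columnar": 98,
    "mild_dysplasia": 182,
    "moderate_dysplasia": 146,
    "severe_dysplasia": 197,
    "carcinoma_in_situ": 150,
}

with tempfile.TemporaryDirectory() as work:
    root = Path(work) / "herlev"
    for category, n in HERLEV_COUNTS.items():
        folder = root / category
        folder.mkdir(parents=True)
        for i in range(n):
            (folder / f"img_{i:04d}.png").touch()  # placeholder files

    manifest = build_manifest(root, dataset_style="herlev")
    print("per-category counts:", manifest.counts())
    print("binary counts:      ", manifest.binary_counts())
    print("total images:       ", len(manifest))

# The three normal cell types (242 images) map to 'normal'; the four
# dysplasia/carcinoma categories (675 images) map to 'abnormal'.
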