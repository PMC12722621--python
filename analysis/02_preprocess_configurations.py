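#!/usr/bin/env python
"""Build the eight preprocessing configurations for one phantom.

Shows how binarization at rising fractions of the white-matter peak strips
texture while preserving shape: foreground voxel counts fall monotonically
with the threshold, and skull-stripping removes everything outside the
brain mask. Writes the per-configuration census to results/.
"""

from pathlib import Path

import pandas as pd

import shortcut_audit as sa

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

cfg = sa.PhantomConfig(grid_shape=(16, 16, 16), n_subjects_per_class=1, seed=0)
im = sa.generate_cohort(cfg).images[0]
peak = sa.compute_wm_peak(im.volume, im.mask)
print(f"white-matter peak of the 196-bin in-mask histogram: {peak:.4f}")

configs = sa.build_configurations(im.volume, im.mask)
rows = []
for cid in ("A1", "B1", "C1", "D1", "A2", "B2", "C2", "D2"):
    vol = configs[cid]
    spec = sa.CONFIGURATIONS[cid]
    rows.append({
        "configuration": cid,
        "skull_stripped": spec.skull_stripped,
        "binarizer": spec.binarizer if spec.binarizer else "none",
        "nonzero_voxels": int((vol.intensities > 0).sum()),
        "intensity_max": round(float(vol.intensities.max()), 3),
    })
table = pd.DataFrame(rows)
table.to_csv(RESULTS / "configuration_census.tsv", sep="\t", index=False)
print(table.to_string(index=False))
print("binarized foreground shrinks with the threshold; the *2 column "
      "equals the *1 column restricted to the brain mask")
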