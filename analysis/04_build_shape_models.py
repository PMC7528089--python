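#!/usr/bin/env python
"""Build the two PCA shape models and report variance structure.

Writes: results/variance_<model>.csv and results/mode_shapes_sd.csv
(mode 1 at +/-2.5 SD summary extents); the full dense model archives
(mean + mode matrix) are bulky generated artifacts and go to
scratch/models/ instead.
"""

import numpy as np
import pandas as pd

from common import SCRATCH, ensure_results, get_run
from lungshape.alignment import ShapeVector
from lungshape.io import save_model
from lungshape.model import mode_shape, variance_explained

run = get_run()
out = ensure_results()
models_dir = SCRATCH.parent / "models"

extent_rows = []
for mode, mr in run.by_mode.items():
    tag = mode.replace("-", "_")
    save_model(models_dir / f"model_{tag}", mr.model, gpa_mode=mode)
    var = pd.DataFrame(
        {
            "mode": np.arange(1, min(11, mr.model.n_modes + 1)),
            "variance_pct": 100 * mr.model.variance_fractions[:10],
            "cumulative_pct": [
                variance_explained(mr.model, m)
                for m in range(1, min(11, mr.model.n_modes + 1))
            ],
        }
    )
    var.to_csv(out / f"variance_{tag}.csv", index=False)
    print(f"{mode}: mode variance % "
          f"{np.round(100 * mr.model.variance_fractions[:4], 1).tolist()} "
          f"(first four, cumulative {var.cumulative_pct.iloc[3]:.0f}%)")

    # the +/-2.5 SD perturbation protocol for mode visualisation
    for w in (-2.5, 2.5):
        sv: ShapeVector = mode_shape(mr.model, 1, w)
        pos = sv.blocks()[:, 0, :]
        extent_rows.append(
            {
                "model": mode, "mode": 1, "sd_weight": w,
                "ap_extent": float(pos[:, 1].max() - pos[:, 1].min()),
                "si_extent": float(pos[:, 2].max() - pos[:, 2].min()),
            }
        )

pd.DataFrame(extent_rows).to_csv(out / "mode_shapes_sd.csv", index=False)
print("wrote model archives and +/-2.5 SD mode-1 extents")
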