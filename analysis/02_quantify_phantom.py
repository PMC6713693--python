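"""Build a synthetic abdominal phantom and quantify it.

Verifies that whole-organ volumes (voxel count x voxel volume) and the mean
liver fat fraction recovered from the emitted masks equal the phantom's
ground truth, and shows the effect of axial confinement on the fat masks.
Writes results/phantom_volumes.csv.
"""

from pathlib import Path

import numpy as np

from fatkinetics.phantom import PhantomSpec, make_phantom
from fatkinetics.pipeline import phantom_stage
from fatkinetics.quantify import axial_confine, mask_volume

SEED = 42
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table = phantom_stage(PhantomSpec(), np.random.default_rng(SEED))
    table.to_csv(RESULTS / "phantom_volumes.csv", index=False, float_format="%.10g")
    print(table.to_string(index=False))
    exact = np.allclose(table["volume_cm3"], table["truth_cm3"], rtol=0, atol=0)
    print(f"\nmeasured volumes equal ground truth exactly: {exact}")

    labels, _, _ = make_phantom(PhantomSpec(), np.random.default_rng(SEED))
    confined = axial_confine(labels, 18, 54)
    v_full = mask_volume(labels, "sat")
    v_conf = mask_volume(confined, "sat")
    print(f"SAT volume full grid {v_full:.1f} cm^3 -> confined slices [18, 54): {v_conf:.1f} cm^3")


if __name__ == "__main__":
    main()
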