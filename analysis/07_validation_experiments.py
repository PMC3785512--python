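#!/usr/bin/env python
"""Run the canonical validation experiments and tabulate their numbers.

Covers the tensor-fit oracle, fiber-orientation recovery, tube tractography
geometry, familywise-error calibration (200 null cohorts × 500
permutations) and injected-effect recovery; writes results/validation.json.
The heavy calibration takes a few minutes on one CPU.
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent))
from _config import SEED  # noqa: E402

from hippoconn import experiments  # noqa: E402

if __name__ == "__main__":
    out = {
        "tensor_oracle": experiments.tensor_oracle(SEED),
        "fiber_recovery": experiments.fiber_recovery(SEED),
        "tube_tractography": experiments.tube_tractography(SEED),
        "fwe_calibration": experiments.fwe_calibration(SEED),
        "effect_recovery": experiments.effect_recovery(SEED),
        "amnestic_rule": experiments.amnestic_rule(),
    }
    path = pathlib.Path("results/validation.json")
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(out, indent=2, default=str))
    print(json.dumps(out, indent=2, default=str))
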