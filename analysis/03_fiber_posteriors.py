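#!/usr/bin/env python
"""Sample ball-and-stick fiber posteriors per voxel (the "bedpost" stage).

Runs the Metropolis sampler (50 retained samples per voxel, two sticks with
a sparsity prior on the second) over the tracking mask of every subject;
persists merged sample volumes plus a JSON sidecar with sampler settings
and seeds under results/analysis/bedpost/.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent))
from _config import analysis_config  # noqa: E402

from hippoconn.pipeline import stage_bedpost  # noqa: E402

if __name__ == "__main__":
    prefixes = stage_bedpost(analysis_config())
    print(f"posterior samples written for {len(prefixes)} subjects")
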