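#!/usr/bin/env python
"""Probabilistic tractography from the hippocampus-like seed → HSC maps.

For every subject, launches 200 bidirectional streamlines from each voxel
of the seed blob, normalizes visit counts into per-seed connection
probabilities, and combines them with the voxelwise max into the subject's
hippocampal structural connectivity (HSC) map under results/analysis/track/.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent))
from _config import analysis_config  # noqa: E402

from hippoconn.pipeline import stage_track  # noqa: E402

if __name__ == "__main__":
    paths = stage_track(analysis_config())
    print(f"wrote {len(paths)} HSC maps")
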