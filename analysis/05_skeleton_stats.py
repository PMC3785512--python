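#!/usr/bin/env python
"""Skeleton-based group statistics with TFCE and permutation FWE.

Builds the mean-FA > 0.2 skeleton, projects each subject's FA, MD and HSC
onto it, and runs one-sided permutation contrasts (patients vs controls;
500 permutations, TFCE-enhanced, familywise-error corrected at α = 0.05).
Writes t / TFCE / 1−p volumes, the skeleton mask and the per-contrast
report table under results/analysis/stats/.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent))
from _config import analysis_config  # noqa: E402

from hippoconn.pipeline import stage_stats  # noqa: E402

if __name__ == "__main__":
    report = stage_stats(analysis_config())
    print(f"statistics written; report table: {report}")
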