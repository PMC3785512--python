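#!/usr/bin/env python
"""Render and display the study summary.

Prints the per-contrast table (abnormal white-matter volume fraction,
global and regional percent differences, group p-values) — the
machine-readable analogue of a cohort comparison table — and writes the
plain-text summary under results/analysis/stats/summary.txt.
"""

import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent))
from _config import analysis_config  # noqa: E402

from hippoconn.pipeline import stage_report  # noqa: E402

if __name__ == "__main__":
    cfg = analysis_config()
    summary = stage_report(cfg)
    df = pd.read_csv(f"{cfg.outdir}/stats/report.tsv", sep="\t")
    print(df.to_string(index=False))
    print()
    print(open(summary).read())
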