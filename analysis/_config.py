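"""Shared configuration for the numbered analysis drivers.

One desk-scale amnestic-MCI-like study: 15 controls vs 15 patients with a
7% mean-diffusivity elevation over a contiguous tract segment, SNR 25,
500-permutation skeleton statistics.  Every driver reads this config so the
whole sequence is reproducible from the single seed below.
"""

from hippoconn.pipeline import PipelineConfig

SEED = 20130927  # study seed


def analysis_config(outdir: str = "results/analysis") -> PipelineConfig:
    return PipelineConfig(
        outdir=outdir,
        seed=SEED,
        preset="amci-like",
        n_per_group={"CN": 15, "aMCI": 15},
        noise_sigma=0.04,        # SNR 25 relative to s0
        track_n_samples=200,     # desk-scale streamline count per seed voxel
        stats_n_perm=500,
    )
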