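"""End-to-end pipeline orchestration with reproducible configuration.

Stages: phantom → tensor fit → fiber posterior ("bedpost") → tractography /
connectivity ("track") → skeleton statistics ("stats") → report.  Each stage
persists its outputs under its own subdirectory, is skipped when those
outputs already exist (resume), and never touches another stage's outputs.
A run manifest records the effective configuration, per-stage seeds and
output file hashes.

Seed discipline: the single global seed expands into named per-stage and
per-subject substreams (``numpy.random.SeedSequence`` spawn keys), so
re-running any stage — or subsetting the cohort — reproduces results
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from hippoconn import io, phantom, skeleton, tensor, tract
from hippoconn.errors import ConfigurationError, InputError
from hippoconn.fibermodel import SamplerConfig, load_posterior, sample_posterior_volume, save_posterior
from hippoconn.tract import StreamlineConfig

STAGE_IDS = {"phantom": 1, "fit": 2, "bedpost": 3, "track": 4, "stats": 5}

PRESETS = ("amci-like", "ad-like", "null")


@dataclass
class PipelineConfig:
    """Serializable configuration for a full run."""

    outdir: str = "hippoconn_run"
    seed: int = 0
    preset: str = "amci-like"
    n_per_group: dict | None = None
    grid_shape: tuple = (32, 32, 16)
    voxel_size: float = 2.0
    n_dirs: int = 32
    n_b0: int = 4
    b_value: float = 1000.0
    noise_sigma: float = 0.04
    effect_fraction: float | None = None   # None → preset default
    sampler_k: int = 50
    sampler_burn_in: int = 200
    sampler_thin: int = 5
    track_n_samples: int = 200
    track_step_mm: float = 0.5
    track_curvature_cos_min: float = 0.2
    track_max_steps: int = 2000
    stats_fa_threshold: float = 0.2
    stats_n_perm: int = 500
    stats_alpha: float = 0.05
    stats_max_dist_mm: float = 4.0
    tfce_e: float = 0.5
    tfce_h: float = 2.0

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ConfigurationError(f"unknown preset {self.preset!r}; choose from {PRESETS}")
        self.grid_shape = tuple(self.grid_shape)

    # -- (de)serialization ---------------------------------------------------
    def to_yaml(self, path: str) -> str:
        d = asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        # the output location is implied by where the file lives; leaving it
        # out keeps two runs of one config byte-identical wherever they land
        d.pop("outdir")
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    # -- derived objects -----------------------------------------------------
    def seed_for(self, stage: str, *extra: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(
            self.seed, spawn_key=(STAGE_IDS[stage],) + tuple(int(e) for e in extra)
        )

    def scheme(self) -> phantom.GradientScheme:
        return phantom.make_gradient_scheme(self.n_dirs, self.n_b0, self.b_value, rng_seed=0)

    def cohort_spec(self) -> phantom.CohortSpec:
        geom = phantom.default_geometry(self.grid_shape, self.voxel_size)
        phantom_seed = int(self.seed_for("phantom").generate_state(1)[0] % (2**31))
        kwargs = dict(
            geometry=geom,
            n_per_group=self.n_per_group,
            rng_seed=phantom_seed,
            noise_sigma=self.noise_sigma,
            scheme=self.scheme(),
        )
        if self.preset == "amci-like":
            if self.effect_fraction is not None:
                kwargs["effect_fraction_along_tract"] = self.effect_fraction
            return phantom.amci_like_spec(**kwargs)
        if self.preset == "ad-like":
            if self.effect_fraction is not None:
                kwargs["effect_fraction_along_tract"] = self.effect_fraction
            return phantom.ad_like_spec(**kwargs)
        # null cohort: two groups, no injected effect
        spec = phantom.amci_like_spec(**kwargs)
        return dataclasses.replace(spec, md_elevation_pct=0.0, fa_reduction_pct=0.0)

    def sampler_config(self) -> SamplerConfig:
        return SamplerConfig(k=self.sampler_k, burn_in=self.sampler_burn_in, thin=self.sampler_thin)

    def streamline_config(self) -> StreamlineConfig:
        return StreamlineConfig(
            n_samples=self.track_n_samples,
            step=self.track_step_mm,
            curvature_cos_min=self.track_curvature_cos_min,
            max_steps=self.track_max_steps,
        )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_dir(cfg: PipelineConfig, stage: str) -> str:
    return io.ensure_dir(os.path.join(cfg.outdir, stage))


def _subjects(cfg: PipelineConfig) -> pd.DataFrame:
    path = os.path.join(cfg.outdir, "phantom", "manifest.tsv")
    if not os.path.exists(path):
        raise InputError("phantom stage output missing: run the 'phantom' stage first")
    return io.load_manifest(path)


def stage_phantom(cfg: PipelineConfig) -> str:
    out = _stage_dir(cfg, "phantom")
    manifest = os.path.join(out, "manifest.tsv")
    if os.path.exists(manifest):
        return manifest
    spec = cfg.cohort_spec()
    subjects = phantom.generate_cohort(spec)
    return phantom.write_cohort(subjects, spec, out)


def stage_fit(cfg: PipelineConfig) -> list:
    out = _stage_dir(cfg, "fit")
    df = _subjects(cfg)
    pdir = os.path.join(cfg.outdir, "phantom")
    paths = []
    for _, row in df.iterrows():
        fa_path = os.path.join(out, f"{row.subject_id}_FA.nii.gz")
        md_path = os.path.join(out, f"{row.subject_id}_MD.nii.gz")
        if os.path.exists(fa_path) and os.path.exists(md_path):
            paths += [fa_path, md_path]
            continue
        dwi, vs = io.load_volume(os.path.join(pdir, row.dwi_path))
        bvals, bvecs = io.load_bvals_bvecs(
            os.path.join(pdir, row.bval_path), os.path.join(pdir, row.bvec_path)
        )
        fa, md, _ = tensor.fit_fa_md(dwi, bvals, bvecs)
        io.save_volume(fa, vs[0], fa_path)
        io.save_volume(md, vs[0], md_path)
        paths += [fa_path, md_path]
    return paths


def stage_bedpost(cfg: PipelineConfig) -> list:
    out = _stage_dir(cfg, "bedpost")
    df = _subjects(cfg)
    pdir = os.path.join(cfg.outdir, "phantom")
    mask, _ = io.load_volume(os.path.join(pdir, "tracking_mask.nii.gz"))
    mask = mask > 0.5
    prefixes = []
    for i, row in df.iterrows():
        prefix = os.path.join(out, row.subject_id)
        sidecar = f"{prefix}_bedpost_sidecar.json"
        prefixes.append(prefix)
        if os.path.exists(sidecar):
            continue
        dwi, vs = io.load_volume(os.path.join(pdir, row.dwi_path))
        bvals, bvecs = io.load_bvals_bvecs(
            os.path.join(pdir, row.bval_path), os.path.join(pdir, row.bvec_path)
        )
        scheme = phantom.GradientScheme(bvals=bvals, bvecs=bvecs)
        rng = np.random.default_rng(cfg.seed_for("bedpost", i))
        post = sample_posterior_volume(dwi, scheme, mask, cfg.sampler_config(), rng)
        save_posterior(
            post,
            vs[0],
            prefix,
            settings={"burn_in": cfg.sampler_burn_in, "thin": cfg.sampler_thin,
                      "stage_seed": [cfg.seed, STAGE_IDS["bedpost"], int(i)]},
        )
    return prefixes


def stage_track(cfg: PipelineConfig) -> list:
    out = _stage_dir(cfg, "track")
    df = _subjects(cfg)
    pdir = os.path.join(cfg.outdir, "phantom")
    seed_mask, _ = io.load_volume(os.path.join(pdir, "seed_mask.nii.gz"))
    seed_mask = seed_mask > 0.5
    paths = []
    for i, row in df.iterrows():
        hsc_path = os.path.join(out, f"{row.subject_id}_HSC.nii.gz")
        paths.append(hsc_path)
        if os.path.exists(hsc_path):
            continue
        post = load_posterior(os.path.join(cfg.outdir, "bedpost", row.subject_id))
        track_seed = int(cfg.seed_for("track", i).generate_state(1)[0] % (2**31))
        hsc = tract.run_hsc(
            post,
            seed_mask,
            cfg.streamline_config(),
            rng_seed=track_seed,
            voxel_size=cfg.voxel_size,
        )
        io.save_volume(hsc.prob, cfg.voxel_size, hsc_path)
        with open(os.path.join(out, f"{row.subject_id}_track_sidecar.json"), "w") as fh:
            json.dump(
                {"rng_seed": track_seed, "cfg": asdict(cfg.streamline_config())},
                fh, indent=2, default=str,
            )
    return paths


def _modality_contrasts(control: str, patient: str) -> list:
    """Directional contrasts per modality: patients show raised diffusivity,
    lowered anisotropy and lowered connectivity relative to controls."""
    return [
        ("MD", patient, control, "A>B"),
        ("FA", patient, control, "A<B"),
        ("HSC", patient, control, "A<B"),
    ]


def stage_stats(cfg: PipelineConfig) -> str:
    out = _stage_dir(cfg, "stats")
    report_path = os.path.join(out, "report.tsv")
    if os.path.exists(report_path):
        return report_path
    df = _subjects(cfg)
    groups = df["group"].to_numpy()
    control = cfg.cohort_spec().control_group
    fa_maps, md_maps, hsc_maps = [], [], []
    for _, row in df.iterrows():
        fa, _ = io.load_volume(os.path.join(cfg.outdir, "fit", f"{row.subject_id}_FA.nii.gz"))
        md, _ = io.load_volume(os.path.join(cfg.outdir, "fit", f"{row.subject_id}_MD.nii.gz"))
        hsc, _ = io.load_volume(os.path.join(cfg.outdir, "track", f"{row.subject_id}_HSC.nii.gz"))
        fa_maps.append(fa)
        md_maps.append(md)
        hsc_maps.append(hsc)
    sk = skeleton.build_skeleton(fa_maps, cfg.stats_fa_threshold)
    io.save_volume(sk.mask_volume(), cfg.voxel_size, os.path.join(out, "skeleton_mask.nii.gz"))
    by_modality = {
        "FA": skeleton.project_cohort(fa_maps, fa_maps, sk, "FA", cfg.stats_max_dist_mm, cfg.voxel_size),
        "MD": skeleton.project_cohort(md_maps, fa_maps, sk, "MD", cfg.stats_max_dist_mm, cfg.voxel_size),
        "HSC": skeleton.project_cohort(hsc_maps, fa_maps, sk, "HSC", cfg.stats_max_dist_mm, cfg.voxel_size),
    }
    stats_seed = int(cfg.seed_for("stats").generate_state(1)[0] % (2**31))
    rows = []
    patients = sorted(set(groups) - {control})
    for patient in patients:
        for modality, ga, gb, direction in _modality_contrasts(control, patient):
            pm = by_modality[modality]
            res = skeleton.permutation_contrast(
                pm, groups, ga, gb, sk.neighbors,
                direction=direction, n_perm=cfg.stats_n_perm,
                e_exp=cfg.tfce_e, h_exp=cfg.tfce_h,
                alpha=cfg.stats_alpha, rng_seed=stats_seed,
            )
            tag = f"{modality}_{ga}_{'gt' if direction == 'A>B' else 'lt'}_{gb}"
            for name, vec in (("tstat", res.t), ("tfce", res.tfce_scores),
                              ("1minusp", 1.0 - res.p_corrected)):
                vol = np.zeros(sk.shape)
                vol[tuple(sk.coords.T)] = vec
                io.save_volume(vol, cfg.voxel_size, os.path.join(out, f"{tag}_{name}.nii.gz"))
            rep = skeleton.summary_metrics(pm, groups, res, cn_label=control)
            gt = rep["groups"].set_index("group")
            rows.append(
                {
                    "contrast": f"{ga} vs {gb} ({direction})",
                    "modality": modality,
                    "abnormal_fraction": skeleton.abnormal_fraction(res, sk),
                    "global_pct_diff": gt.loc[ga, "global_pct_diff"],
                    "regional_pct_diff": gt.loc[ga, "regional_pct_diff"],
                    "p_global": gt.loc[ga, "p_global"],
                    "n_skeleton_voxels": sk.n_voxels,
                    "n_perm": res.n_perm,
                    "exhaustive": res.exhaustive,
                }
            )
    pd.DataFrame(rows).to_csv(report_path, sep="\t", index=False)
    return report_path


def stage_report(cfg: PipelineConfig) -> str:
    """Render a plain-text summary of the stats report."""
    report_path = os.path.join(cfg.outdir, "stats", "report.tsv")
    if not os.path.exists(report_path):
        raise InputError("stats stage output missing: run the 'stats' stage first")
    df = pd.read_csv(report_path, sep="\t")
    out = os.path.join(cfg.outdir, "stats", "summary.txt")
    lines = ["Skeleton group-comparison summary", "=" * 34, ""]
    for _, r in df.iterrows():
        lines.append(
            f"{r.contrast:30s} {r.modality:4s} abnormal WM fraction "
            f"{r.abnormal_fraction:6.3f}  global Δ {r.global_pct_diff:+7.2f}%  "
            f"regional Δ {r.regional_pct_diff:+7.2f}%  p_global {r.p_global:.4g}"
        )
    with open(out, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and write the run manifest; returns the manifest."""
    io.ensure_dir(cfg.outdir)
    cfg.to_yaml(os.path.join(cfg.outdir, "config.yaml"))
    stage_phantom(cfg)
    stage_fit(cfg)
    stage_bedpost(cfg)
    stage_track(cfg)
    stage_stats(cfg)
    stage_report(cfg)
    manifest = {"config": asdict(cfg), "seed": cfg.seed, "outputs": {}}
    manifest["config"]["grid_shape"] = list(cfg.grid_shape)
    for root, _, files in os.walk(cfg.outdir):
        for fn in sorted(files):
            if fn == "run_manifest.json":
                continue
            p = os.path.join(root, fn)
            manifest["outputs"][os.path.relpath(p, cfg.outdir)] = io.sha256_file(p)
    with open(os.path.join(cfg.outdir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
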