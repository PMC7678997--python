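"""End-to-end orchestration: generate -> fit -> aggregate -> slopes ->
associate, from one config, with per-stage caching and a run manifest.

Each stage writes plain-text artifacts (CSV, NIfTI) into the output
directory; a stage whose config section and inputs are unchanged is skipped
on rerun, so the statistics can iterate without repeating the voxel fits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import joint_fw_mdt, measure_contrast_table, slope_association_table
from .freewater import FreeWaterModel
from .gradients import make_gradient_scheme
from .nifti import save_phantom, save_volume
from .slopes import IstSlopeModel
from .synthetic import (
    DEFAULT_VISIT_TIMES,
    make_phantom,
    simulate_longitudinal_scores,
)
from .tensor import DiffusionTensorModel
from .tractometry import aggregate_tract, percent_change, wmh_volumetrics

__all__ = ["PipelineConfig", "run_pipeline"]

MAP_NAMES = ("fa", "md", "rd", "ad", "fat", "mdt", "rdt", "adt", "fw")


@dataclasses.dataclass
class PipelineConfig:
    """Everything a run needs, serializable to/from YAML."""

    # phantom / scheme
    n_subjects: int = 8
    grid_shape: tuple = (16, 16, 12)
    bundle_radius: float = 1.4
    wmh_overlap_fraction: float = 0.1
    fw_bundle_mean: float = 0.141
    fw_bundle_sd: float = 0.017
    bundle_fa_mean: float = 0.567
    bundle_fa_sd: float = 0.054
    bundle_md_mean: float = 0.755e-3
    bundle_md_sd: float = 0.034e-3
    snr: float | None = None
    n_dirs_half: int = 21
    bvalue: float = 1000.0
    n_series: int = 2
    # cohort / trajectories
    visit_times: tuple = DEFAULT_VISIT_TIMES
    mean_slope_ist15: float = -0.489
    sd_intercept: float = 2.0
    sd_slope: float = 0.15
    resid_sd: float = 1.0
    effect_measure: str | None = None  # e.g. "mdt"
    effect_per_sd: float = 0.0  # slope change (words/yr) per SD of the measure
    # statistics
    fdr_q: float = 0.05
    covariates: tuple = ("age", "cingulum_volume_pct_tiv")
    adjust_wmh: bool = False
    # bookkeeping
    seed: int = 0
    out_dir: str = "fwtract_run"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["visit_times"] = list(self.visit_times)
        d["covariates"] = list(self.covariates)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("grid_shape", "visit_times", "covariates"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    def section_hash(self, *fields: str) -> str:
        d = dataclasses.asdict(self)
        payload = json.dumps({f: str(d[f]) for f in sorted(fields)}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_fresh(out: Path, stage: str, key: str, outputs: list[Path]) -> bool:
    marker = out / f".{stage}.hash"
    return marker.exists() and marker.read_text() == key and all(p.exists() for p in outputs)


def _stage_done(out: Path, stage: str, key: str) -> None:
    (out / f".{stage}.hash").write_text(key)


def run_pipeline(config: PipelineConfig, force: bool = False) -> Path:
    """Run every stage; returns the output directory.

    Any stage failure raises with the stage name (and subject, where
    applicable) in the message. A manifest with the config, seeds, package
    version and per-stage wall times is written at the end.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = {"version": __version__, "seed": config.seed, "stages": {}}
    rng = np.random.default_rng(config.seed)
    sub_seeds = rng.integers(2**31, size=config.n_subjects)
    traj_seed = int(rng.integers(2**31))
    manifest["subject_seeds"] = [int(s) for s in sub_seeds]
    manifest["trajectory_seed"] = traj_seed

    def timed(stage):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, exc_type, exc, tb):
                manifest["stages"][stage] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

        return _T()

    scheme = make_gradient_scheme(config.n_dirs_half, config.bvalue, config.n_series)
    phantom_fields = (
        "n_subjects", "grid_shape", "bundle_radius", "wmh_overlap_fraction",
        "fw_bundle_mean", "fw_bundle_sd", "bundle_fa_mean", "bundle_fa_sd",
        "bundle_md_mean", "bundle_md_sd", "snr", "n_dirs_half", "bvalue",
        "n_series", "seed",
    )
    sim_key = config.section_hash(*phantom_fields)
    tract_csv = out / "tract_measures.csv"

    # ---- simulate + fit + aggregate, per subject ---------------------------
    if force or not _stage_fresh(out, "fit", sim_key, [tract_csv]):
        rows = []
        with timed("simulate_fit_aggregate"):
            fw_model = FreeWaterModel(scheme)
            dti_model = DiffusionTensorModel(scheme)
            for i in range(config.n_subjects):
                srng = np.random.default_rng(sub_seeds[i])
                # per-subject tissue state: bundle scalars drawn around the
                # cohort means, so measures vary across subjects
                fw_mean = float(
                    np.clip(srng.normal(config.fw_bundle_mean, config.fw_bundle_sd), 0.01, 0.9)
                )
                fa_i = float(np.clip(srng.normal(config.bundle_fa_mean, config.bundle_fa_sd), 0.1, 0.95))
                md_i = float(np.clip(srng.normal(config.bundle_md_mean, config.bundle_md_sd), 2e-4, 2.5e-3))
                try:
                    ph = make_phantom(
                        grid_shape=config.grid_shape,
                        bundle_radius=config.bundle_radius,
                        wmh_overlap_fraction=config.wmh_overlap_fraction,
                        fw_bundle=fw_mean,
                        bundle_fa=fa_i,
                        bundle_md=md_i,
                        snr=config.snr,
                        scheme=scheme,
                        seed=int(sub_seeds[i]),
                    )
                    sub_dir = out / f"sub-{i:03d}"
                    save_phantom(ph, sub_dir, f"sub-{i:03d}")

                    bundle = ph.left_mask | ph.right_mask
                    sel = bundle.flat[ph.in_brain_index()].astype(bool)
                    dti = dti_model.fit(ph.signal[sel])
                    fwf = fw_model.fit(ph.signal[sel], init_fraction=None)

                    maps = {
                        "fa": dti.fa, "md": dti.md, "rd": dti.rd, "ad": dti.ad,
                        "fat": fwf.fat, "mdt": fwf.mdt, "rdt": fwf.rdt,
                        "adt": fwf.adt, "fw": fwf.fw_fraction,
                    }
                    row = {"subject": i}
                    bundle_vals = np.zeros(ph.grid_shape)
                    flat_idx = ph.in_brain_index()[sel]
                    for name, vals in maps.items():
                        bundle_vals.flat[flat_idx] = vals
                        ts = aggregate_tract(bundle_vals, ph.left_mask, ph.right_mask)
                        row[name] = ts.bilateral_mean
                        save_volume(bundle_vals, sub_dir / f"sub-{i:03d}_{name}.nii.gz", ph.voxel_size)
                    for conv, corr in (("fa", "fat"), ("md", "mdt"), ("rd", "rdt"), ("ad", "adt")):
                        row[f"pct_change_{conv}"] = percent_change(row[conv], row[corr])
                    vol = wmh_volumetrics(
                        ph.wmh_mask, ph.wm_mask, bundle, ph.icv_mask, ph.voxel_volume_ml
                    )
                    row["total_wmh_ml"] = vol.total_wmh_ml
                    row["total_wmh_log"] = vol.total_wmh_log
                    row["cingulum_wmh_pct"] = vol.cingulum_wmh_pct
                    row["cingulum_volume_pct_tiv"] = vol.bundle_volume_pct_tiv
                    row["age"] = float(srng.normal(81.2, 4.0))
                    rows.append(row)
                except Exception as exc:
                    raise RuntimeError(f"subject {i}: {exc}") from exc
            pd.DataFrame(rows).to_csv(tract_csv, index=False)
        _stage_done(out, "fit", sim_key)

    tract = pd.read_csv(tract_csv)

    # ---- longitudinal scores + slopes --------------------------------------
    slope_fields = phantom_fields + (
        "visit_times", "mean_slope_ist15", "sd_intercept", "sd_slope",
        "resid_sd", "effect_measure", "effect_per_sd",
    )
    slopes_key = config.section_hash(*slope_fields)
    scores_csv = out / "ist_scores.csv"
    slopes_csv = out / "ist_slopes.csv"
    if force or not _stage_fresh(out, "slopes", slopes_key, [scores_csv, slopes_csv]):
        with timed("slopes"):
            cov = None
            if config.effect_measure:
                m = tract[config.effect_measure]
                cov = ((m - m.mean()) / m.std(ddof=1)).to_numpy()
            scores = simulate_longitudinal_scores(
                n_subjects=config.n_subjects,
                visit_times=config.visit_times,
                mean_slope=config.mean_slope_ist15,
                sd_intercept=config.sd_intercept,
                sd_slope=config.sd_slope,
                resid_sd=config.resid_sd,
                covariate=cov,
                covariate_link=config.effect_per_sd,
                seed=traj_seed,
            )
            scores.to_csv(scores_csv, index=False)
            if config.n_subjects >= 10:
                res = IstSlopeModel(scores).fit()
                res.subject_slopes.add_prefix("slope_").to_csv(slopes_csv)
                summary = res.summary()
            else:
                # mixed model needs >= 10 subjects; tiny cohorts get the
                # two-stage per-subject OLS estimator instead
                from .slopes import SCORE_COLUMNS, ols_slopes

                slopes_df = pd.concat(
                    [ols_slopes(scores, s).rename(f"slope_{s}") for s in SCORE_COLUMNS], axis=1
                )
                slopes_df.index.name = "subject"
                slopes_df.to_csv(slopes_csv)
                summary = "per-subject OLS slopes (cohort too small for the mixed model)"
            (out / "slopes_summary.txt").write_text(summary + "\n")
        _stage_done(out, "slopes", slopes_key)

    # ---- association --------------------------------------------------------
    assoc_key = config.section_hash(*(slope_fields + ("fdr_q", "covariates", "adjust_wmh")))
    t2_csv = out / "measure_contrast_table.csv"
    t3_csv = out / "slope_association_table.csv"
    joint_csv = out / "joint_fw_mdt.csv"
    if force or not _stage_fresh(out, "associate", assoc_key, [t2_csv, t3_csv, joint_csv]):
        with timed("associate"):
            slopes = pd.read_csv(slopes_csv)
            cohort = tract.merge(slopes, on="subject")
            extra = ["total_wmh_log"] if config.adjust_wmh else []
            n = len(cohort)
            # trim covariates a tiny cohort cannot support (n > p + 2)
            covs = list(config.covariates) + extra
            while covs and n <= 1 + len(covs) + 2:
                covs.pop()
            measure_contrast_table(cohort, q=config.fdr_q).to_csv(t2_csv, index=False)
            slope_association_table(cohort, covariates=covs, q=config.fdr_q).to_csv(t3_csv, index=False)
            if n > 2 + len(covs) + 2:
                joint_fw_mdt(cohort, covariates=covs).to_csv(joint_csv, index=False)
            else:
                joint_csv.write_text("score,predictor,beta,p_raw,r_squared,n\n")
        _stage_done(out, "associate", assoc_key)

    manifest["outputs"] = sorted(str(p.relative_to(out)) for p in out.rglob("*.csv"))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
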