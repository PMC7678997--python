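"""Synthetic inputs with planted ground truth.

Everything the pipeline consumes can be generated here: bi-tensor
diffusion-weighted signals with Rician noise, bundle/lesion/tissue masks on
a small 3D grid, longitudinal verbal-fluency trajectories with random
intercepts and slopes, screening records with staged exclusion flags, and
cohort-level tables with a planted diffusion-slope effect. Ground truth
(tensors, fractions, slopes) travels with every object so recovery can be
tested.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .freewater import D_ISO
from .gradients import GradientScheme, make_gradient_scheme
from .tensor import tensor_scalars

__all__ = [
    "VoxelModel",
    "PhantomVolume",
    "ScreeningRecord",
    "tensor_from_scalars",
    "simulate_bitensor_signal",
    "make_phantom",
    "simulate_longitudinal_scores",
    "apply_exclusions",
    "make_screening_records",
    "make_cohort_table",
    "EXCLUSION_STAGES",
    "DEFAULT_VISIT_TIMES",
]

DEFAULT_VISIT_TIMES = (0.0, 2.0, 4.0, 7.0, 10.0, 12.0)

# screening attrition stages, applied in this order
EXCLUSION_STAGES = (
    "dementia",
    "brain_pathology",
    "mri_unavailable",
    "mri_artefacts",
    "preprocessing_failure",
    "cingulum_reconstruction_failure",
    "tractography_qc_failure",
)


@dataclasses.dataclass
class VoxelModel:
    """Planted two-compartment voxel: tissue tensor (mm^2/s), free-water
    fraction in [0, 1] and non-DW amplitude s0 > 0."""

    tissue_tensor: np.ndarray
    fw_fraction: float
    s0: float = 1.0

    def __post_init__(self):
        D = np.asarray(self.tissue_tensor, dtype=float)
        if D.shape != (3, 3) or not np.allclose(D, D.T):
            raise ValueError("tissue_tensor must be symmetric 3x3")
        if np.linalg.eigvalsh(D).min() < -1e-15:
            raise ValueError("tissue_tensor must be positive semidefinite")
        if not 0.0 <= self.fw_fraction <= 1.0:
            raise ValueError("fw_fraction must lie in [0, 1]")
        if self.s0 <= 0:
            raise ValueError("s0 must be > 0")
        self.tissue_tensor = D


def tensor_from_scalars(fa: float, md: float) -> np.ndarray:
    """Axially symmetric eigenvalue triple (lam1, lam_perp, lam_perp) with the
    requested FA and MD.

    For a prolate triple (a, b, b) FA reduces to |a - b| / sqrt(a^2 + 2 b^2),
    which inverts in closed form: a - b = FA * MD * sqrt(3 / (1 - 2 FA^2 / 3)).
    """
    if not 0.0 <= fa < 1.0:
        raise ValueError("fa must lie in [0, 1)")
    if md <= 0:
        raise ValueError("md must be > 0")
    d = fa * md * np.sqrt(3.0 / (1.0 - 2.0 * fa**2 / 3.0))
    lam_perp = md - d / 3.0
    lam1 = md + 2.0 * d / 3.0
    if lam_perp < 0:
        raise ValueError(f"fa={fa}, md={md} would force a negative radial eigenvalue")
    return np.array([lam1, lam_perp, lam_perp])


def _axially_symmetric_tensor(eigenvalues: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Tensor with principal eigenvalue along ``axis`` and the two remaining
    (equal) eigenvalues transverse to it."""
    e1 = np.asarray(axis, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    lam1, lam2, lam3 = eigenvalues
    return lam2 * np.eye(3) + (lam1 - lam2) * np.outer(e1, e1) + (lam3 - lam2) * 0.0 * np.eye(3)


def simulate_bitensor_signal(
    model: VoxelModel,
    scheme: GradientScheme,
    snr: float | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Forward bi-tensor signal per volume, optionally with Rician noise.

    Noise-free value: S0 * [(1-f) exp(-b g^T D g) + f exp(-b d_iso)].
    With ``snr`` given, Rician noise of width sigma = S0 / snr is applied to
    each volume (Gaussian noise on two quadrature channels, magnitude taken),
    reproducibly under ``seed``.
    """
    if snr is not None and snr <= 0:
        raise ValueError("snr must be > 0 or None")
    b = scheme.bvals
    g = scheme.bvecs
    q = np.einsum("vi,ij,vj->v", g, model.tissue_tensor, g)
    f = model.fw_fraction
    signal = model.s0 * ((1.0 - f) * np.exp(-b * q) + f * np.exp(-b * D_ISO))
    if snr is not None:
        rng = np.random.default_rng(seed)
        sigma = model.s0 / snr
        re = signal + sigma * rng.standard_normal(signal.shape)
        im = sigma * rng.standard_normal(signal.shape)
        signal = np.hypot(re, im)
    return signal


# ---------------------------------------------------------------------------
# phantom volumes
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PhantomVolume:
    """Desk-scale stand-in for one subject's native-space data.

    ``signal`` is (n_voxels, n_volumes) over the in-brain (intracranial)
    voxels in C order of ``np.flatnonzero(icv_mask)``. Ground-truth tensors
    and fractions are per in-brain voxel in the same order.
    """

    signal: np.ndarray
    grid_shape: tuple
    voxel_size: float  # mm, isotropic
    scheme: GradientScheme
    left_mask: np.ndarray
    right_mask: np.ndarray
    wm_mask: np.ndarray
    wmh_mask: np.ndarray
    icv_mask: np.ndarray
    true_tensors: np.ndarray
    true_fractions: np.ndarray
    true_s0: np.ndarray

    def __post_init__(self):
        bundle = self.left_mask | self.right_mask
        if not (bundle <= self.wm_mask).all():
            raise ValueError("bundle masks must lie inside the white-matter mask")
        if not (self.wm_mask <= self.icv_mask).all():
            raise ValueError("white-matter mask must lie inside the intracranial mask")
        if not (self.wmh_mask <= self.wm_mask).all():
            raise ValueError("WMH mask must lie inside the white-matter mask")
        if np.any(self.signal < 0):
            raise ValueError("signals must be nonnegative")

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size**3 / 1000.0

    def in_brain_index(self) -> np.ndarray:
        return np.flatnonzero(self.icv_mask)

    def map_to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-in-brain-voxel values back onto the 3D grid."""
        vol = np.full(self.grid_shape, fill, dtype=float)
        vol.flat[self.in_brain_index()] = values
        return vol


def _tube_mask(grid_shape, center_xz, radius, y_span):
    """Tube along y: voxels whose (x, z) distance to center is <= radius."""
    nx, ny, nz = grid_shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cz = center_xz
    in_xz = (x - cx) ** 2 + (z - cz) ** 2 <= radius**2
    in_y = (y >= y_span[0]) & (y < y_span[1])
    return np.broadcast_to(in_xz & in_y, grid_shape).copy()


def make_phantom(
    grid_shape: tuple = (24, 24, 16),
    bundle_radius: float = 1.6,
    wmh_overlap_fraction: float = 0.1,
    fw_bundle: float = 0.141,
    fw_wm: float = 0.25,
    fw_wmh_boost: float = 0.2,
    bundle_fa: float = 0.567,
    bundle_md: float = 0.755e-3,
    wm_fa: float = 0.35,
    wm_md: float = 0.80e-3,
    snr: float | None = None,
    scheme: GradientScheme | None = None,
    voxel_size: float = 2.0,
    seed: int = 0,
) -> PhantomVolume:
    """Build a phantom: two tube-shaped bundles inside a white-matter slab
    inside an intracranial box, a lesion blob overlapping the left bundle by
    the requested fraction, planted bi-tensor voxel models and signals.

    Default tissue scalars and free-water fractions are set to healthy
    elderly cingulum values; the lesion raises the local free-water fraction
    by ``fw_wmh_boost``.
    """
    if not 0.0 <= wmh_overlap_fraction <= 1.0:
        raise ValueError("wmh_overlap_fraction must lie in [0, 1]")
    if max(grid_shape) > 64:
        raise ValueError("phantom grids are capped at 64 voxels per axis")
    if scheme is None:
        scheme = make_gradient_scheme(21, 1000.0, 2)

    nx, ny, nz = grid_shape
    rng = np.random.default_rng(seed)

    icv = np.zeros(grid_shape, dtype=bool)
    icv[1:-1, 1:-1, 1:-1] = True
    wm = np.zeros(grid_shape, dtype=bool)
    wm[2:-2, 2:-2, 2:-2] = True

    y_span = (3, ny - 3)
    zc = nz // 2
    left = _tube_mask(grid_shape, (nx // 2 - max(3, nx // 6), zc), bundle_radius, y_span) & wm
    right = _tube_mask(grid_shape, (nx // 2 + max(3, nx // 6), zc), bundle_radius, y_span) & wm
    bundle = left | right

    # lesion: grow from one end of the left bundle until the requested share
    # of bundle voxels is covered, then pad with nearby non-bundle WM voxels
    n_bundle = int(bundle.sum())
    n_overlap = int(round(wmh_overlap_fraction * n_bundle))
    wmh = np.zeros(grid_shape, dtype=bool)
    if n_overlap > 0:
        idx = np.argwhere(left)
        idx = idx[np.lexsort((idx[:, 2], idx[:, 0], idx[:, 1]))]  # sweep along y
        take = idx[:n_overlap]
        if take.shape[0] < n_overlap:  # spill into the right bundle if needed
            extra = np.argwhere(right)[: n_overlap - take.shape[0]]
            take = np.vstack([take, extra])
        wmh[tuple(take.T)] = True
    # non-bundle lesion shell, ~ the same size as the bundle part
    shell = np.argwhere(wm & ~bundle)
    order = np.argsort(((shell - [nx // 2 - max(3, nx // 6), 4, zc]) ** 2).sum(1))
    n_shell = max(n_overlap, n_bundle // 8)
    wmh[tuple(shell[order[:n_shell]].T)] = True
    wmh &= wm

    in_brain = np.flatnonzero(icv)
    n_vox = in_brain.size
    flat = lambda m: m.flat[in_brain].astype(bool)
    fl_left, fl_right, fl_wm, fl_wmh = map(flat, (left, right, wm, wmh))
    fl_bundle = fl_left | fl_right

    bundle_eigs = tensor_from_scalars(bundle_fa, bundle_md)
    wm_eigs = tensor_from_scalars(wm_fa, wm_md)

    tensors = np.empty((n_vox, 3, 3))
    fractions = np.empty(n_vox)
    # non-WM in-brain voxels behave like free water (CSF-ish rim)
    tensors[:] = (D_ISO / 3.0) * np.eye(3)
    fractions[:] = 0.95
    tensors[fl_wm] = _axially_symmetric_tensor(wm_eigs, rng.standard_normal(3))
    fractions[fl_wm] = fw_wm
    tensors[fl_bundle] = _axially_symmetric_tensor(bundle_eigs, np.array([0.0, 1.0, 0.0]))
    fractions[fl_bundle] = fw_bundle
    fractions[fl_wmh] = np.clip(fractions[fl_wmh] + fw_wmh_boost, 0.0, 0.95)
    s0 = np.full(n_vox, 1000.0)

    signal = np.empty((n_vox, scheme.n_volumes))
    child = rng.spawn(n_vox) if snr is not None else [None] * n_vox
    for v in range(n_vox):
        vm = VoxelModel(tensors[v], float(fractions[v]), float(s0[v]))
        signal[v] = simulate_bitensor_signal(vm, scheme, snr=snr, seed=child[v] or 0)

    return PhantomVolume(
        signal=signal,
        grid_shape=grid_shape,
        voxel_size=voxel_size,
        scheme=scheme,
        left_mask=left,
        right_mask=right,
        wm_mask=wm,
        wmh_mask=wmh,
        icv_mask=icv,
        true_tensors=tensors,
        true_fractions=fractions,
        true_s0=s0,
    )


# ---------------------------------------------------------------------------
# longitudinal verbal-fluency trajectories
# ---------------------------------------------------------------------------


def simulate_longitudinal_scores(
    n_subjects: int,
    visit_times: tuple = DEFAULT_VISIT_TIMES,
    mean_intercept: float = 30.0,
    mean_slope: float = -0.489,
    sd_intercept: float = 2.0,
    sd_slope: float = 0.15,
    resid_sd: float = 1.0,
    covariate: np.ndarray | None = None,
    covariate_link: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Linear verbal-fluency trajectories with random intercepts and slopes.

    Each subject's 15-second count follows
    score(t) = (mu0 + b0_i) + (mu1 + b1_i + gamma * cov_i) * t + eps,
    with b0_i ~ N(0, sd_intercept^2), b1_i ~ N(0, sd_slope^2) and
    eps ~ N(0, resid_sd^2). The 30 s and 60 s counts are built as the 15 s
    count plus nonnegative increments (one fluency trial accumulates words),
    so ist15 <= ist30 <= ist60 at every visit by construction.

    Returns a long-format DataFrame (subject, time_years, ist15, ist30,
    ist60) with the planted truth in columns ``true_intercept`` and
    ``true_slope`` (the 15 s trajectory's).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    times = np.asarray(visit_times, dtype=float)
    if times.size < 3 or np.any(np.diff(times) <= 0):
        raise ValueError("need >= 3 strictly increasing visit times")
    if min(sd_intercept, sd_slope, resid_sd) < 0:
        raise ValueError("variance components must be nonnegative")
    if covariate is not None and len(covariate) != n_subjects:
        raise ValueError("covariate must have one value per subject")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = np.zeros(n_subjects) if covariate is None else np.asarray(covariate, dtype=float)

    b0 = sd_intercept * rng.standard_normal(n_subjects)
    b1 = sd_slope * rng.standard_normal(n_subjects)
    true_int = mean_intercept + b0
    true_slope = mean_slope + b1 + covariate_link * cov

    rows = []
    for i in range(n_subjects):
        eps = resid_sd * rng.standard_normal(times.size)
        ist15 = true_int[i] + true_slope[i] * times + eps
        # cumulative increments: ~ doubling by 30 s, tripling by 60 s
        inc30 = np.abs(0.5 * true_int[i] + resid_sd * rng.standard_normal(times.size))
        inc60 = np.abs(0.5 * true_int[i] + resid_sd * rng.standard_normal(times.size))
        for j, t in enumerate(times):
            rows.append(
                {
                    "subject": i,
                    "time_years": t,
                    "ist15": ist15[j],
                    "ist30": ist15[j] + inc30[j],
                    "ist60": ist15[j] + inc30[j] + inc60[j],
                    "true_intercept": true_int[i],
                    "true_slope": true_slope[i],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# screening / exclusions
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ScreeningRecord:
    """One screened subject: staged exclusion flags plus covariates."""

    subject: int
    flags: dict
    age: float = 81.2
    sex: str = "F"
    education_high: bool = False
    mmse: float = 27.0
    cesd: float = 8.0
    bmi: float = 25.0
    diabetes: bool = False
    hypertension: bool = False

    def __post_init__(self):
        unknown = set(self.flags) - set(EXCLUSION_STAGES)
        if unknown:
            raise ValueError(f"unknown exclusion flags: {sorted(unknown)}")
        if not 0 <= self.mmse <= 30:
            raise ValueError("MMSE must lie in [0, 30]")
        self.flags = {s: bool(self.flags.get(s, False)) for s in EXCLUSION_STAGES}


def make_screening_records(
    stage_counts: dict | None = None, n_screened: int = 239, seed: int = 0
) -> list[ScreeningRecord]:
    """Screening cohort with planted per-stage attrition.

    Default stage counts reproduce a 239 -> 68 screening funnel: dementia 8,
    brain pathology 27, MRI unavailable 62, MRI artefacts 24, preprocessing
    failure 15, cingulum reconstruction failure 16, tractography QC 19.
    """
    if stage_counts is None:
        stage_counts = dict(
            zip(EXCLUSION_STAGES, (8, 27, 62, 24, 15, 16, 19))
        )
    if sum(stage_counts.values()) > n_screened:
        raise ValueError("stage counts exceed the screened cohort size")
    rng = np.random.default_rng(seed)
    records = []
    pool = list(rng.permutation(n_screened))
    assigned = {}
    for stage in EXCLUSION_STAGES:
        k = int(stage_counts.get(stage, 0))
        for sid in pool[:k]:
            assigned[sid] = stage
        pool = pool[k:]
    for sid in range(n_screened):
        flags = {assigned[sid]: True} if sid in assigned else {}
        records.append(
            ScreeningRecord(
                subject=sid,
                flags=flags,
                age=float(rng.normal(81.2, 4.0)),
                sex="M" if rng.random() < 0.368 else "F",
                education_high=bool(rng.random() < 0.37),
                mmse=float(np.clip(rng.normal(27.3, 2.0), 24, 30)),
                cesd=float(max(0.0, rng.normal(8.3, 5.0))),
                bmi=float(rng.normal(25.2, 3.5)),
                diabetes=bool(rng.random() < 0.103),
                hypertension=bool(rng.random() < 0.353),
            )
        )
    return records


def apply_exclusions(
    records: list[ScreeningRecord], stage_order: tuple = EXCLUSION_STAGES
) -> tuple[list[ScreeningRecord], dict]:
    """Sequential screening: each subject is attributed to the first stage
    whose flag excludes them; later flags never double-count.

    Returns (included records, per-stage attrition counts).
    """
    if set(stage_order) != set(EXCLUSION_STAGES):
        missing = set(EXCLUSION_STAGES) - set(stage_order)
        extra = set(stage_order) - set(EXCLUSION_STAGES)
        raise ValueError(f"stage order mismatch: missing {sorted(missing)}, unknown {sorted(extra)}")
    counts = {s: 0 for s in stage_order}
    included = []
    for rec in records:
        for stage in stage_order:
            if rec.flags[stage]:
                counts[stage] += 1
                break
        else:
            included.append(rec)
    return included, counts


# ---------------------------------------------------------------------------
# cohort-level tables for the association layer
# ---------------------------------------------------------------------------

COHORT_MEASURES = ("fa", "md", "rd", "ad", "fat", "mdt", "rdt", "adt", "fw")

_MEASURE_MEANS = {
    "fa": (0.543, 0.049),
    "md": (0.768, 0.041),
    "rd": (0.506, 0.047),
    "ad": (1.29, 0.0683),
    "fat": (0.567, 0.054),
    "mdt": (0.755, 0.034),
    "rdt": (0.493, 0.049),
    "adt": (1.27, 0.0638),
    "fw": (0.141, 0.017),
}


def make_cohort_table(
    n_subjects: int = 68,
    effect_measure: str | None = None,
    effect_beta: float = 0.0,
    seed: int = 0,
    slope_noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-subject analysis table: bilateral tract measures, covariates and
    IST slopes, with an optional planted standardized diffusion-slope effect.

    Diffusivity columns are in 1e-3 mm^2/s. Measures share a latent
    "tissue state" factor so they are realistically correlated. When
    ``effect_measure`` is given, the slope outcome is built so its
    standardized regression coefficient on that measure equals
    ``effect_beta`` in expectation; all other measures pick up association
    only through their correlation with it. ``effect_beta = 0`` (default) is
    the null cohort.
    """
    if effect_measure is not None and effect_measure not in COHORT_MEASURES:
        raise ValueError(f"unknown measure {effect_measure!r}")
    if abs(effect_beta) >= 1:
        raise ValueError("|effect_beta| must be < 1 for a standardized outcome")
    rng = np.random.default_rng(seed)

    latent = rng.standard_normal(n_subjects)  # shared tissue-state factor
    z = {}
    for m in COHORT_MEASURES:
        unique = rng.standard_normal(n_subjects)
        zm = np.sqrt(0.5) * latent + np.sqrt(0.5) * unique
        sign = 1.0 if m in ("fa", "fat") else -1.0  # anisotropy moves opposite
        z[m] = sign * zm

    df = pd.DataFrame({"subject": np.arange(n_subjects)})
    for m in COHORT_MEASURES:
        mu, sd = _MEASURE_MEANS[m]
        df[m] = mu + sd * z[m]
    df["fw"] = df["fw"].clip(0.0, 1.0)

    df["age"] = rng.normal(81.2, 4.0, n_subjects)
    df["cingulum_volume_pct_tiv"] = rng.normal(0.46, 0.06, n_subjects).clip(0.05)
    df["total_wmh_log"] = rng.normal(np.log(15.9 / 450.0), 0.8, n_subjects)
    df["cingulum_wmh_pct"] = np.abs(rng.normal(3.2, 2.0, n_subjects))

    for score, mu_s in (("ist15", -0.489), ("ist30", -0.697), ("ist60", -0.924)):
        noise = rng.standard_normal(n_subjects)
        if effect_measure is None or effect_beta == 0.0:
            zslope = noise
        else:
            zx = (df[effect_measure] - df[effect_measure].mean()) / df[effect_measure].std()
            zslope = effect_beta * zx.to_numpy() + np.sqrt(1 - effect_beta**2) * noise
        df[f"slope_{score}"] = mu_s + 0.15 * slope_noise_sd * zslope
    return df
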