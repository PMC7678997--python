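import numpy as np
import pytest

from fwtract.freewater import D_ISO
from fwtract.synthetic import (
    EXCLUSION_STAGES,
    ScreeningRecord,
    VoxelModel,
    apply_exclusions,
    make_phantom,
    make_screening_records,
    simulate_bitensor_signal,
    simulate_longitudinal_scores,
    tensor_from_scalars,
)
from fwtract.tensor import tensor_scalars

from .conftest import random_spd_tensor


class TestBitensorSignal:
    def test_zero_fraction_is_pure_tensor_attenuation(self, scheme, rng):
        D = random_spd_tensor(rng)
        sig = simulate_bitensor_signal(VoxelModel(D, 0.0, 500.0), scheme)
        q = np.einsum("vi,ij,vj->v", scheme.bvecs, D, scheme.bvecs)
        assert np.allclose(sig, 500.0 * np.exp(-scheme.bvals * q), rtol=1e-14)

    def test_unit_fraction_hits_isotropic_floor(self, scheme, rng):
        """f=1 at b=1000: every DW volume equals S0*exp(-3)."""
        sig = simulate_bitensor_signal(VoxelModel(random_spd_tensor(rng), 1.0, 200.0), scheme)
        expected = 200.0 * np.exp(-1000.0 * D_ISO)
        assert np.allclose(sig[scheme.dw_mask], expected, rtol=1e-14)
        assert np.allclose(sig[scheme.b0_mask], 200.0)

    def test_antipodal_symmetry(self, scheme, rng):
        """Noise-free signal is even in g: |S(g) - S(-g)| <= 1e-12 * S0."""
        for _ in range(5):
            model = VoxelModel(random_spd_tensor(rng), rng.uniform(0, 1), 1000.0)
            sig = simulate_bitensor_signal(model, scheme)
            dirs = scheme.bvecs[scheme.dw_mask]
            vals = sig[scheme.dw_mask]
            for i in range(len(dirs)):
                j = np.argmax(dirs @ (-dirs[i]))
                assert abs(vals[i] - vals[j]) <= 1e-12 * model.s0

    def test_rician_noise_floor(self, scheme):
        """As the true signal goes to zero the Rician mean approaches
        sigma * sqrt(pi/2)."""
        model = VoxelModel(np.eye(3) * 2.9e-3, 1.0, 1.0)
        reps = np.array(
            [
                simulate_bitensor_signal(model, scheme, snr=1e-4, seed=k)[scheme.dw_mask]
                for k in range(120)
            ]
        )  # sigma = 1e4 dwarfs the signal -> pure noise, ~1e4 draws
        sigma = 1.0 / 1e-4
        assert reps.size >= 10_000
        assert abs(reps.mean() / (sigma * np.sqrt(np.pi / 2)) - 1) < 0.05
        assert (reps >= 0).all()

    def test_noise_reproducible_under_seed(self, scheme, rng):
        model = VoxelModel(random_spd_tensor(rng), 0.2, 800.0)
        a = simulate_bitensor_signal(model, scheme, snr=20, seed=42)
        b = simulate_bitensor_signal(model, scheme, snr=20, seed=42)
        assert np.array_equal(a, b)

    def test_invalid_snr_rejected(self, scheme, rng):
        with pytest.raises(ValueError, match="snr"):
            simulate_bitensor_signal(VoxelModel(np.eye(3) * 1e-3, 0.1), scheme, snr=-3)


class TestTensorFromScalars:
    def test_isotropic_case(self):
        assert np.allclose(tensor_from_scalars(0.0, 1e-3), [1e-3, 1e-3, 1e-3])

    @pytest.mark.parametrize("fa,md", [(0.567, 0.755e-3), (0.3, 1e-3), (0.85, 0.6e-3)])
    def test_round_trip_through_scalar_formulas(self, fa, md):
        """Recomputing FA/MD from the constructed eigenvalues returns the
        inputs to 1e-10."""
        lam = tensor_from_scalars(fa, md)
        assert lam[0] >= lam[1] == lam[2] >= 0
        sc = tensor_scalars(lam)
        assert abs(sc["fa"] - fa) < 1e-10
        assert abs(sc["md"] - md) < 1e-10

    def test_stick_limit(self):
        """fa -> 1 at fixed MD: radial eigenvalue -> 0+, axial -> 3 MD."""
        lam = tensor_from_scalars(0.99, 1e-3)
        assert 0 < lam[1] < 3e-5
        assert abs(lam[0] - 3e-3) < 1e-4

    def test_infeasible_inputs_rejected(self):
        with pytest.raises(ValueError):
            tensor_from_scalars(1.0, 1e-3)
        with pytest.raises(ValueError):
            tensor_from_scalars(0.5, -1e-3)


class TestPhantom:
    def test_mask_nesting_and_zero_overlap(self, small_scheme):
        ph = make_phantom(grid_shape=(16, 16, 12), wmh_overlap_fraction=0.0, scheme=small_scheme)
        bundle = ph.left_mask | ph.right_mask
        assert (bundle <= ph.wm_mask).all()
        assert (ph.wm_mask <= ph.icv_mask).all()
        assert (ph.wmh_mask <= ph.wm_mask).all()
        assert int((bundle & ph.wmh_mask).sum()) == 0

    def test_requested_overlap_fraction(self, small_scheme):
        """Intersection voxel count matches the request within one voxel,
        verified by direct voxel counting."""
        ph = make_phantom(grid_shape=(24, 24, 16), wmh_overlap_fraction=0.25, scheme=small_scheme)
        bundle = ph.left_mask | ph.right_mask
        n_bundle = int(bundle.sum())
        n_inter = int(np.logical_and(bundle, ph.wmh_mask).sum())
        assert abs(n_inter - 0.25 * n_bundle) <= 1

    def test_determinism(self, small_scheme):
        a = make_phantom(grid_shape=(16, 16, 12), snr=15, scheme=small_scheme, seed=9)
        b = make_phantom(grid_shape=(16, 16, 12), snr=15, scheme=small_scheme, seed=9)
        assert np.array_equal(a.signal, b.signal)
        assert np.array_equal(a.wmh_mask, b.wmh_mask)

    def test_parameter_validation(self, small_scheme):
        with pytest.raises(ValueError, match="overlap"):
            make_phantom(wmh_overlap_fraction=1.5, scheme=small_scheme)
        with pytest.raises(ValueError, match="64"):
            make_phantom(grid_shape=(128, 16, 16), scheme=small_scheme)


class TestLongitudinalScores:
    def test_deterministic_lines_recover_mean_slope(self):
        """With no random slope, no residual and no covariate link, every
        subject's OLS slope equals the population slope exactly."""
        df = simulate_longitudinal_scores(12, sd_slope=0.0, resid_sd=0.0, mean_slope=-0.489, seed=0)
        for _, g in df.groupby("subject"):
            slope = np.polyfit(g["time_years"], g["ist15"], 1)[0]
            assert abs(slope - (-0.489)) < 1e-12

    def test_scores_nested_at_every_visit(self):
        df = simulate_longitudinal_scores(40, seed=3)
        assert (df["ist15"] <= df["ist30"]).all()
        assert (df["ist30"] <= df["ist60"]).all()

    def test_mean_ols_slope_matches_population_slope(self):
        """Two-stage OLS oracle: the mean per-subject slope sits within
        3 standard errors of the planted population slope at n=2000."""
        df = simulate_longitudinal_scores(2000, resid_sd=1.0, mean_slope=-0.489, seed=11)
        slopes = df.groupby("subject").apply(
            lambda g: np.polyfit(g["time_years"], g["ist15"], 1)[0], include_groups=False
        )
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - (-0.489)) < 3 * se

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_longitudinal_scores(1)
        with pytest.raises(ValueError, match="variance"):
            simulate_longitudinal_scores(5, sd_slope=-1.0)
        with pytest.raises(ValueError, match="increasing"):
            simulate_longitudinal_scores(5, visit_times=(0.0, 2.0, 1.0))


class TestExclusions:
    def test_default_funnel_reaches_68(self):
        """239 screened, staged exclusions 8/27/62/24/15/16/19 -> 68 kept."""
        records = make_screening_records(seed=4)
        included, counts = apply_exclusions(records)
        assert len(included) == 68
        assert list(counts.values()) == [8, 27, 62, 24, 15, 16, 19]

    def test_no_flags_keeps_everyone(self):
        records = [ScreeningRecord(subject=i, flags={}) for i in range(10)]
        included, counts = apply_exclusions(records)
        assert len(included) == 10
        assert all(c == 0 for c in counts.values())

    def test_double_flag_counted_at_first_stage_only(self):
        rec = ScreeningRecord(
            subject=0,
            flags={"brain_pathology": True, "preprocessing_failure": True},
        )
        _, counts = apply_exclusions([rec])
        assert counts["brain_pathology"] == 1
        assert counts["preprocessing_failure"] == 0

    def test_attrition_conservation(self):
        """Included + per-stage exclusions account for every screened subject."""
        records = make_screening_records(seed=8)
        included, counts = apply_exclusions(records)
        assert len(included) + sum(counts.values()) == len(records)

    def test_unknown_flag_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ScreeningRecord(subject=0, flags={"bad_flag": True})
        recs = make_screening_records(seed=0)
        with pytest.raises(ValueError, match="stage order"):
            apply_exclusions(recs, stage_order=EXCLUSION_STAGES[:-1])
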