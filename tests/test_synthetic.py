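"""Generators: planted truth, seed determinism, statistical structure."""

import numpy as np
import pandas as pd
import pytest

import endowm as e
from endowm.synthetic import GeometryError


class TestPhantom:
    def test_no_lesions_truth_volume_zero(self):
        ph = e.generate_phantom(e.PhantomSpec(seed=0))
        assert ph.truth_lesion_volume_mm3 == 0.0
        assert not ph.truth_lesion_mask.any()

    def test_sphere_voxel_count_matches_brute_force(self):
        """Planted r=5 sphere at 1mm isotropic: truth voxel count equals a
        brute-force enumeration of voxels with ||x - c|| <= r."""
        center, radius = (28, 30, 34), 5.0
        ph = e.generate_phantom(e.PhantomSpec(
            lesions=(e.LesionSpec(center, radius, 160.0, 8.0),), seed=1))
        brute = 0
        for i in range(center[0] - 6, center[0] + 7):
            for j in range(center[1] - 6, center[1] + 7):
                for k in range(center[2] - 6, center[2] + 7):
                    if (i - center[0]) ** 2 + (j - center[1]) ** 2 + (k - center[2]) ** 2 <= radius ** 2:
                        brute += 1
        assert ph.truth_lesion_mask.sum() == brute
        # planted-truth conservation: count x voxel volume = reported mm3
        assert ph.truth_lesion_volume_mm3 == brute * 1.0

    def test_seed_determinism_bit_identical(self):
        spec = e.PhantomSpec(secondary_weight=0.1, seed=9)
        a, b = e.generate_phantom(spec), e.generate_phantom(spec)
        assert np.array_equal(a.volume, b.volume)
        assert np.array_equal(a.wm_mask, b.wm_mask)

    def test_lesion_outside_wm_rejected(self):
        with pytest.raises(GeometryError):
            e.generate_phantom(e.PhantomSpec(
                lesions=(e.LesionSpec((2, 2, 2), 3.0, 160.0, 8.0),), seed=0))

    def test_mixture_moments_match_spec(self, mixture_phantom):
        """Empirical mean/SD of non-lesion WM voxels match the mixture
        moments within 3 standard errors."""
        spec = mixture_phantom.spec
        vals = mixture_phantom.volume[mixture_phantom.wm_mask]
        w2 = spec.secondary_weight
        m = (1 - w2) * spec.dominant.mu + w2 * spec.secondary.mu
        ev2 = (1 - w2) * (spec.dominant.sigma ** 2 + spec.dominant.mu ** 2) + \
            w2 * (spec.secondary.sigma ** 2 + spec.secondary.mu ** 2)
        sd = np.sqrt(ev2 - m ** 2)
        n = vals.size
        assert abs(vals.mean() - m) < 3 * sd / np.sqrt(n)
        # SE of the SD of a (non-Gaussian) mixture: use 3x the Gaussian
        # approximation with margin
        assert abs(vals.std() - sd) < 6 * sd / np.sqrt(2 * n)

    def test_nonbrain_zero_frontal_subset(self, mixture_phantom):
        assert np.all(mixture_phantom.volume[~mixture_phantom.brain_mask] == 0)
        assert not np.any(mixture_phantom.frontal_mask & ~mixture_phantom.wm_mask)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            e.PhantomSpec(secondary_weight=0.6)
        with pytest.raises(ValueError):
            e.PhantomSpec(wm_shape=(40.0, 40.0, 40.0))  # not nested
        with pytest.raises(ValueError):
            e.GaussianComponent(100.0, -1.0)


class TestPat:
    def test_identity_ratio_envelopes_equal(self):
        sig = e.generate_pat(e.PatSpec(hyperemia_ratio=1.0, noise_sd=0.0))
        pre = sig.samples[slice(*sig.phases["baseline"])]
        post = sig.samples[slice(*sig.phases["post"])]
        assert np.isclose(np.abs(pre).max(), np.abs(post).max())

    def test_ratio_two_envelope_maxima(self):
        sig = e.generate_pat(e.PatSpec(hyperemia_ratio=2.0, noise_sd=0.0))
        pre = sig.samples[slice(*sig.phases["baseline"])]
        post = sig.samples[slice(*sig.phases["post"])]
        assert np.isclose(post.max() / pre.max(), 2.0)

    def test_seed_determinism(self):
        spec = e.PatSpec(noise_sd=0.05, seed=3)
        assert np.array_equal(e.generate_pat(spec).samples, e.generate_pat(spec).samples)

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            e.PatSpec(sample_rate=0.0)
        with pytest.raises(ValueError):
            e.PatSpec(occlusion_residual=0.5)

    def test_csv_round_trip(self, tmp_path):
        sig = e.generate_pat(e.PatSpec(noise_sd=0.02, seed=1))
        p = tmp_path / "pat.csv"
        sig.to_frame().to_csv(p, index=False)
        back = e.PatSignal.from_frame(pd.read_csv(p))
        assert back.phases == sig.phases
        assert np.allclose(back.samples, sig.samples)
        assert np.isclose(back.sample_rate, sig.sample_rate)


def _targets():
    return (
        e.TargetSpec("SFG", 9000, 60.0),
        e.TargetSpec("FP", 6000, 45.0),
        e.TargetSpec("PrM", 7000, 35.0),
    )


class TestConnectivity:
    def test_noise_free_winner_strictly_exceeds(self):
        spec = e.ConnectivitySpec(targets=_targets(),
                                  assignment_truth=("SFG", "FP", "PrM", "SFG"), seed=0)
        conn = e.generate_connectivity(spec)
        arr = conn.counts.to_numpy()
        for i, name in enumerate(spec.assignment_truth):
            j = list(conn.counts.columns).index(name)
            others = np.delete(arr[i], j)
            assert arr[i, j] > others.max()

    def test_single_live_target_wins_everywhere(self):
        targets = (e.TargetSpec("A", 100, 0.0), e.TargetSpec("B", 100, 50.0))
        spec = e.ConnectivitySpec(targets=targets, assignment_truth=("B",) * 10,
                                  stochastic=True, background_rate=0.0, seed=2)
        conn = e.generate_connectivity(spec)
        seg = e.hard_segment(conn)
        assert (seg.assignment == "B").all()

    def test_stochastic_recovery_rate(self):
        """Large mean separation: hard segmentation recovers the planted
        assignment for >= 99% of 1000 voxels."""
        rng = np.random.default_rng(0)
        truth = tuple(rng.choice(["SFG", "FP", "PrM"], size=1000))
        spec = e.ConnectivitySpec(targets=_targets(), assignment_truth=truth,
                                  stochastic=True, background_rate=2.0, seed=5)
        conn = e.generate_connectivity(spec)
        seg = e.hard_segment(conn)
        rate = (seg.assignment.to_numpy() == np.asarray(truth, dtype=object)).mean()
        assert rate >= 0.99

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            e.ConnectivitySpec(targets=_targets(), assignment_truth=("nope",))
        with pytest.raises(ValueError):
            e.TargetSpec("X", 0, 10.0)

    def test_long_frame_round_trip(self):
        spec = e.ConnectivitySpec(targets=_targets(),
                                  assignment_truth=("SFG", "FP"), seed=0)
        conn = e.generate_connectivity(spec)
        back = e.SeedConnectivity.from_frames(conn.to_long_frame(), conn.targets_frame())
        assert np.array_equal(back.counts.to_numpy(),
                              conn.counts[back.counts.columns].to_numpy())
        assert back.target_sizes == conn.target_sizes


class TestCohort:
    def test_zero_latent_correlation_large_n(self):
        """Independent latents: sample r within sampling error ~ 1/sqrt(n)."""
        df = e.generate_cohort(e.CohortSpec(n=10000, latent_corr=np.eye(3), seed=0))
        tmt_diff = df["tmt_b_s"] - df["tmt_a_s"]
        assert abs(np.corrcoef(df["rhi"], tmt_diff)[0, 1]) < 0.03
        assert abs(np.corrcoef(df["rhi"], df["cluster_fa"])[0, 1]) < 0.03

    def test_default_cohort_shape(self, cohort36):
        assert len(cohort36) == 36
        assert not cohort36.isna().any().any()
        assert set(cohort36["sex"]) <= {"F", "M"}
        assert ((cohort36["cluster_fa"] > 0) & (cohort36["cluster_fa"] < 1)).all()
        assert (cohort36[["tmt_a_s", "tmt_b_s"]] > 0).all().all()

    def test_latent_correlation_recovered_at_large_n(self):
        C = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        df = e.generate_cohort(e.CohortSpec(n=20000, latent_corr=C, seed=1))
        r = np.corrcoef(df["rhi"], df["cluster_fa"])[0, 1]
        assert abs(r - 0.5) < 0.03

    def test_non_pd_covariance_rejected(self):
        C = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            e.CohortSpec(latent_corr=C)

    def test_seed_determinism(self):
        spec = e.CohortSpec(n=12, seed=4)
        pd.testing.assert_frame_equal(e.generate_cohort(spec), e.generate_cohort(spec))
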