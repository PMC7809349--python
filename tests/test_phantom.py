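"""Phantom generator: ROI statistics, determinism, forward simulations."""

import numpy as np
import pytest

from mwimap.epg import EchoTrainSpec
from mwimap.phantom import (CohortSpec, LesionSpec, make_cohort, make_phantom,
                            simulate_grase, simulate_mcdespot)
from mwimap.ssmodels import PoolModel, bssfp_signal, irspgr_signal, spgr_signal


def uniform_truth(f=0.0, t2_free=80.0, kappa=1.0, dims=(2, 2, 1)):
    """Minimal hand-built subject for voxel-level simulator checks."""
    from mwimap.phantom import PhantomTruth

    ones = np.ones(dims)
    return PhantomTruth(
        kind="brain",
        labels=np.full(dims, 5, dtype=np.int16),
        f_m_true=f * ones,
        t1_myelin=450.0 * ones, t2_myelin=20.0 * ones,
        t1_free=1000.0 * ones, t2_free=t2_free * ones,
        tau_myelin=150.0 * ones,
        t1_single=1000.0 * ones,
        m0=ones.copy(), kappa=kappa * ones, delta_f=np.zeros(dims),
    )


class TestMakePhantom:
    def test_brain_roi_means_seeded_from_normative_table(self, brain_truth):
        t = brain_truth
        assert t.f_m_true[t.roi_mask("genu")].mean() == pytest.approx(0.091, abs=0.003)
        assert t.f_m_true[t.roi_mask("splenium")].mean() == pytest.approx(0.134, abs=0.003)
        assert t.f_m_true[t.roi_mask("cortical_gm")].mean() == pytest.approx(0.037, abs=0.003)

    def test_brain_wm_ordering(self, brain_truth):
        t = brain_truth
        genu = t.f_m_true[t.roi_mask("genu")].mean()
        splenium = t.f_m_true[t.roi_mask("splenium")].mean()
        pic = t.f_m_true[t.roi_mask("posterior_internal_capsule")].mean()
        assert genu < splenium < pic

    def test_cord_whole_mean(self, cord_truth):
        m = cord_truth.roi_mask("whole_cord")
        assert cord_truth.f_m_true[m].mean() == pytest.approx(0.221, abs=0.02)

    def test_minimum_roi_count(self, brain_truth, cord_truth):
        assert len(np.unique(brain_truth.labels[brain_truth.labels > 0])) >= 4
        assert len(np.unique(cord_truth.labels[cord_truth.labels > 0])) >= 4

    def test_kappa_field_range_and_smoothness(self, brain_truth):
        k = brain_truth.kappa
        assert np.all((k >= 0.8) & (k <= 1.2))
        assert np.abs(np.diff(k, axis=0)).max() < 0.05  # smooth

    def test_deterministic_for_fixed_seed(self):
        a, _ = make_phantom("brain", (16, 16, 16), seed=42)
        b, _ = make_phantom("brain", (16, 16, 16), seed=42)
        for name in ("f_m_true", "kappa", "delta_f", "m0"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_rejects_unknown_kind_and_small_dims(self):
        with pytest.raises(ValueError):
            make_phantom("liver", (16, 16, 16))
        with pytest.raises(ValueError):
            make_phantom("brain", (8, 8, 8))
        with pytest.raises(ValueError):
            make_phantom("cord", (16, 16, 4))


class TestSimulateGrase:
    def test_single_pool_voxel_is_monoexponential(self):
        spec = EchoTrainSpec(10.0, 10.0, 32, 1501.0)
        truth = uniform_truth(f=0.0, t2_free=80.0, kappa=1.0)
        ds = simulate_grase(truth, spec, snr=np.inf)
        expected = np.exp(-spec.echo_times / 80.0)
        assert np.allclose(ds.echoes[0, 0, 0], expected, atol=1e-12)

    def test_two_pool_voxel_decays_monotonically(self):
        spec = EchoTrainSpec(10.0, 10.0, 32, 1501.0)
        truth = uniform_truth(f=0.2, kappa=0.95)
        ds = simulate_grase(truth, spec, snr=np.inf)
        sig = ds.echoes[0, 0, 0]
        assert np.all(np.diff(sig) < 0)

    def test_kappa_above_one_folds_onto_valid_refocusing_angle(self):
        spec = EchoTrainSpec(10.0, 10.0, 32, 1501.0)
        hi = simulate_grase(uniform_truth(f=0.2, kappa=1.1), spec, snr=np.inf)
        lo = simulate_grase(uniform_truth(f=0.2, kappa=0.9), spec, snr=np.inf)
        assert np.allclose(hi.echoes, lo.echoes, atol=1e-12)

    def test_noise_mean_matches_rician_moment(self, rng):
        spec = EchoTrainSpec(10.0, 10.0, 32, 1501.0)
        truth = uniform_truth(f=0.2, dims=(2, 2, 1))
        clean = simulate_grase(truth, spec, snr=np.inf).echoes[0, 0, 0, 0]
        draws = np.array([
            simulate_grase(truth, spec, snr=100, seed=s).echoes[0, 0, 0, 0]
            for s in range(1000)
        ])
        sigma = clean / 100.0  # WM-uniform phantom: reference = this voxel
        # large-b asymptotic of the Rician mean, nu + sigma^2/(2 nu)
        # (scipy's rice.mean overflows at b = nu/sigma = 100)
        expected = clean + sigma**2 / (2.0 * clean)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se

    def test_seed_reproducibility(self):
        spec = EchoTrainSpec(10.0, 10.0, 32, 1501.0)
        truth = uniform_truth(f=0.2)
        a = simulate_grase(truth, spec, snr=50, seed=7).echoes
        b = simulate_grase(truth, spec, snr=50, seed=7).echoes
        assert np.array_equal(a, b)


class TestSimulateMcdespot:
    def test_noiseless_voxel_matches_forward_models(self, brain_protocol):
        truth = uniform_truth(f=0.2, kappa=0.93)
        truth.delta_f[:] = 11.0
        ds = simulate_mcdespot(truth, brain_protocol, snr=np.inf)
        pools = PoolModel(f_myelin=0.2, t1_myelin=450, t2_myelin=20,
                          t1_free=1000, t2_free=80, tau_myelin=150,
                          delta_f=11.0, m0=1.0)
        spgr = spgr_signal(pools, brain_protocol.spgr_tr,
                           brain_protocol.spgr_fas, kappa=0.93)
        assert np.allclose(ds.spgr[0, 0, 0], spgr, atol=1e-12)
        ir = irspgr_signal(pools, brain_protocol.irspgr_tr,
                           brain_protocol.irspgr_ti, brain_protocol.irspgr_fa,
                           kappa=0.93)
        assert ds.irspgr[0, 0, 0] == pytest.approx(ir, abs=1e-12)
        for pc in brain_protocol.phase_cycles:
            b = bssfp_signal(pools, brain_protocol.bssfp_tr,
                             brain_protocol.bssfp_fas, pc, kappa=0.93,
                             te=brain_protocol.bssfp_te)
            assert np.allclose(ds.bssfp[pc][0, 0, 0], b, atol=1e-12)

    def test_spgr_vanishes_at_zero_flip_angle(self, brain_protocol):
        from dataclasses import replace

        prot = replace(brain_protocol, spgr_fas=(1e-9, 3.0))
        truth = uniform_truth(f=0.0)
        ds = simulate_mcdespot(truth, prot, snr=np.inf)
        assert ds.spgr[0, 0, 0, 0] < 1e-9

    def test_phase_cycles_differ(self, brain_protocol):
        truth = uniform_truth(f=0.0)
        truth.delta_f[:] = 25.0
        ds = simulate_mcdespot(truth, brain_protocol, snr=np.inf)
        assert not np.allclose(ds.bssfp[0.0], ds.bssfp[180.0])

    def test_seed_reproducibility(self, brain_protocol):
        truth = uniform_truth(f=0.2)
        a = simulate_mcdespot(truth, brain_protocol, snr=60, seed=3)
        b = simulate_mcdespot(truth, brain_protocol, snr=60, seed=3)
        assert np.array_equal(a.spgr, b.spgr)
        assert np.array_equal(a.bssfp[0.0], b.bssfp[0.0])


class TestMakeCohort:
    def test_zero_cv_gives_identical_subjects(self):
        cohort = make_cohort("brain", (16, 16, 16),
                             CohortSpec(n_subjects=3, between_subject_cv=0.0,
                                        snr=np.inf, seed=4))
        f0 = cohort[0].truth.f_m_true
        for subj in cohort[1:]:
            assert np.array_equal(subj.truth.f_m_true, f0)
            assert np.array_equal(subj.truth.kappa, cohort[0].truth.kappa)
            assert np.array_equal(subj.grase.echoes, cohort[0].grase.echoes)

    def test_nonzero_cv_varies_subjects(self):
        cohort = make_cohort("brain", (16, 16, 16),
                             CohortSpec(n_subjects=3, between_subject_cv=0.1,
                                        snr=np.inf, seed=4), simulate=())
        assert not np.array_equal(cohort[0].truth.f_m_true,
                                  cohort[1].truth.f_m_true)

    def test_cord_atlas_size_cohort_builds(self):
        # the published cord atlas pooled 23 participants
        cohort = make_cohort("cord", (32, 32, 8),
                             CohortSpec(n_subjects=23, snr=60, seed=0),
                             simulate=())
        assert len(cohort) == 23

    def test_lesion_halves_local_truth(self):
        spec = LesionSpec(n_lesions=2, radius_vox=(2.0, 3.0),
                          f_m_reduction=0.5, t2_free_increase=20.0)
        cohort = make_cohort("brain", (16, 16, 16),
                             CohortSpec(n_subjects=2, between_subject_cv=0.0,
                                        snr=np.inf, seed=4),
                             lesions={1: spec}, simulate=())
        healthy, lesioned = cohort[0].truth, cohort[1].truth
        lm = lesioned.lesion_mask
        assert lm is not None and lm.sum() > 0
        assert np.allclose(lesioned.f_m_true[lm], 0.5 * healthy.f_m_true[lm])
        assert np.allclose(lesioned.t2_free[lm], healthy.t2_free[lm] + 20.0)
        assert healthy.lesion_mask is None
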