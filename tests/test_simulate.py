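"""State-space speaker simulator: limiting cases, closed form, recovery."""

import numpy as np
import pandas as pd
import pytest

import aafadapt as aaf
from aafadapt.simulate import WORD_OFFSETS, recover_learning_rate


def _noiseless(**kw):
    defaults = dict(subject_id="s1", group="NT", sigma_trial=0.0, sigma_within=0.0)
    defaults.update(kw)
    return aaf.SpeakerParams(**defaults)


def _base(params, words):
    offs = np.array([WORD_OFFSETS[w] for w in words])
    return np.column_stack(
        [params.baseline_f1 + offs[:, 0], params.baseline_f2 + offs[:, 1]]
    )


class TestSimulateSpeaker:
    @pytest.mark.parametrize("paradigm", ["gradual", "sudden"])
    def test_inert_speaker_produces_baseline(self, paradigm, shift):
        p = _noiseless(lam=0.0, g=0.0)
        tab = aaf.simulate_speaker(p, aaf.make_schedule(paradigm), shift, seed=0)
        base = _base(p, tab["word"])
        assert np.allclose(tab[["early_f1", "early_f2"]], base)
        assert np.allclose(tab[["late_f1", "late_f2"]], tab[["early_f1", "early_f2"]])

    def test_dominant_threshold_gates_all_errors_off(self, sudden, shift):
        # threshold far above any achievable error: identical to an inert run
        p_gated = _noiseless(lam=0.2, g=0.3, theta=10 * shift.norm)
        p_inert = _noiseless(lam=0.0, g=0.0)
        a = aaf.simulate_speaker(p_gated, sudden, shift, seed=5)
        b = aaf.simulate_speaker(p_inert, sudden, shift, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_state_matches_analytic_geometric_recursion(self, sudden, shift):
        # sudden paradigm, rho=1, theta=0, g=0, no noise: during the
        # full-perturbation block x_t = -delta*(1-(1-lam)^(t-31)); derived
        # by solving x_{t+1} = x_t - lam*(x_t + delta) with x_31 = 0
        lam = 0.25
        p = _noiseless(lam=lam, rho=1.0, g=0.0)
        tab = aaf.simulate_speaker(p, sudden, shift, seed=0)
        base = _base(p, tab["word"])
        x = tab[["early_f1", "early_f2"]].to_numpy() - base
        delta = np.array([shift.df1, shift.df2])
        for t in range(31, 91):
            expect = -delta * (1 - (1 - lam) ** (t - 31))
            assert np.allclose(x[t - 1], expect, atol=1e-9)

    def test_corrective_equals_gated_feedback_response(self, sudden, shift):
        # no noise, g>0: late - early = -g*error on every detected trial,
        # opposing the perturbation (F1 down, F2 up)
        p = _noiseless(lam=0.1, g=0.4)
        tab = aaf.simulate_speaker(p, sudden, shift, seed=0)
        base = _base(p, tab["word"])
        x = tab[["early_f1", "early_f2"]].to_numpy() - base
        pert = np.array(
            [aaf.perturbation_at(sudden, shift, int(t)) for t in tab["trial"]]
        )
        corrective = (
            tab[["late_f1", "late_f2"]].to_numpy()
            - tab[["early_f1", "early_f2"]].to_numpy()
        )
        assert np.allclose(corrective, -p.g * (x + pert), atol=1e-9)
        perturbed = tab["trial"].between(31, 90).to_numpy()
        assert np.all(corrective[perturbed, 0] < 0)
        assert np.all(corrective[perturbed, 1] > 0)

    def test_deterministic_given_seed(self, gradual, shift):
        p = aaf.SpeakerParams("s1", "NT")
        a = aaf.simulate_speaker(p, gradual, shift, seed=11)
        b = aaf.simulate_speaker(p, gradual, shift, seed=11)
        c = aaf.simulate_speaker(p, gradual, shift, seed=12)
        pd.testing.assert_frame_equal(a, b)
        assert not a[["early_f1"]].equals(c[["early_f1"]])

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            aaf.SpeakerParams("s", "NT", lam=1.5)
        with pytest.raises(ValueError):
            aaf.SpeakerParams("s", "NT", sigma_trial=-1)
        with pytest.raises(ValueError):
            aaf.SpeakerParams("s", "NT", baseline_f1=float("nan"))


class TestLearningRateRecovery:
    def test_exact_without_noise(self, sudden, shift):
        p = _noiseless(lam=0.2, g=0.3)
        tab = aaf.simulate_speaker(p, sudden, shift, seed=1)
        assert recover_learning_rate(tab, p, sudden, shift) == pytest.approx(
            0.2, abs=1e-12
        )

    def test_median_error_small_under_noise(self, sudden, shift):
        errors = []
        for s in range(20):
            p = aaf.SpeakerParams("s", "NT", sigma_trial=5.0, sigma_within=0.0)
            tab = aaf.simulate_speaker(p, sudden, shift, seed=200 + s)
            errors.append(abs(recover_learning_rate(tab, p, sudden, shift) - 0.2))
        assert np.median(errors) < 0.05


class TestSimulatePretest:
    def test_zero_noise_hits_targets(self):
        p = _noiseless()
        prods = aaf.simulate_pretest(p, n_reps=5, seed=0)
        assert set(prods) == {"i", "eh", "ae"}
        for vowel, target in aaf.simulate.DEFAULT_VOWEL_TARGETS.items():
            assert np.allclose(prods[vowel], np.tile(target, (5, 1)))

    def test_centroid_recovers_targets_under_noise(self):
        p = aaf.SpeakerParams("s", "NT", sigma_trial=10.0)
        prods = aaf.simulate_pretest(p, n_reps=25, seed=42)
        tol = 3 * 10 / np.sqrt(25)
        for vowel, (f1, f2) in aaf.simulate.DEFAULT_VOWEL_TARGETS.items():
            c = aaf.compute_centroid(prods[vowel], vowel)
            assert abs(c.f1 - f1) < tol and abs(c.f2 - f2) < tol

    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            aaf.simulate_pretest(_noiseless(), n_reps=0, seed=0)


class TestSimulateCohort:
    def test_structure_and_counterbalancing(self, shift):
        nt = aaf.default_nt_spec(shift)
        pwa = aaf.default_pwa_spec(shift)
        tab = aaf.simulate_cohort([nt, pwa], [3, 2], seed=9, shift=shift)
        assert len(tab) == 5 * 2 * 120
        counts = tab.groupby(["subject_id", "paradigm"]).size()
        assert (counts == 120).all()
        # every subject runs both paradigms; order alternates across subjects
        first = tab.groupby("subject_id", sort=False)["paradigm"].first()
        assert list(first[["NT01", "NT02", "NT03"]]) == ["gradual", "sudden", "gradual"]

    def test_degenerate_spec_composes_single_speaker_runs(self, shift):
        # all-degenerate distributions with zero noise: each run equals a
        # direct simulate_speaker call with those exact parameters
        spec = aaf.GroupSpec(
            group="NT",
            dists={"lam": (0.2, 0.0), "g": (0.3, 0.0), "theta": (0.0, 0.0),
                   "sigma_trial": (0.0, 0.0), "sigma_within": (0.0, 0.0)},
        )
        tab = aaf.simulate_cohort([spec], [1], seed=3, shift=shift)
        p = _noiseless(subject_id="NT01", lam=0.2, g=0.3)
        for paradigm in ("gradual", "sudden"):
            run = tab[tab["paradigm"] == paradigm].reset_index(drop=True)
            ref = aaf.simulate_speaker(
                p, aaf.make_schedule(paradigm), shift, seed=0
            )
            # noiseless dynamics do not depend on the run seed; only the
            # word ordering does, so compare per-word joins
            merged = run.merge(
                ref, on=["word", "trial"], suffixes=("", "_ref")
            )
            assert np.allclose(merged["early_f1"], merged["early_f1_ref"])

    def test_nt_cohort_adapts_against_f1_perturbation(self, gradual, shift):
        tab = aaf.simulate_cohort([aaf.default_nt_spec(shift)], [12], seed=21,
                                  shift=shift)
        hold = aaf.hold_average(aaf.baseline_correct(tab), gradual)
        f1 = hold[hold["formant"] == "F1"]
        assert f1["adaptive_mean"].mean() < 0  # opposes the +dF1 shift

    def test_deterministic(self, shift):
        spec = aaf.default_nt_spec(shift)
        a = aaf.simulate_cohort([spec], [2], seed=5, shift=shift)
        b = aaf.simulate_cohort([spec], [2], seed=5, shift=shift)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_n_rejected(self, shift):
        with pytest.raises(ValueError):
            aaf.simulate_cohort([aaf.default_nt_spec(shift)], [0], seed=1)
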