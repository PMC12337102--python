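import numpy as np
import pytest

from specd.mapping import (
    ContributionMap,
    ElectrodeSets,
    ResponsivenessMap,
    SpectralConfig,
    band_power,
    contributions,
    longform_activation,
    multitaper_band_power,
    responsiveness,
    shared_set,
)
from specd.session import NeuralSession, TrialRecord
from specd.simulate import SimConfig, simulate_session


def _noise_session(seed, n_trials=20, n_el=6, task="speech"):
    """Exchangeable null: pure noise with fabricated trial timing."""
    rng = np.random.default_rng(seed)
    spacing = 5.0
    T = int(200 * (n_trials * spacing + 10))
    trials = [
        TrialRecord(task, i % 10, 3.0 + i * spacing, 5.0 + i * spacing, 7.5 + i * spacing,
                    5.1 + i * spacing, 7.0 + i * spacing)
        for i in range(n_trials)
    ]
    return NeuralSession(
        hga=rng.normal(size=(T, n_el)),
        lfs=rng.normal(size=(T, n_el)),
        electrode_regions=["other"] * n_el,
        trials=trials,
    )


class TestResponsiveness:
    def test_type_i_rate_on_exchangeable_null(self):
        fams = 0
        reps = 200
        for i in range(reps):
            rmap = responsiveness(_noise_session(i), "speech")
            fams += rmap.significant.any()
        assert fams / reps <= 0.07  # familywise alpha 0.05 + slack

    def test_designed_electrode_significant(self):
        s = simulate_session(SimConfig(n_electrodes=12, n_trials=100, task="speech", seed=9))
        rmap = responsiveness(s, "speech")
        truth = np.array([p.responsive("speech") for p in s.profiles])
        assert np.all(rmap.significant[truth])
        assert not np.any(rmap.significant[~truth])

    def test_negative_statistic_displayed_as_zero(self):
        s = _noise_session(0)
        s.hga[:, 2] -= 0.0  # keep null; force a negative Z by suppressing post windows
        for t in s.trials:
            a = int(t.go_cue_s * 200)
            s.hga[a : a + 200, 2] -= 1.0
        rmap = responsiveness(s, "speech")
        assert rmap.z_statistic[2] < 0
        assert rmap.display_statistic[2] == 0.0

    def test_adjusted_p_not_below_raw(self):
        rmap = responsiveness(_noise_session(3), "speech")
        assert np.all(rmap.p_adjusted >= rmap.p_raw - 1e-15)

    def test_too_few_trials_errors(self):
        s = _noise_session(1, n_trials=1)
        with pytest.raises(ValueError):
            responsiveness(s, "speech")

    def test_unknown_task_errors(self):
        with pytest.raises(ValueError):
            responsiveness(_noise_session(2), "juggling")


class TestSharedSet:
    def _map(self, sig):
        sig = np.asarray(sig, dtype=bool)
        n = len(sig)
        return ResponsivenessMap("x", np.ones(n), np.ones(n), np.ones(n), sig)

    def test_intersection(self):
        maps = {
            "speech": self._map([1, 1, 0, 1]),
            "reading": self._map([1, 0, 0, 1]),
            "listening": self._map([1, 1, 0, 0]),
        }
        assert shared_set(maps).shared.tolist() == [True, False, False, False]

    def test_empty_when_any_task_empty(self):
        maps = {
            "speech": self._map([1, 1]),
            "reading": self._map([0, 0]),
            "listening": self._map([1, 1]),
        }
        assert not shared_set(maps).shared.any()

    def test_missing_task_errors(self):
        with pytest.raises(ValueError):
            shared_set({"speech": self._map([1])})

    def test_disjointness_validated(self):
        with pytest.raises(ValueError):
            ElectrodeSets(shared=np.array([True, False]), articulatory=np.array([True, True]))

    def test_recovery_on_sim_truth(self):
        maps = {}
        for i, task in enumerate(("speech", "reading", "listening")):
            s = simulate_session(SimConfig(n_electrodes=20, n_trials=67, task=task, seed=5 + i))
            maps[task] = responsiveness(s, task)
        truth = np.array([p.klass == "shared" for p in s.profiles])
        recovered = shared_set(maps).shared
        sens = (recovered & truth).sum() / truth.sum()
        spec = (~recovered & ~truth).sum() / (~truth).sum()
        assert sens >= 0.9
        assert spec >= 0.9


class TestContributions:
    def test_masked_electrode_contributes_zero(self, classifier_session, classifier_split):
        from specd.classify import ClassifierHyper, fit_classifier

        X, y, tr, te = classifier_split
        mask = np.ones(classifier_session.n_electrodes, dtype=bool)
        mask[:3] = False
        ens = fit_classifier(
            X[tr], y[tr], ClassifierHyper(hidden=8, n_members=1, epochs=2, seed=0),
            electrode_mask=mask,
        )
        cm = contributions(ens, X[te], y[te])
        assert np.all(cm.total[:3] == 0.0)
        assert np.all(cm.total[3:] > 0.0)
        assert np.allclose(cm.total, cm.hga + cm.lfs)

    def test_non_differentiable_model_errors(self, classifier_split):
        X, y, _, te = classifier_split

        class _Opaque:
            members = [object()]
            electrode_mask = None

        with pytest.raises(TypeError):
            contributions(_Opaque(), X[te], y[te])

    def test_duplicated_signal_preserves_ranking_of_others(
        self, trained_classifier, classifier_split
    ):
        X, y, _, te = classifier_split
        cm0 = contributions(trained_classifier, X[te], y[te])
        X_dup = X[te].copy()
        e = X.shape[-1] // 2
        X_dup[:, :, e - 1] = X_dup[:, :, 0]  # copy an informative HGA channel into a dead one
        cm1 = contributions(trained_classifier, X_dup, y[te])
        from scipy.stats import spearmanr

        others = np.arange(1, e - 1)
        # ranking of untouched channels barely moves
        rho = spearmanr(cm0.hga[others], cm1.hga[others]).statistic
        assert rho > 0.9


class TestBandPower:
    def test_pure_theta_oscillation(self):
        t = np.arange(400) / 200.0
        x = np.sin(2 * np.pi * 8.0 * t)
        theta = multitaper_band_power(x, (5.0, 12.0))
        beta = multitaper_band_power(x, (20.0, 30.0))
        assert theta > 50 * beta

    def test_band_above_nyquist_errors(self):
        with pytest.raises(ValueError):
            multitaper_band_power(np.zeros(400), (90.0, 120.0))

    def test_matches_periodogram_oracle_on_white_noise(self):
        from scipy.signal import periodogram

        rng = np.random.default_rng(4)
        band = (20.0, 30.0)
        mt, pg = [], []
        for _ in range(40):
            x = rng.normal(size=400)
            mt.append(multitaper_band_power(x, band))
            f, p = periodogram(x, fs=200.0)
            sel = (f >= band[0]) & (f <= band[1])
            pg.append(p[sel].mean())
        assert np.mean(mt) == pytest.approx(np.mean(pg), rel=0.1)

    def test_white_noise_z_scores_centred(self):
        sessions = {
            task: _noise_session(10 + i, n_trials=40, task=task)
            for i, task in enumerate(("speech", "listening"))
        }
        out = band_power(sessions, SpectralConfig(pseudo_block_trials=10))
        for bname in ("theta", "beta"):
            pooled = np.concatenate(list(out[bname].values()))
            assert abs(pooled.mean()) < 1e-9  # z-scored across pooled blocks
            assert pooled.std() == pytest.approx(1.0)

    def test_too_few_trials_errors(self):
        with pytest.raises(ValueError):
            band_power({"speech": _noise_session(1, n_trials=5)}, SpectralConfig())


class TestLongformActivation:
    def test_null_calibration(self):
        # with-replacement sampling of overlapping windows is anticonservative
        # on short autocorrelated sessions; blocks must be long relative to
        # the 4 s window for the rank-sum test to hold its level
        T = 600 * 200
        sig_frac = []
        for i in range(8):
            rng = np.random.default_rng(100 + i)
            a = NeuralSession(rng.normal(size=(T, 5)), np.zeros((T, 5)), ["other"] * 5)
            b = NeuralSession(rng.normal(size=(T, 5)), np.zeros((T, 5)), ["other"] * 5)
            rmap = longform_activation(a, b, n_points=100, seed=i)
            sig_frac.append(rmap.significant.mean())
        assert np.mean(sig_frac) <= 0.05

    def test_designed_auditory_effect(self):
        lf = simulate_session(
            SimConfig(n_electrodes=12, schedule="longform", task="listening", longform_s=400, seed=8)
        )
        bl = simulate_session(SimConfig(n_electrodes=12, schedule="rest", longform_s=400, seed=9))
        rmap = longform_activation(lf, bl, n_points=100, seed=0)
        aud = np.array([p.klass in ("auditory", "shared") for p in lf.profiles])
        assert np.all(rmap.significant[aud])
        silent = np.array([p.klass == "silent" for p in lf.profiles])
        assert np.mean(rmap.significant[silent]) <= 0.25

    def test_single_point_errors(self):
        rng = np.random.default_rng(0)
        s = NeuralSession(rng.normal(size=(2000, 3)), rng.normal(size=(2000, 3)), ["other"] * 3)
        with pytest.raises(ValueError):
            longform_activation(s, s, n_points=1)
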