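import numpy as np
import pytest

from mispeed.montage import SSMRP_CHANNELS
from mispeed.simulate import (
    ConditionSpec,
    NoiseSpec,
    SessionDesign,
    default_conditions,
    generate_session,
    make_schedule,
    synthesize_trial,
)


class TestSchedule:
    def test_study_design_counts(self, study_design):
        events = make_schedule(study_design, seed=0)
        assert len(events) == 105
        labels = [ev.label for ev in events]
        for mi in ("slow", "medium", "fast"):
            assert labels.count(mi) == 30
        assert labels.count("rest") == 15
        per_run = {r: sum(1 for ev in events if ev.run == r) for r in range(3)}
        assert per_run == {0: 35, 1: 35, 2: 35}

    def test_inter_trial_spacing_and_onset(self, study_design):
        events = make_schedule(study_design, seed=1)
        trial_n = int(study_design.trial_s * study_design.fs)
        cue_n = int(study_design.cue_s * study_design.fs)
        onsets = np.array([ev.onset_sample for ev in events])
        assert onsets[0] == cue_n
        assert set(np.diff(onsets)) == {trial_n}

    def test_single_trial_degenerate(self):
        d = SessionDesign(n_runs=1, trials_per_class_per_run={"slow": 1})
        events = make_schedule(d, seed=5)
        assert len(events) == 1
        assert events[0].onset_sample == int(d.cue_s * d.fs)
        assert events[0].label == "slow"

    def test_determinism(self, study_design):
        a = make_schedule(study_design, seed=7)
        b = make_schedule(study_design, seed=7)
        assert a == b

    def test_rejects_misaligned_durations(self):
        with pytest.raises(ValueError, match="sample-aligned"):
            SessionDesign(cue_s=1.0001).validate()

    def test_rejects_low_fs(self):
        with pytest.raises(ValueError, match="fs"):
            SessionDesign(fs=50).validate()


class TestTrialSynthesis:
    def test_pure_tone(self):
        """With all noise off and one harmonic, the MI span is exactly a sinusoid."""
        d = SessionDesign(
            n_runs=1,
            trials_per_class_per_run={"slow": 1},
            cue_s=0.5,
            mi_s=1.0,
            break_s=0.5,
            channel_names=("Cz",),
        )
        cond = ConditionSpec(f0=2.0, harmonic_amps=(1.0,), ssvep_amp=0.0)
        x = synthesize_trial(cond, NoiseSpec(0.0, 0.0, 0.0, 0.0), d, seed=0)[0]
        fs = d.fs
        mi = slice(int(0.5 * fs), int(1.5 * fs))
        t = np.arange(int(1.0 * fs)) / fs
        # least-squares fit of a 2-Hz sinusoid: unit amplitude, zero residual
        basis = np.column_stack([np.sin(2 * np.pi * 2 * t), np.cos(2 * np.pi * 2 * t)])
        coef, *_ = np.linalg.lstsq(basis, x[mi], rcond=None)
        assert np.hypot(*coef) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(basis @ coef, x[mi], atol=1e-9)
        assert np.allclose(x[: mi.start], 0) and np.allclose(x[mi.stop :], 0)

    def test_harmonic_argmax_at_second(self, study_design):
        """Noiseless medium trials have their largest harmonic-bin Fourier
        magnitude at the second harmonic."""
        conds = default_conditions(study_design.channel_names, grid_aligned=True)
        cond = conds["medium"]
        x = synthesize_trial(cond, NoiseSpec(0.0, 0.0, 0.0, 0.0), study_design, seed=4)
        fs = study_design.fs
        mi = slice(int(1.0 * fs), int(6.0 * fs))
        seg = x[study_design.channel_names.index("Cz"), mi]
        mag = np.abs(np.fft.rfft(seg, n=int(10 * fs)))  # 0.1-Hz bins
        harm_bins = [int(round(h * 2.1 * 10)) for h in (1, 2, 3, 4)]
        assert np.argmax([mag[b] for b in harm_bins]) == 1

    def test_rest_has_no_harmonic_peaks(self, study_design):
        """Rest-trial SNR at the medium harmonics is ~1 (no false peaks)."""
        from mispeed.preprocess import EpochSet
        from mispeed.spectral import snr_spectrum, steady_state_psd

        conds = default_conditions(study_design.channel_names, grid_aligned=True)
        rng_seeds = np.random.SeedSequence(55).spawn(100)
        trials = [
            synthesize_trial(conds["rest"], NoiseSpec(), study_design, s) for s in rng_seeds
        ]
        t = np.arange(trials[0].shape[-1]) / study_design.fs - study_design.cue_s
        ep = EpochSet(
            data=np.stack(trials),
            labels=np.zeros(len(trials)),
            time_axis=t,
            fs=study_design.fs,
            channel_names=study_design.channel_names,
        )
        freq, _, lin = steady_state_psd(ep, "ssmrp", tmin=0.0, tmax=5.0)
        snr = snr_spectrum(freq, lin)
        for h in (1, 2, 3):
            b = int(np.argmin(np.abs(freq - h * 2.1)))
            assert snr.snr[b] < 2.0

    def test_nyquist_harmonics_dropped_with_warning(self):
        d = SessionDesign(
            n_runs=1, trials_per_class_per_run={"fast": 1}, channel_names=("Cz",)
        )
        cond = ConditionSpec(f0=100.0, harmonic_amps=(1.0, 1.0), ssvep_amp=0.0)
        with pytest.warns(RuntimeWarning, match="Nyquist"):
            x = synthesize_trial(cond, NoiseSpec(0, 0, 0, 0), d, seed=0)
        assert np.isfinite(x).all()

    def test_erd_power_ratio_matches_ground_truth(self, study_design):
        """8-12 Hz motor-channel power during MI: fast/rest ~ (1-erd_alpha)^2.

        Background and beta rhythm are off so the alpha band isolates the
        rhythm whose attenuation is being measured.
        """
        from scipy.signal import welch

        conds = default_conditions(study_design.channel_names, grid_aligned=True)
        erd = conds["fast"].erd_alpha
        noise = NoiseSpec(one_over_f_exponent=1.0, noise_scale=0.0,
                          alpha_rhythm_amp=2.0, beta_rhythm_amp=0.0)
        fs = study_design.fs
        mi = slice(int(1.3 * fs), int(5.7 * fs))  # inside MI, away from ramps
        ch = [study_design.channel_names.index(c) for c in SSMRP_CHANNELS]

        def band_power(cond, seeds):
            p = 0.0
            for s in seeds:
                x = synthesize_trial(cond, noise, study_design, s)[ch, mi]
                f, pxx = welch(x, fs=fs, nperseg=512, axis=-1)
                band = (f >= 8) & (f <= 12)
                p += pxx[:, band].mean()
            return p / len(seeds)

        ss = np.random.SeedSequence(77)
        fast_seeds, rest_seeds = ss.spawn(2)
        pf = band_power(conds["fast"], fast_seeds.spawn(100))
        pr = band_power(conds["rest"], rest_seeds.spawn(100))
        assert pf / pr == pytest.approx((1 - erd) ** 2, rel=0.10)

    def test_full_noise_erd_still_reduces_alpha(self, study_design):
        from scipy.signal import welch

        conds = default_conditions(study_design.channel_names)
        fs = study_design.fs
        mi = slice(int(1.3 * fs), int(5.7 * fs))
        cz = study_design.channel_names.index("Cz")
        ss = np.random.SeedSequence(78).spawn(80)
        powers = {}
        for lab in ("fast", "rest"):
            acc = 0.0
            for s in ss:
                x = synthesize_trial(conds[lab], NoiseSpec(), study_design, s)[cz, mi]
                f, pxx = welch(x, fs=fs, nperseg=512)
                acc += pxx[(f >= 8) & (f <= 12)].mean()
            powers[lab] = acc
        assert powers["fast"] < powers["rest"]


class TestSession:
    def test_study_design_event_count(self, study_design):
        conds = default_conditions(study_design.channel_names)
        sess = generate_session(study_design, conds, NoiseSpec(), seed=1)
        assert len(sess.events) == 105
        assert sess.data.shape == (
            len(study_design.channel_names),
            105 * int(study_design.trial_s * study_design.fs),
        )

    def test_zero_runs_empty_session(self):
        d = SessionDesign(n_runs=0)
        conds = default_conditions(d.channel_names)
        sess = generate_session(d, conds, NoiseSpec(), seed=1)
        assert sess.events == [] and sess.data.shape[1] == 0

    def test_seed_determinism_and_schedule_noise_separation(self, small_design):
        conds = default_conditions(small_design.channel_names)
        a = generate_session(small_design, conds, NoiseSpec(), seed=9)
        b = generate_session(small_design, conds, NoiseSpec(), seed=9)
        c = generate_session(small_design, conds, NoiseSpec(), seed=10)
        assert np.array_equal(a.data, b.data) and a.events == b.events
        assert not np.array_equal(a.data, c.data)
        from collections import Counter

        assert Counter(ev.label for ev in a.events) == Counter(ev.label for ev in c.events)
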