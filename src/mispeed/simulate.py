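"""Synthetic paced-motor-imagery EEG sessions with known ground truth.

The generator emulates a cued MI-speed protocol: each trial is a 1-s visual
cue, a beep marking the onset of a 5-s imagery period paced at a
condition-specific rate, and a 2-s break.  Four classes are simulated
(rest, slow, medium, fast).  Non-rest trials carry

* a steady-state movement-related potential (SSMRP): sinusoids at the pacing
  fundamental and its harmonics (strongest at the second), weighted by a
  smooth frontocentral topography, present during the MI period only;
* a steady-state visual response (SSVEP) with the same harmonic structure on
  an occipital/parietal topography, with larger amplitude than the SSMRP;
* event-related desynchronization (ERD): fractional attenuation of the
  ongoing alpha (8-12 Hz) and beta (13-30 Hz) rhythms over motor channels,
  starting a configurable lead time before the beep (anticipatory ERD) and
  lasting through the MI period.

Background activity is 1/f noise plus the two band-limited rhythms on every
channel.  Everything is driven by a single integer seed and is bit-exact
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .montage import DEFAULT_CHANNELS, SSMRP_CHANNELS, SSVEP_CHANNELS, gaussian_topography

CLASS_LABELS = ("rest", "slow", "medium", "fast")

#: Pacing fundamentals (Hz) of the three imagined-grasp speeds.
SPEED_F0 = {"rest": 0.0, "slow": 0.93, "medium": 2.12, "fast": 2.56}
#: Variant with fundamentals on a 0.1-Hz grid so all harmonics are bin-aligned
#: at 0.1-Hz spectral resolution.
SPEED_F0_GRID = {"rest": 0.0, "slow": 0.9, "medium": 2.1, "fast": 2.6}

#: Harmonic amplitude profile (microvolts) for h = 1..4: second harmonic
#: strongest, gradual attenuation above.
HARMONIC_PROFILE = (0.6, 1.0, 0.5, 0.25)


# --------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class SessionDesign:
    """Timing and trial-count layout of one recording session."""

    n_runs: int = 3
    trials_per_class_per_run: dict = field(
        default_factory=lambda: {"rest": 5, "slow": 10, "medium": 10, "fast": 10}
    )
    cue_s: float = 1.0
    mi_s: float = 5.0
    break_s: float = 2.0
    fs: float = 250.0
    class_labels: tuple = CLASS_LABELS
    channel_names: tuple = DEFAULT_CHANNELS

    @property
    def trial_s(self) -> float:
        return self.cue_s + self.mi_s + self.break_s

    @property
    def trials_per_run(self) -> int:
        return sum(self.trials_per_class_per_run.values())

    def validate(self) -> None:
        if min(self.cue_s, self.mi_s, self.break_s) <= 0:
            raise ValueError("all trial-phase durations must be > 0")
        if self.fs < 100:
            raise ValueError(f"fs must be >= 100 Hz, got {self.fs}")
        if self.n_runs < 0:
            raise ValueError("n_runs must be >= 0")
        unknown = set(self.trials_per_class_per_run) - set(self.class_labels)
        if unknown:
            raise ValueError(f"unknown class labels in design: {sorted(unknown)}")
        for dur, name in [(self.cue_s, "cue_s"), (self.mi_s, "mi_s"), (self.break_s, "break_s")]:
            n = dur * self.fs
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"{name}={dur} s is not sample-aligned at fs={self.fs} Hz"
                )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    def label_index(self, label: str) -> int:
        return self.class_labels.index(label)


@dataclass(frozen=True)
class ConditionSpec:
    """Ground-truth signal content of one class."""

    f0: float  # pacing fundamental, Hz; 0 for rest
    harmonic_amps: tuple = HARMONIC_PROFILE  # microvolts, h = 1..H
    erd_alpha: float = 0.0  # fractional 8-12 Hz attenuation in [0, 1]
    erd_beta: float = 0.0  # fractional 13-30 Hz attenuation in [0, 1]
    pre_lead_s: float = 1.0  # anticipatory ERD lead before MI onset
    ssvep_amp: float = 1.5  # microvolts at the strongest harmonic
    ssmrp_topography: np.ndarray | None = None  # per-channel weights
    ssvep_topography: np.ndarray | None = None

    def validate(self, n_channels: int | None = None) -> None:
        if self.f0 < 0:
            raise ValueError("f0 must be >= 0")
        if any(a < 0 for a in self.harmonic_amps):
            raise ValueError("harmonic amplitudes must be nonnegative")
        for v, name in [(self.erd_alpha, "erd_alpha"), (self.erd_beta, "erd_beta")]:
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ssvep_amp < 0 or self.pre_lead_s < 0:
            raise ValueError("ssvep_amp and pre_lead_s must be >= 0")
        for topo in (self.ssmrp_topography, self.ssvep_topography):
            if topo is not None and n_channels is not None and len(topo) != n_channels:
                raise ValueError("topography length does not match channel count")


@dataclass(frozen=True)
class NoiseSpec:
    """Background model: 1/f noise plus band-limited alpha/beta rhythms."""

    one_over_f_exponent: float = 1.0
    noise_scale: float = 1.0  # RMS microvolts of the 1/f background
    alpha_rhythm_amp: float = 2.0  # RMS microvolts, 8-12 Hz
    beta_rhythm_amp: float = 1.0  # RMS microvolts, 13-30 Hz

    def validate(self) -> None:
        if not 0 <= self.one_over_f_exponent <= 2:
            raise ValueError("one_over_f_exponent must lie in [0, 2]")
        if min(self.noise_scale, self.alpha_rhythm_amp, self.beta_rhythm_amp) < 0:
            raise ValueError("noise/rhythm scales must be >= 0")


@dataclass(frozen=True)
class Event:
    onset_sample: int  # MI onset (the beep), in samples from session start
    label: str
    run: int


@dataclass
class RawSession:
    """Continuous session: channels x samples (microvolts) + event schedule."""

    data: np.ndarray
    fs: float
    channel_names: tuple
    events: list  # list[Event], sorted by onset
    design: SessionDesign
    ground_truth: dict | None = None  # label -> ConditionSpec

    def validate(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be channels x samples")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        mi_n = int(round(self.design.mi_s * self.fs))
        for ev in self.events:
            if ev.onset_sample + mi_n > self.data.shape[1]:
                raise ValueError(f"event at sample {ev.onset_sample} exceeds recording")
        onsets = [ev.onset_sample for ev in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")


def default_conditions(
    channel_names: tuple = DEFAULT_CHANNELS,
    grid_aligned: bool = False,
    separability: str = "default",
) -> dict:
    """Per-class ground-truth specs.

    ``grid_aligned`` snaps the pacing fundamentals to a 0.1-Hz grid
    (0.9/2.1/2.6 Hz) so harmonics fall on exact spectral bins.
    ``separability='high'`` strengthens the class-discriminative components
    (deeper, more class-distinct ERD and larger steady-state amplitudes) for
    decoder-recovery experiments.
    """
    f0 = SPEED_F0_GRID if grid_aligned else SPEED_F0
    ssmrp_topo = gaussian_topography(channel_names, SSMRP_CHANNELS)
    ssvep_topo = gaussian_topography(channel_names, SSVEP_CHANNELS)
    if separability == "default":
        erd = {"rest": (0.0, 0.0), "slow": (0.2, 0.1), "medium": (0.35, 0.25), "fast": (0.5, 0.4)}
        amps, ssvep_amp = HARMONIC_PROFILE, 1.5
    elif separability == "high":
        erd = {"rest": (0.0, 0.0), "slow": (0.6, 0.05), "medium": (0.35, 0.35), "fast": (0.1, 0.7)}
        amps = tuple(2.0 * a for a in HARMONIC_PROFILE)
        ssvep_amp = 1.5 * max(amps)
    else:
        raise ValueError(f"unknown separability preset {separability!r}")
    conds = {}
    for label in CLASS_LABELS:
        ea, eb = erd[label]
        conds[label] = ConditionSpec(
            f0=f0[label],
            harmonic_amps=amps if f0[label] > 0 else (),
            erd_alpha=ea,
            erd_beta=eb,
            ssvep_amp=ssvep_amp if f0[label] > 0 else 0.0,
            ssmrp_topography=ssmrp_topo,
            ssvep_topography=ssvep_topo,
        )
    return conds


# --------------------------------------------------------------------------
# operations


def make_schedule(design: SessionDesign, seed: int) -> list:
    """Seeded per-run shuffled event list; onsets mark MI onset (the beep)."""
    design.validate()
    rng = np.random.default_rng(seed)
    trial_n = int(round(design.trial_s * design.fs))
    cue_n = int(round(design.cue_s * design.fs))
    events = []
    trial_idx = 0
    for run in range(design.n_runs):
        labels = [
            lab
            for lab in design.class_labels
            for _ in range(design.trials_per_class_per_run.get(lab, 0))
        ]
        rng.shuffle(labels)
        for lab in labels:
            events.append(Event(onset_sample=trial_idx * trial_n + cue_n, label=lab, run=run))
            trial_idx += 1
    return events


def _one_over_f_noise(rng, n_channels, n_samples, fs, exponent, scale):
    if scale == 0 or n_samples == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, 1 / fs)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    rms = x.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return scale * x / rms


def _band_rhythm(rng, n_channels, n_samples, fs, band, amp):
    if amp == 0 or n_samples == 0:
        return np.zeros((n_channels, n_samples))
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    # pad so filter transients do not bias the in-trial RMS
    pad = int(round(fs))
    x = signal.sosfiltfilt(sos, rng.standard_normal((n_channels, n_samples + 2 * pad)), axis=-1)
    x = x[:, pad : pad + n_samples]
    rms = x.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return amp * x / rms


def _erd_envelope(cond, design, n_samples, motor_weight, erd, ramp_s=0.2):
    """Per-channel multiplicative envelope: dips to 1 - erd*w on motor channels."""
    fs = design.fs
    t = np.arange(n_samples) / fs
    start = design.cue_s - cond.pre_lead_s
    stop = design.cue_s + design.mi_s
    depth = np.zeros(n_samples)
    core = (t >= start) & (t < stop)
    depth[core] = 1.0
    if ramp_s > 0:  # raised-cosine edges to avoid broadband steps
        rise = (t >= start - ramp_s) & (t < start)
        depth[rise] = 0.5 * (1 + np.cos(np.pi * (start - t[rise]) / ramp_s))
        fall = (t >= stop) & (t < stop + ramp_s)
        depth[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - stop) / ramp_s))
    return 1.0 - erd * motor_weight[:, None] * depth[None, :]


def _steady_state(rng, cond, design, n_samples, amps, topo):
    """Sum of harmonics of f0 during the MI window, phase-locked to the beep."""
    fs = design.fs
    out = np.zeros((len(topo), n_samples))
    if cond.f0 <= 0 or len(amps) == 0:
        return out
    t = np.arange(n_samples) / fs
    mi = (t >= design.cue_s) & (t < design.cue_s + design.mi_s)
    wave = np.zeros(n_samples)
    for h, a_h in enumerate(amps, start=1):
        f_h = h * cond.f0
        if f_h >= fs / 2:
            warnings.warn(
                f"harmonic {h} at {f_h:.2f} Hz exceeds Nyquist ({fs / 2:.1f} Hz); dropped",
                RuntimeWarning,
                stacklevel=3,
            )
            continue
        phi = rng.uniform(0, 2 * np.pi)
        wave[mi] += a_h * np.sin(2 * np.pi * f_h * (t[mi] - design.cue_s) + phi)
    return topo[:, None] * wave[None, :]


def synthesize_trial(
    cond: ConditionSpec, noise: NoiseSpec, design: SessionDesign, seed
) -> np.ndarray:
    """One trial (channels x samples, microvolts): background + rhythms
    (with ERD for non-rest classes) + SSMRP + SSVEP during the MI window."""
    design.validate()
    noise.validate()
    n_ch = len(design.channel_names)
    cond.validate(n_ch)
    rng = np.random.default_rng(seed)
    n = int(round(design.trial_s * design.fs))

    ones = np.ones(n_ch)
    ssmrp_topo = ones if cond.ssmrp_topography is None else np.asarray(cond.ssmrp_topography)
    ssvep_topo = ones if cond.ssvep_topography is None else np.asarray(cond.ssvep_topography)

    x = _one_over_f_noise(
        rng, n_ch, n, design.fs, noise.one_over_f_exponent, noise.noise_scale
    )
    is_rest = cond.f0 <= 0
    for band, amp, erd in (
        ((8.0, 12.0), noise.alpha_rhythm_amp, cond.erd_alpha),
        ((13.0, 30.0), noise.beta_rhythm_amp, cond.erd_beta),
    ):
        rhythm = _band_rhythm(rng, n_ch, n, design.fs, band, amp)
        if not is_rest and erd > 0:
            rhythm = rhythm * _erd_envelope(cond, design, n, ssmrp_topo, erd)
        x += rhythm

    x += _steady_state(rng, cond, design, n, cond.harmonic_amps, ssmrp_topo)
    if cond.ssvep_amp > 0 and len(cond.harmonic_amps) > 0:
        peak = max(cond.harmonic_amps)
        scale = cond.ssvep_amp / peak if peak > 0 else 0.0
        ssvep_amps = tuple(scale * a for a in cond.harmonic_amps)
        x += _steady_state(rng, cond, design, n, ssvep_amps, ssvep_topo)
    return x


def generate_session(
    design: SessionDesign,
    conditions: dict,
    noise: NoiseSpec,
    seed: int,
) -> RawSession:
    """Full session: schedule + per-trial synthesis, reproducible from seed."""
    design.validate()
    for lab in design.class_labels:
        if design.trials_per_class_per_run.get(lab, 0) > 0 and lab not in conditions:
            raise ValueError(f"no ConditionSpec for class {lab!r}")
    ss = np.random.SeedSequence(seed)
    schedule_seed, trial_root = ss.spawn(2)
    events = make_schedule(design, schedule_seed.generate_state(1)[0] % (2**31))
    trial_n = int(round(design.trial_s * design.fs))
    n_ch = len(design.channel_names)
    data = np.zeros((n_ch, trial_n * len(events)))
    for i, (ev, trial_seed) in enumerate(zip(events, trial_root.spawn(len(events)))):
        data[:, i * trial_n : (i + 1) * trial_n] = synthesize_trial(
            conditions[ev.label], noise, design, trial_seed
        )
    sess = RawSession(
        data=data,
        fs=design.fs,
        channel_names=design.channel_names,
        events=events,
        design=design,
        ground_truth=dict(conditions),
    )
    sess.validate()
    return sess


def rest_only(cond: ConditionSpec) -> ConditionSpec:
    """Strip all class-specific content (background + rhythms remain)."""
    return replace(cond, f0=0.0, harmonic_amps=(), erd_alpha=0.0, erd_beta=0.0, ssvep_amp=0.0)
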