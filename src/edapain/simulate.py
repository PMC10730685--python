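"""Synthetic electrodermal-activity cohorts under the heat-pain protocol.

The generator emulates, per subject, a continuous skin-conductance recording
during a calibrated heat-pain session: a slowly drifting tonic level, phasic
skin-conductance responses (SCRs) time-locked to each heat stimulus whose
expected amplitude grows with the stimulus class, occasional spontaneous
(non-specific) SCRs, and i.i.d. Gaussian measurement noise.  Stimuli follow
the protocol timing: 20 repetitions of each of the five classes in shuffled
order, 4 s each, separated by randomized 8-12 s pain-free intervals.

The ``separation`` knob scales the class-dependent SCR amplitude spacing;
``separation = 0`` produces label-independent signals (a chance-level
cohort), larger values make the classes progressively easier to tell apart.
All randomness flows from a single integer seed, so cohorts are bit-for-bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import ProtocolConfig, TemperatureCalibration, compute_temperature_stages

# Phasic SCR shape: bi-exponential with typical rise/decay time constants.
SCR_RISE_TAU = 0.75  # s
SCR_DECAY_TAU = 3.0  # s
SCR_SUPPORT = 30.0  # s of kernel support evaluated per event

# Expected SCR amplitude step per stimulus class, in microsiemens, at
# separation = 1 and scr_gain = 1 (class c >= 1 has expected amplitude
# c * AMP_STEP * separation * scr_gain).
AMP_STEP = 0.2
AMP_JITTER_SIGMA = 0.25  # lognormal sd of per-event amplitude jitter

# Tonic slow wave (very slow oscillatory component of the conductance level).
SLOW_WAVE_AMP = 0.15  # microsiemens
SLOW_WAVE_PERIOD = 90.0  # s

# Spontaneous (non-stimulus-locked) SCRs.
SPONTANEOUS_RATE_PER_MIN = 1.5
SPONTANEOUS_AMP = 0.1  # microsiemens, scaled by scr_gain

# Stimulus onset offset inside each analysis window (the window starts this
# many seconds before the stimulus).
DEFAULT_PRE_ONSET = 0.5

SEGMENT_DIALECTS = (5.5, 4.5)


class ParameterError(ValueError):
    """A waveform or profile parameter violates its constraint."""


class BoundaryError(ValueError):
    """A requested segment extends outside the recorded stream."""


@dataclass(frozen=True)
class SubjectProfile:
    """Subject-level physiological variability knobs."""

    subject_id: str
    tonic_level: float  # baseline skin conductance, microsiemens
    tonic_drift_rate: float  # microsiemens per second
    scr_gain: float  # dimensionless multiplier on all phasic responses
    latency: float  # s between stimulus onset and SCR onset
    noise_sd: float  # microsiemens
    calibration: TemperatureCalibration

    def __post_init__(self) -> None:
        if self.scr_gain < 0:
            raise ParameterError("scr_gain must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.latency < 0:
            raise ParameterError("latency must be >= 0")


@dataclass
class SignalSegment:
    """One analysis window: a labelled stretch of conductance samples."""

    subject_id: str
    label: int
    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D vector")
        if self.label not in (0, 1, 2, 3, 4):
            raise ValueError(f"label must be in 0..4, got {self.label}")


@dataclass
class SubjectStream:
    """A subject's continuous recording with stimulus annotations."""

    subject_id: str
    t: np.ndarray  # seconds from stream start
    gsr: np.ndarray  # microsiemens
    onsets: np.ndarray  # stimulus onset times, seconds
    labels: np.ndarray  # stimulus class per onset
    sampling_rate: float
    components: dict[str, np.ndarray] | None = None


@dataclass
class Cohort:
    """A multi-subject collection of labelled segments."""

    subjects: list[SubjectProfile]
    segments: list[SignalSegment]
    protocol: ProtocolConfig
    seed: int
    separation: float = 1.0

    def validate(self) -> None:
        ids = {p.subject_id for p in self.subjects}
        seg_ids = {s.subject_id for s in self.segments}
        if seg_ids - ids:
            raise ValueError(f"segments reference unknown subjects: {seg_ids - ids}")
        per = self.protocol.reps_per_class
        for sid in ids:
            labels = [s.label for s in self.segments if s.subject_id == sid]
            counts = np.bincount(labels, minlength=self.protocol.classes)
            if not np.all(counts == per):
                raise ValueError(
                    f"subject {sid} has class counts {counts.tolist()}, "
                    f"expected {per} per class"
                )

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stack segments into (X, y, subject_ids) arrays."""
        X = np.stack([s.samples for s in self.segments]).astype(np.float32)
        y = np.array([s.label for s in self.segments], dtype=np.int64)
        sids = np.array([s.subject_id for s in self.segments])
        return X, y, sids


def scr_waveform(
    t: np.ndarray,
    onset: float,
    amplitude: float,
    rise_tau: float = SCR_RISE_TAU,
    decay_tau: float = SCR_DECAY_TAU,
) -> np.ndarray:
    """Bi-exponential skin-conductance response.

    Zero before ``onset``; rises with time constant ``rise_tau``, decays with
    ``decay_tau``, and is analytically normalized so its peak equals
    ``amplitude``.  Returns asymptotically to zero.
    """
    if rise_tau >= decay_tau:
        raise ParameterError(
            f"rise_tau must be < decay_tau, got {rise_tau} >= {decay_tau}"
        )
    if amplitude < 0:
        raise ParameterError("amplitude must be >= 0")
    t = np.asarray(t, dtype=float)
    s = t - onset
    out = np.zeros_like(s)
    pos = s > 0
    sp = s[pos]
    raw = np.exp(-sp / decay_tau) - np.exp(-sp / rise_tau)
    # Analytic peak of exp(-s/d) - exp(-s/r) at s* = rd/(d-r) * ln(d/r).
    s_star = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-s_star / decay_tau) - np.exp(-s_star / rise_tau)
    out[pos] = amplitude * raw / peak
    return out


def _sample_profile(i: int, rng: np.random.Generator, baseline: float) -> SubjectProfile:
    T_P = float(np.clip(rng.normal(42.5, 1.0), 40.0, 45.0))
    T_T = float(min(T_P + rng.uniform(3.5, 5.5), 50.5))
    return SubjectProfile(
        subject_id=f"S{i + 1:03d}",
        tonic_level=float(rng.uniform(2.0, 12.0)),
        tonic_drift_rate=float(rng.uniform(-0.005, 0.005)),
        scr_gain=float(rng.lognormal(-0.4**2 / 2.0, 0.4)),
        latency=float(rng.uniform(1.2, 2.8)),
        noise_sd=float(rng.uniform(0.03, 0.08)),
        calibration=compute_temperature_stages(T_P, T_T, baseline),
    )


def generate_profiles(
    protocol: ProtocolConfig, seed: int | np.random.SeedSequence
) -> list[SubjectProfile]:
    """Draw the usable subject roster.

    ``n_recruited`` profiles are sampled and the last ``n_excluded`` are
    dropped deterministically, mirroring the study's exclusions.
    """
    rng = np.random.default_rng(seed)
    profiles = [
        _sample_profile(i, rng, protocol.baseline_temp)
        for i in range(protocol.n_recruited)
    ]
    return profiles[: protocol.n_subjects]


def generate_subject_stream(
    profile: SubjectProfile,
    protocol: ProtocolConfig,
    seed: int | np.random.SeedSequence | np.random.Generator,
    separation: float = 1.0,
    return_components: bool = False,
) -> SubjectStream:
    """Simulate one subject's continuous recording for a full session.

    The stimulus schedule interleaves ``reps_per_class`` repetitions of every
    class in shuffled order; each stimulus lasts ``stimulus_duration`` seconds
    preceded by a Uniform(interval_range) pain-free gap.
    """
    if separation < 0:
        raise ParameterError("separation must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = protocol.sampling_rate
    n_events = protocol.classes * protocol.reps_per_class

    labels = np.repeat(np.arange(protocol.classes), protocol.reps_per_class)
    rng.shuffle(labels)

    lo, hi = protocol.interval_range
    intervals = rng.uniform(lo, hi, size=n_events)
    onsets = np.empty(n_events)
    cursor = 10.0  # lead-in before the first stimulus
    for k in range(n_events):
        cursor += intervals[k]
        onsets[k] = cursor
        cursor += protocol.stimulus_duration
    duration = cursor + 10.0  # tail after the last stimulus

    n = int(np.ceil(duration * fs))
    t = np.arange(n) / fs

    phase = rng.uniform(0.0, 2.0 * np.pi)
    tonic = (
        profile.tonic_level
        + profile.tonic_drift_rate * t
        + SLOW_WAVE_AMP * np.sin(2.0 * np.pi * t / SLOW_WAVE_PERIOD + phase)
    )

    phasic = np.zeros(n)

    def add_scr(onset_s: float, amp: float) -> None:
        if amp <= 0:
            return
        i0 = int(onset_s * fs)
        i1 = min(n, int((onset_s + SCR_SUPPORT) * fs))
        if i0 >= n:
            return
        phasic[i0:i1] += scr_waveform(t[i0:i1], onset_s, amp)

    # Stimulus-locked responses: expected amplitude proportional to class.
    for onset, lab in zip(onsets, labels):
        if lab == 0:
            continue
        jitter = rng.lognormal(-AMP_JITTER_SIGMA**2 / 2.0, AMP_JITTER_SIGMA)
        amp = separation * AMP_STEP * lab * profile.scr_gain * jitter
        lat = profile.latency + rng.uniform(-0.2, 0.2)
        add_scr(onset + lat, amp)

    # Spontaneous SCRs, label-independent.
    n_spont = rng.poisson(SPONTANEOUS_RATE_PER_MIN * duration / 60.0)
    spont_times = np.sort(rng.uniform(0.0, duration, size=n_spont))
    for st in spont_times:
        amp = SPONTANEOUS_AMP * profile.scr_gain * rng.lognormal(
            -AMP_JITTER_SIGMA**2 / 2.0, AMP_JITTER_SIGMA
        )
        add_scr(st, amp)

    noise = rng.normal(0.0, profile.noise_sd, size=n) if profile.noise_sd > 0 else 0.0
    gsr = tonic + phasic + noise

    components = None
    if return_components:
        components = {
            "tonic": tonic,
            "phasic": phasic,
            "noise": np.broadcast_to(noise, (n,)).copy() if np.ndim(noise) else np.zeros(n),
        }
    return SubjectStream(
        subject_id=profile.subject_id,
        t=t,
        gsr=gsr,
        onsets=onsets,
        labels=labels,
        sampling_rate=fs,
        components=components,
    )


def segment_stream(
    stream: SubjectStream,
    window: float = 5.5,
    pre_onset: float = DEFAULT_PRE_ONSET,
    onsets: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> list[SignalSegment]:
    """Cut stimulus-locked windows out of a continuous recording.

    ``window`` selects the segmentation dialect (5.5 s default, 4.5 s
    alternative).  Each window starts ``pre_onset`` seconds before its
    stimulus onset and contains ``round(rate * window)`` samples.
    """
    if window not in SEGMENT_DIALECTS:
        raise ValueError(f"window dialect must be one of {SEGMENT_DIALECTS}, got {window}")
    fs = stream.sampling_rate
    n_samples = round(fs * window)
    onsets = stream.onsets if onsets is None else np.asarray(onsets, dtype=float)
    labels = stream.labels if labels is None else np.asarray(labels)
    segments = []
    for onset, lab in zip(onsets, labels):
        start = onset - pre_onset
        i0 = int(round(start * fs))
        if i0 < 0 or i0 + n_samples > stream.gsr.shape[0]:
            raise BoundaryError(
                f"segment at onset {onset:.3f}s extends outside the stream"
            )
        segments.append(
            SignalSegment(
                subject_id=stream.subject_id,
                label=int(lab),
                samples=stream.gsr[i0 : i0 + n_samples].astype(np.float32),
                sampling_rate=fs,
            )
        )
    return segments


def generate_subject(
    profile: SubjectProfile,
    protocol: ProtocolConfig,
    seed: int | np.random.SeedSequence,
    separation: float = 1.0,
    window: float = 5.5,
) -> list[SignalSegment]:
    """Simulate and segment one subject: ``classes * reps_per_class`` windows."""
    stream = generate_subject_stream(profile, protocol, seed, separation)
    return segment_stream(stream, window=window)


def generate_cohort(
    protocol: ProtocolConfig | None = None,
    separation: float = 1.0,
    seed: int = 0,
    n_subjects: int | None = None,
) -> Cohort:
    """Simulate the full multi-subject cohort.

    Parameters
    ----------
    protocol : protocol constants; defaults to the emulated study design.
    separation : scales inter-class SCR amplitude spacing; 0 means the labels
        carry no signal.
    seed : master seed; subject-level generators are spawned from it.
    n_subjects : optional down-scaled roster size for desk-scale experiments
        (takes the first ``n_subjects`` usable profiles).
    """
    protocol = protocol or ProtocolConfig()
    ss = np.random.SeedSequence(seed)
    profile_ss, subject_root = ss.spawn(2)
    profiles = generate_profiles(protocol, profile_ss)
    if n_subjects is not None:
        if not 1 <= n_subjects <= len(profiles):
            raise ValueError(f"n_subjects must be in 1..{len(profiles)}")
        profiles = profiles[:n_subjects]
    child_seeds = subject_root.spawn(len(profiles))
    segments: list[SignalSegment] = []
    for prof, child in zip(profiles, child_seeds):
        segments.extend(generate_subject(prof, protocol, child, separation))
    cohort = Cohort(
        subjects=profiles,
        segments=segments,
        protocol=protocol,
        seed=seed,
        separation=separation,
    )
    cohort.validate()
    return cohort
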