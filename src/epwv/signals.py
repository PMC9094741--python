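"""Render subjects into annotated multichannel recordings.

Each subject becomes a uniformly sampled bundle of three channels — ECG,
Doppler envelope at the aortic valve, and a thigh-cuff pulse — whose
ground-truth beat annotations encode the subject's isovolumetric
contraction time (ICT) and aortic transit time exactly:

    t_valve - t_r   = ict
    t_foot  - t_valve = distance / true_pwv

Morphology is deliberately simple (Gaussian QRS, half-sine Doppler burst,
raised-cosine cuff upstroke with exponential decay): the contract is
fiducial *timing*, not clinical realism.

Arrival convention: t_foot is the pulse arrival time under the
intersecting-tangent convention used by transit-time instruments.  For a
raised-cosine upstroke of rise time T the tangent foot sits
(1/2 - 1/pi)*T after the first departure from baseline, so the renderer
starts the upstroke at t_foot - (1/2 - 1/pi)*T; the tangent foot of the
clean waveform is then exactly t_foot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import SubjectProfile
from .errors import InsufficientSignalError, InvalidInputError

__all__ = [
    "BeatAnnotation",
    "WaveformBundle",
    "SignalConfig",
    "TANGENT_OFFSET_FRACTION",
    "beat_schedule",
    "synthesize_recording",
]

#: Fraction of the rise time by which the tangent-intersection foot trails
#: the first departure from baseline, for a raised-cosine upstroke.
TANGENT_OFFSET_FRACTION = 0.5 - 1.0 / np.pi


@dataclass(frozen=True)
class BeatAnnotation:
    """Ground-truth event times for one beat (seconds from recording start)."""

    beat_index: int
    t_r: float      # ECG R-peak
    t_valve: float  # aortic valve opening
    t_foot: float   # pulse arrival at the thigh cuff (tangent convention)


@dataclass
class WaveformBundle:
    """Uniformly sampled multichannel recording plus truth annotations."""

    subject_id: str
    sampling_rate: float  # Hz
    duration: float       # s
    channels: dict[str, np.ndarray]
    truth: list[BeatAnnotation] = field(default_factory=list)

    @property
    def time(self) -> np.ndarray:
        n = len(next(iter(self.channels.values())))
        return np.arange(n) / self.sampling_rate


@dataclass(frozen=True)
class SignalConfig:
    """Rendering parameters (defaults: 1 kHz, 30 s, 2% white noise)."""

    duration: float = 30.0
    sampling_rate: float = 1000.0
    noise_sd: float = 0.02          # fraction of channel amplitude
    jitter: float = 0.03            # multiplicative beat-interval jitter SD
    qrs_sigma: float = 0.008        # s; Gaussian QRS width (~19 ms FWHM)
    rise_time: float = 0.08         # s; cuff upstroke
    ejection_time: float = 0.30     # s; Doppler burst duration
    decay_tau: float = 0.25         # s; cuff diastolic decay constant
    baseline_wander: bool = False   # optional 0.25 Hz drift on the cuff


def beat_schedule(subject: SubjectProfile, duration: float,
                  rng: np.random.Generator | None = None,
                  jitter: float = 0.03, start: float = 0.4) -> list[BeatAnnotation]:
    """R-peak schedule with multiplicative interval jitter, plus exact truth.

    Every annotation satisfies t_valve - t_r = ict and
    t_foot - t_valve = distance / true_pwv exactly.
    """
    if duration < 5.0:
        raise InvalidInputError(f"duration must be >= 5 s, got {duration}")
    if jitter > 0 and rng is None:
        raise InvalidInputError("rng is required when jitter > 0")
    base = 60.0 / subject.heart_rate
    transit = subject.distance / subject.true_pwv
    beats: list[BeatAnnotation] = []
    t = start
    while True:
        t_foot = t + subject.ict + transit
        if t_foot + 0.65 > duration:  # leave room for the full cuff pulse
            break
        beats.append(BeatAnnotation(len(beats), t, t + subject.ict, t_foot))
        z = float(rng.normal()) if jitter > 0 else 0.0
        t += base * (1.0 + jitter * min(max(z, -3.0), 3.0))
    if len(beats) < 3:
        raise InsufficientSignalError(
            f"duration {duration} s yields only {len(beats)} beats")
    return beats


def _add_local(signal: np.ndarray, fs: float, t0: float, t1: float, func) -> None:
    """Add func(t) to signal on the sample range covering [t0, t1)."""
    i0 = max(int(np.ceil(t0 * fs)), 0)
    i1 = min(int(np.ceil(t1 * fs)), len(signal))
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs
    signal[i0:i1] += func(t)


def synthesize_recording(subject: SubjectProfile, duration: float = 30.0,
                         sampling_rate: float = 1000.0, noise_sd: float = 0.02,
                         rng: np.random.Generator | None = None,
                         config: SignalConfig | None = None,
                         schedule: list[BeatAnnotation] | None = None) -> WaveformBundle:
    """Render one annotated recording.

    The truth annotations are produced by :func:`beat_schedule` and do not
    depend on the sampling rate.  With ``noise_sd=0`` the cuff channel is
    exactly baseline before each upstroke onset
    (t_foot - TANGENT_OFFSET_FRACTION * rise_time).
    """
    cfg = config or SignalConfig(duration=duration, sampling_rate=sampling_rate,
                                 noise_sd=noise_sd)
    fs = cfg.sampling_rate
    if fs < 200.0:
        raise InvalidInputError(f"sampling_rate must be >= 200 Hz, got {fs}")
    if rng is None:
        rng = np.random.default_rng(0)
    if schedule is None:
        schedule = beat_schedule(subject, cfg.duration, rng, jitter=cfg.jitter)

    n = int(round(cfg.duration * fs))
    ecg = np.zeros(n)
    doppler = np.zeros(n)
    cuff = np.zeros(n)

    sig = cfg.qrs_sigma
    dur_burst = cfg.ejection_time
    rise = cfg.rise_time
    offset = TANGENT_OFFSET_FRACTION * rise
    onsets = [b.t_foot - offset for b in schedule]

    for i, beat in enumerate(schedule):
        # ECG: narrow Gaussian QRS centred on the R-peak
        _add_local(ecg, fs, beat.t_r - 5 * sig, beat.t_r + 5 * sig,
                   lambda t, tr=beat.t_r: np.exp(-0.5 * ((t - tr) / sig) ** 2))
        # Doppler envelope: half-sine burst starting exactly at valve opening
        _add_local(doppler, fs, beat.t_valve, beat.t_valve + dur_burst,
                   lambda t, tv=beat.t_valve: np.sin(np.pi * (t - tv) / dur_burst))
        # Cuff: raised-cosine upstroke then exponential decay, tapered to a
        # flat baseline at least 100 ms before the next beat's onset.
        on = onsets[i]
        if i + 1 < len(onsets):
            end = min(onsets[i + 1] - 0.10, cfg.duration)
        else:
            end = min(on + 0.55, cfg.duration)
        taper_start = end - 0.08

        def pulse(t, on=on, end=end, taper_start=taper_start):
            tau = t - on
            rise_part = 0.5 * (1.0 - np.cos(np.pi * np.clip(tau, 0, rise) / rise))
            decay = np.where(tau > rise,
                             np.exp(-np.clip(tau - rise, 0, None) / cfg.decay_tau), 1.0)
            w = np.ones_like(t)
            in_taper = t >= taper_start
            w[in_taper] = 0.5 * (1.0 + np.cos(np.pi * np.clip(
                (t[in_taper] - taper_start) / (end - taper_start), 0, 1)))
            return rise_part * decay * w

        _add_local(cuff, fs, on, end, pulse)

    if cfg.baseline_wander:
        cuff += 0.05 * np.sin(2 * np.pi * 0.25 * np.arange(n) / fs)
    if cfg.noise_sd > 0:
        for chan in (ecg, doppler, cuff):
            chan += rng.normal(0.0, cfg.noise_sd, n)  # channel amplitudes are 1

    return WaveformBundle(subject_id=subject.subject_id, sampling_rate=fs,
                          duration=cfg.duration,
                          channels={"ecg": ecg, "doppler_env": doppler, "cuff": cuff},
                          truth=list(schedule))
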