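"""Synthetic stimulus-evoked LFP recordings.

Generates continuous cortical voltage traces with the statistical structure
the downstream analysis assumes: a 1/f ("pink") background, occasional
spontaneous band-limited bursts, a deterministic stimulus-locked evoked
potential (a damped sinusoid), and stimulus-induced oscillatory bursts that
are *not* phase-locked — amplitude-modulated band-limited noise — so they
cancel in the across-trial average but survive single-trial envelope
analysis.  Which induced bursts appear depends on the stimulation condition
(e.g. C-fiber-attributed γ/β bursts present under "AC" but not "A", and
removed again in the post-silencing condition), which is how fiber
recruitment and pharmacological C-fiber silencing are emulated.

Age groups are plain parameter sets (which bursts exist, at what gain);
no developmental model is implied.  An acquisition-style zero-phase 100-Hz
low-pass is applied to the stochastic components.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .bands import CANONICAL_BANDS, BandDefinition, bandpass
from .recording import Recording

__all__ = [
    "BurstSpec",
    "SimConfig",
    "KNOWN_CONDITIONS",
    "evoked_waveform",
    "simulate_recording",
    "simulate_cohort",
]

#: Stimulation/treatment conditions understood out of the box.  Any label
#: appearing in a BurstSpec condition mask is also accepted.
KNOWN_CONDITIONS = ("A", "AC", "AC_preQX", "AC_postQX")

_DEFAULT_STIM_TIMES = tuple(10.0 + 10.0 * k for k in range(10))


def _label_entropy(label: str) -> int:
    """Stable non-negative integer derived from a string label (for seeding)."""
    return zlib.crc32(str(label).encode("utf-8"))


@dataclass(frozen=True)
class BurstSpec:
    """A stimulus-induced band-limited oscillatory burst.

    ``amplitude_gain`` g scales the burst so that, inside its raised-cosine
    window, the mean band envelope energy is about g² × the background's
    (g = 1 means no burst; gains below 1 are treated as absent).
    ``conditions`` lists the condition labels under which the burst occurs.
    """

    band_low: float
    band_high: float
    onset_latency_ms: float
    duration_ms: float
    amplitude_gain: float
    conditions: frozenset = frozenset({"AC"})

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError(f"invalid burst band {self.band_low}-{self.band_high} Hz")
        if self.duration_ms <= 0:
            raise ValueError("burst duration must be positive")
        if self.amplitude_gain < 0:
            raise ValueError("amplitude_gain must be non-negative")
        object.__setattr__(self, "conditions", frozenset(self.conditions))

    def to_dict(self) -> dict:
        return {
            "band_low": self.band_low,
            "band_high": self.band_high,
            "onset_latency_ms": self.onset_latency_ms,
            "duration_ms": self.duration_ms,
            "amplitude_gain": self.amplitude_gain,
            "conditions": sorted(self.conditions),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BurstSpec":
        d = dict(d)
        d["conditions"] = frozenset(d.get("conditions", ("AC",)))
        return cls(**d)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated recording session.

    Defaults follow the emulated acquisition: 16 kHz sampling, 100-Hz
    low-pass, 10 stimuli at 10-s inter-stimulus interval.  Amplitude-scale
    parameters (noise_sd, ep_amplitude, burst gains) are free choices of the
    simulator, documented in the methods note.
    """

    sampling_rate: float = 16000.0
    recording_duration: float = 110.0
    stim_times: tuple = _DEFAULT_STIM_TIMES
    noise_exponent: float = 1.0
    noise_sd: float = 20.0
    spontaneous_burst_rate: float = 0.05
    ep_amplitude: float = 200.0
    ep_latency_ms: float = 20.0
    ep_decay_ms: float = 30.0
    ep_frequency_hz: float = 20.0
    burst_specs: tuple = ()
    rng_seed: int = 0
    lowpass_hz: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stim_times", tuple(float(t) for t in self.stim_times))
        object.__setattr__(self, "burst_specs", tuple(self.burst_specs))
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate < 200:
            raise ValueError("sampling_rate must be at least 200 Hz")
        highest = max((b.band_high for b in self.burst_specs), default=0.0)
        if self.sampling_rate <= 2 * highest:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz must exceed twice the highest "
                f"burst band edge ({highest} Hz)"
            )
        if any(b <= a for a, b in zip(self.stim_times, self.stim_times[1:])):
            raise ValueError("stim_times must be strictly increasing")
        for name in ("noise_sd", "spontaneous_burst_rate", "ep_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ep_decay_ms <= 0 or self.ep_frequency_hz <= 0:
            raise ValueError("ep_decay_ms and ep_frequency_hz must be positive")
        if self.rng_seed < 0:
            raise ValueError("rng_seed must be a non-negative integer")
        if self.lowpass_hz and self.lowpass_hz >= self.sampling_rate / 2:
            raise ValueError("lowpass_hz must be below Nyquist")

    def to_dict(self) -> dict:
        d = {
            "sampling_rate": self.sampling_rate,
            "recording_duration": self.recording_duration,
            "stim_times": list(self.stim_times),
            "noise_exponent": self.noise_exponent,
            "noise_sd": self.noise_sd,
            "spontaneous_burst_rate": self.spontaneous_burst_rate,
            "ep_amplitude": self.ep_amplitude,
            "ep_latency_ms": self.ep_latency_ms,
            "ep_decay_ms": self.ep_decay_ms,
            "ep_frequency_hz": self.ep_frequency_hz,
            "burst_specs": [b.to_dict() for b in self.burst_specs],
            "rng_seed": self.rng_seed,
            "lowpass_hz": self.lowpass_hz,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        d["burst_specs"] = tuple(
            b if isinstance(b, BurstSpec) else BurstSpec.from_dict(b)
            for b in d.get("burst_specs", ())
        )
        if "stim_times" in d:
            d["stim_times"] = tuple(d["stim_times"])
        return cls(**d)


def evoked_waveform(config: SimConfig) -> np.ndarray:
    """The deterministic per-stimulus EP waveform, from the stimulus sample on.

    A damped sinusoid ``exp(−t/τ)·sin(2πf₀t)`` starting ``ep_latency_ms``
    after the stimulus, normalized so its sampled peak magnitude equals
    ``ep_amplitude`` exactly.  Support is truncated at latency + 10 τ.
    """
    fs = config.sampling_rate
    n_lat = round(config.ep_latency_ms * fs / 1000.0)
    tau = config.ep_decay_ms / 1000.0
    n_dur = round(10.0 * tau * fs)
    if config.ep_amplitude == 0 or n_dur == 0:
        return np.zeros(n_lat)
    t = np.arange(n_dur) / fs
    w = np.exp(-t / tau) * np.sin(2 * np.pi * config.ep_frequency_hz * t)
    peak = np.max(np.abs(w))
    if peak > 0:
        w *= config.ep_amplitude / peak
    return np.concatenate([np.zeros(n_lat), w])


def _pink_noise(n: int, fs: float, exponent: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent power spectrum, scaled to ``sd``."""
    white = rng.standard_normal(n)
    if exponent == 0:
        x = white
    else:
        X = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, 1.0 / fs)
        shape = np.zeros_like(f)
        shape[1:] = f[1:] ** (-exponent / 2.0)
        x = np.fft.irfft(X * shape, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _burst_waveform(
    n_win: int, low: float, high: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS band-limited noise under a raised-cosine (Hann) window.

    The returned waveform w(t)·n_b(t) has underlying noise variance 1 before
    windowing; the caller applies the amplitude scale.
    """
    pad = round(3.0 * fs / low)
    raw = rng.standard_normal(n_win + 2 * pad)
    band = BandDefinition("burst", low, high)
    filt = bandpass(raw, band, fs)[pad : pad + n_win]
    s = filt.std()
    if s > 0:
        filt = filt / s
    return filt * np.hanning(n_win)

# mean of a squared Hann window — converts windowed-burst energy to a flat
# per-window average so amplitude_gain keeps its g² energy meaning
_HANN_SQ_MEAN = 0.375


def _add_burst(
    x: np.ndarray,
    start: int,
    n_win: int,
    low: float,
    high: float,
    gain: float,
    sigma_band: float,
    fs: float,
    rng: np.random.Generator,
) -> None:
    if gain <= 1.0 or n_win < 4:
        return
    amp = sigma_band * np.sqrt((gain**2 - 1.0) / _HANN_SQ_MEAN)
    w = amp * _burst_waveform(n_win, low, high, fs, rng)
    stop = min(len(x), start + n_win)
    if stop > start >= 0:
        x[start:stop] += w[: stop - start]


def simulate_recording(
    config: SimConfig,
    condition: str,
    subject_id: str = "sim",
    age_group: str = "NA",
) -> Recording:
    """Simulate one continuous recording under a given condition.

    The trace is the sum of 1/f background, Poisson spontaneous bursts,
    per-stimulus induced bursts for every :class:`BurstSpec` whose condition
    mask contains ``condition``, all passed through the acquisition low-pass,
    plus the deterministic EP waveform at each stimulus.  Identical
    ``rng_seed`` (with the same subject/condition labels) gives bit-identical
    output.
    """
    config.validate()
    allowed = set(KNOWN_CONDITIONS)
    for spec in config.burst_specs:
        allowed |= spec.conditions
    if condition not in allowed:
        raise ValueError(
            f"unknown condition {condition!r}; recognized: {sorted(allowed)}"
        )
    if config.stim_times:
        needed = config.stim_times[-1] + 5.0
        if config.recording_duration < needed:
            raise ValueError(
                f"recording_duration {config.recording_duration} s is shorter than "
                f"last stimulus + 5 s ({needed} s); post-stimulus window would be truncated"
            )
    fs = config.sampling_rate
    n = round(config.recording_duration * fs)
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [config.rng_seed, _label_entropy(subject_id), _label_entropy(condition)]
        )
    )

    x = np.zeros(n)
    if config.noise_sd > 0:
        bg = _pink_noise(n, fs, config.noise_exponent, config.noise_sd, rng)
        x += bg
    else:
        bg = None

    # background band RMS — reference scale for burst gains
    sigma_cache: dict[tuple[float, float], float] = {}

    def band_sigma(low: float, high: float) -> float:
        key = (low, high)
        if key not in sigma_cache:
            if bg is None:
                sigma_cache[key] = 1.0
            else:
                sigma_cache[key] = float(bandpass(bg, BandDefinition("ref", low, high), fs).std())
        return sigma_cache[key]

    # spontaneous bursts: Poisson in time, random canonical band
    if config.spontaneous_burst_rate > 0:
        n_events = rng.poisson(config.spontaneous_burst_rate * config.recording_duration)
        spont_dur_s = 0.3
        for _ in range(n_events):
            t0 = rng.uniform(0.0, max(config.recording_duration - spont_dur_s, 0.0))
            band = CANONICAL_BANDS[rng.integers(len(CANONICAL_BANDS))]
            gain = rng.uniform(2.0, 4.0)
            if band.high >= fs / 2:
                continue
            _add_burst(
                x,
                round(t0 * fs),
                round(spont_dur_s * fs),
                band.low,
                band.high,
                gain,
                band_sigma(band.low, band.high),
                fs,
                rng,
            )

    # stimulus-induced (non-phase-locked) bursts
    for t in config.stim_times:
        for spec in config.burst_specs:
            if condition not in spec.conditions:
                continue
            start = round((t + spec.onset_latency_ms / 1000.0) * fs)
            _add_burst(
                x,
                start,
                round(spec.duration_ms * fs / 1000.0),
                spec.band_low,
                spec.band_high,
                spec.amplitude_gain,
                band_sigma(spec.band_low, spec.band_high),
                fs,
                rng,
            )

    # acquisition low-pass on the stochastic part
    if config.lowpass_hz and np.any(x):
        sos = sps.butter(4, config.lowpass_hz, btype="low", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)

    # deterministic phase-locked EP, added after the acquisition filter so a
    # noise-free simulation equals the analytic sum of EP waveforms exactly
    if config.ep_amplitude > 0:
        w = evoked_waveform(config)
        for t in config.stim_times:
            i = round(t * fs)
            stop = min(n, i + len(w))
            if stop > i:
                x[i:stop] += w[: stop - i]

    return Recording(
        samples=x,
        sampling_rate=fs,
        stim_times=config.stim_times,
        subject_id=subject_id,
        age_group=age_group,
        condition=condition,
    )


def simulate_cohort(
    config_by_age: Mapping[str, SimConfig],
    n_subjects: int,
    conditions: Sequence[str],
    ep_jitter_sd: float = 0.15,
) -> list[Recording]:
    """Simulate a paired cohort: every subject recorded under every condition.

    Per-subject seeds are derived deterministically from each age config's
    ``rng_seed``, and a subject-level lognormal EP-amplitude jitter is shared
    across that subject's conditions, preserving the paired design.
    """
    if not conditions:
        raise ValueError("conditions list must not be empty")
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    recordings: list[Recording] = []
    for age, cfg in config_by_age.items():
        master = np.random.SeedSequence([cfg.rng_seed, _label_entropy(age)])
        jitter_rng = np.random.default_rng(master)
        jitters = jitter_rng.lognormal(mean=0.0, sigma=ep_jitter_sd, size=n_subjects)
        subject_seeds = master.generate_state(n_subjects, dtype=np.uint32)
        for i in range(n_subjects):
            sub_cfg = replace(
                cfg,
                ep_amplitude=cfg.ep_amplitude * jitters[i],
                rng_seed=int(subject_seeds[i]) & 0x7FFFFFFF,
            )
            subject_id = f"{age}-s{i + 1:02d}"
            for condition in conditions:
                recordings.append(
                    simulate_recording(sub_cfg, condition, subject_id, age_group=age)
                )
    return recordings
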