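"""Seeded synthetic EEG: 1/f-like background and rhythmic ictal bursts.

The generator emulates the two regimes every downstream stage must
distinguish: low-amplitude colored-noise background activity and
higher-amplitude rhythmic spike-wave bursts confined to a low-frequency
band, as seen during seizures.  It makes no claim of physiological
realism — it exists so the whole pipeline is testable without external
recordings.

Background is spectrally shaped Gaussian noise (inverse FFT of a white
spectrum scaled by 1/f^(beta/2)).  Ictal records add Gaussian-windowed
sinusoid bursts whose frequency jitters inside ``ictal_band`` and whose
amplitude scales with ``(ictal_amplitude_ratio - 1)`` times the background
RMS, so a ratio of 1 (or a spike rate of 0) degenerates exactly to
background.  Every record is a pure function of the master seed via
``numpy.random.SeedSequence`` child spawning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import LabeledDataset, Signal


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of the synthetic-EEG study.

    Defaults mirror a Bonn-like single-channel segment: 173.61 Hz sampling
    and a duration giving 4097 samples, 1/f background (beta = 1), 2-5 Hz
    ictal rhythm at three times the background amplitude, one burst per
    second, 10 uV background RMS.
    """

    fs: float = 173.61
    duration: float = 4097 / 173.61
    spectral_exponent: float = 1.0
    ictal_band: tuple[float, float] = (2.0, 5.0)
    ictal_amplitude_ratio: float = 3.0
    spike_rate: float = 1.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 2 * self.ictal_band[1]:
            raise ValueError("fs must exceed twice the ictal band's upper edge")
        if not self.ictal_band[0] > 0 or not self.ictal_band[1] > self.ictal_band[0]:
            raise ValueError("ictal_band must satisfy 0 < low < high")
        if self.duration * self.fs < 64:
            raise ValueError("duration * fs must be >= 64 samples")
        if self.ictal_amplitude_ratio < 1:
            raise ValueError("ictal_amplitude_ratio must be >= 1")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


def _rng(cfg: SynthConfig, *spawn_key: int) -> np.random.Generator:
    """Child generator derived deterministically from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=spawn_key))


def _colored_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^beta, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-beta / 2.0)
    scale[0] = 0.0  # zero mean
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_background(cfg: SynthConfig) -> Signal:
    """Zero-mean 1/f^beta background of ``round(fs * duration)`` samples."""
    n = cfg.n_samples
    x = _colored_noise(n, cfg.spectral_exponent, _rng(cfg, 0)) * cfg.noise_sd
    return Signal(x, fs=cfg.fs, channel="synth", record_id=f"bg-{cfg.seed}",
                  class_label="normal")


def generate_ictal(cfg: SynthConfig) -> Signal:
    """Background plus rhythmic spike-wave bursts inside ``ictal_band``.

    Burst centers are laid out at the configured spike rate with jitter;
    each burst is a Gaussian-windowed sinusoid (about three cycles wide)
    with a small second-harmonic component giving a spiky waveform.
    """
    n = cfg.n_samples
    bg = _colored_noise(n, cfg.spectral_exponent, _rng(cfg, 0)) * cfg.noise_sd
    rng = _rng(cfg, 1)  # burst stream independent of the background stream
    n_bursts = int(round(cfg.spike_rate * cfg.duration))
    amp = (cfg.ictal_amplitude_ratio - 1.0) * cfg.noise_sd
    t = np.arange(n) / cfg.fs
    bursts = np.zeros(n)
    if n_bursts > 0 and amp > 0:
        centers = (np.arange(n_bursts) + 0.5) / cfg.spike_rate
        centers = centers + rng.uniform(-0.2, 0.2, size=n_bursts) / cfg.spike_rate
        lo, hi = cfg.ictal_band
        for c in centers:
            f0 = rng.uniform(lo, hi)
            width = 1.5 / f0  # ~3 cycles inside the Gaussian window
            phase = rng.uniform(0, 2 * np.pi)
            env = np.exp(-0.5 * ((t - c) / width) ** 2)
            carrier = np.sin(2 * np.pi * f0 * (t - c) + phase)
            spike = 0.3 * np.sin(4 * np.pi * f0 * (t - c) + 2 * phase)
            bursts += amp * env * (carrier + spike)
    return Signal(bg + bursts, fs=cfg.fs, channel="synth",
                  record_id=f"ictal-{cfg.seed}", class_label="seizure")


def generate_labeled_dataset(
    n_records: int, seizure_fraction: float, cfg: SynthConfig
) -> LabeledDataset:
    """Dataset of ``n_records`` signals; the stated fraction is ictal.

    Exactly ``round(n_records * seizure_fraction)`` records are ictal
    ("seizure"), the rest background ("normal").  Record ``i`` uses the
    child seed spawned at key ``(2, i)`` from the master seed, so the whole
    dataset is a pure function of the config.
    """
    if n_records < 2:
        raise ValueError("n_records must be >= 2")
    if not 0.0 < seizure_fraction < 1.0:
        raise ValueError("seizure_fraction must lie strictly inside (0, 1)")
    n_seiz = int(round(n_records * seizure_fraction))
    instances: list[tuple[object, str]] = []
    for i in range(n_records):
        child_seed = int(
            np.random.SeedSequence(cfg.seed, spawn_key=(2, i)).generate_state(1)[0]
            % (2**31)
        )
        rec_cfg = SynthConfig(
            fs=cfg.fs, duration=cfg.duration,
            spectral_exponent=cfg.spectral_exponent, ictal_band=cfg.ictal_band,
            ictal_amplitude_ratio=cfg.ictal_amplitude_ratio,
            spike_rate=cfg.spike_rate, noise_sd=cfg.noise_sd, seed=child_seed,
        )
        if i < n_seiz:
            sig = generate_ictal(rec_cfg)
            label = "seizure"
        else:
            sig = generate_background(rec_cfg)
            label = "normal"
        sig.record_id = f"synth-{cfg.seed}-{i:04d}"
        sig.class_label = label
        instances.append((sig, label))
    return LabeledDataset(instances, class_names=["normal", "seizure"])
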