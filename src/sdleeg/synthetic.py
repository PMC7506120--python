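"""Seeded synthetic scalp-EEG generator.

The clinical recordings behind this analysis are not publicly deposited,
so this module generates surrogate data with the statistical structure the
method relies on: normal background EEG (1/f-type colored noise with an
alpha rhythm, channel-correlated through a shared source) and seven
classes of epileptiform discharge waveforms whose durations and amplitudes
follow the standard clinical definitions:

=================  ====================  ==================
subtype            duration              amplitude
=================  ====================  ==================
spike              20-70 ms              > 50 µV
sharp              70-200 ms             100-200 µV
spike_slow         spike + slow wave     slow wave larger
sharp_slow         sharp + slow wave     slow wave larger
polyspike          >= 2 spikes           as spike
polyspike_slow     polyspikes + wave     as spike
spike_rhythm       > 1 s at 10-25 Hz     100-200 µV
=================  ====================  ==================

Spikes are biphasic difference-of-Gaussians transients with negative
leading phase; slow waves are half-sine lobes. Discharges repeat through
the epoch at a few hertz (the classic spike-and-wave train picture) and
are injected on at least 10 of the 19 channels with channel-varying gain,
so the 10 strongest channels predominantly carry the discharge.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_edf import CHANNELS_1020, EEGEpoch, write_edf

logger = logging.getLogger(__name__)

#: The seven discharge classes with their default case counts (sum 540).
SUBTYPE_COUNTS = {
    "spike": 69,
    "sharp": 82,
    "spike_slow": 174,
    "sharp_slow": 72,
    "polyspike": 64,
    "polyspike_slow": 77,
    "spike_rhythm": 2,
}

SUBTYPES = list(SUBTYPE_COUNTS)


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-EEG generation settings.

    Background: per-channel 1/f^alpha colored noise (``slope`` = alpha)
    mixed with a shared source, plus an alpha rhythm drawn from
    ``alpha_band``; channel RMS drawn from ``rms_range_uv`` (typical
    scalp EEG runs a few tens of µV). Discharges are injected on at
    least ``min_inject_channels`` channels with gains in ``gain_range``
    and repeat at ``repeat_hz`` (spike-and-wave trains cluster around
    3 Hz clinically).
    """

    fs: float = 256.0
    epoch_seconds: float = 4.0
    n_channels: int = 19
    slope: float = 1.0                       # 1/f^alpha exponent
    alpha_band: tuple[float, float] = (8.0, 13.0)
    alpha_rms_uv: float = 12.0               # alpha-rhythm RMS per channel
    rms_range_uv: tuple[float, float] = (20.0, 60.0)
    shared_mix: float = 0.5                  # weight of the common source
    epi_slope: float = 1.6                   # patient background 1/f^alpha
    epi_rms_range_uv: tuple[float, float] = (30.0, 70.0)
    min_inject_channels: int = 10
    gain_range: tuple[float, float] = (0.7, 1.2)
    repeat_hz: tuple[float, float] = (2.0, 4.0)

    @property
    def n_samples(self) -> int:
        n = self.fs * self.epoch_seconds
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * epoch_seconds must be an integer")
        return int(round(n))


def _colored_noise(rng: np.random.Generator, n: int, fs: float,
                   alpha: float) -> np.ndarray:
    """Unit-RMS 1/f^alpha noise; spectrum flattened below 1 Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    weight = np.ones_like(freqs)
    nz = freqs > 0
    weight[nz] = np.maximum(freqs[nz], 1.0) ** (-alpha / 2.0)
    weight[0] = 0.0
    x = np.fft.irfft(spec * weight, n)
    return x / max(np.std(x), 1e-12)


def gen_background(cfg: GeneratorConfig = GeneratorConfig(),
                   seed: int | np.random.Generator = 0,
                   epoch_id: str = "") -> EEGEpoch:
    """One normal-background epoch: colored noise + alpha rhythm.

    Channels share a common colored-noise source (scalp channels are far
    from independent) and a common alpha frequency with per-channel
    phase jitter and amplitude.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    shared = _colored_noise(rng, n, cfg.fs, cfg.slope)
    f_alpha = rng.uniform(*cfg.alpha_band)
    phase0 = rng.uniform(0, 2 * np.pi)
    rows = []
    for _ in range(cfg.n_channels):
        own = _colored_noise(rng, n, cfg.fs, cfg.slope)
        noise = cfg.shared_mix * shared + (1 - cfg.shared_mix) * own
        noise /= max(np.std(noise), 1e-12)
        target_rms = rng.uniform(*cfg.rms_range_uv)
        alpha_amp = cfg.alpha_rms_uv * np.sqrt(2) * rng.uniform(0.5, 1.5)
        phase = phase0 + rng.normal(scale=0.3)
        alpha_wave = alpha_amp * np.sin(2 * np.pi * f_alpha * t + phase)
        noise_rms = np.sqrt(max(target_rms ** 2
                                - 0.5 * alpha_amp ** 2, 25.0))
        rows.append(noise_rms * noise + alpha_wave)
    names = (CHANNELS_1020 if cfg.n_channels == len(CHANNELS_1020)
             else [f"ch{i}" for i in range(cfg.n_channels)])
    return EEGEpoch(data=np.vstack(rows), fs=cfg.fs,
                    channel_names=list(names), label="normal",
                    epoch_id=epoch_id)


def _biphasic(n: int) -> np.ndarray:
    """Unit-peak biphasic transient (negative leading phase)."""
    u = np.linspace(0, 1, n)
    w = (np.exp(-((u - 0.35) / 0.16) ** 2)
         - 0.55 * np.exp(-((u - 0.72) / 0.22) ** 2))
    return -w / np.max(np.abs(w))


def _half_sine(n: int) -> np.ndarray:
    return np.sin(np.pi * np.linspace(0, 1, n))


def _duration_samples(rng: np.random.Generator, lo_s: float, hi_s: float,
                      fs: float) -> int:
    """Sample count strictly inside a duration window in seconds."""
    lo_n = int(np.ceil(lo_s * fs))
    hi_n = int(np.floor(hi_s * fs))
    return int(rng.integers(lo_n, hi_n + 1))


def _spike(rng: np.random.Generator, fs: float) -> np.ndarray:
    n = _duration_samples(rng, 0.020, 0.070, fs)
    return rng.uniform(55.0, 150.0) * _biphasic(n)


def _sharp(rng: np.random.Generator, fs: float) -> np.ndarray:
    n = _duration_samples(rng, 0.070, 0.200, fs)
    return rng.uniform(100.0, 200.0) * _biphasic(n)


def _with_slow_wave(rng: np.random.Generator, fs: float,
                    transient: np.ndarray) -> np.ndarray:
    n_slow = _duration_samples(rng, 0.150, 0.350, fs)
    amp = np.max(np.abs(transient)) * rng.uniform(1.1, 1.6)
    return np.concatenate([transient, amp * _half_sine(n_slow)])


def _polyspike(rng: np.random.Generator, fs: float) -> np.ndarray:
    k = int(rng.integers(2, 6))
    return np.concatenate([_spike(rng, fs) for _ in range(k)])


def _spike_rhythm(rng: np.random.Generator, fs: float) -> np.ndarray:
    freq = rng.uniform(10.0, 25.0)
    dur = rng.uniform(1.2, 3.0)
    period = max(2, int(round(fs / freq)))
    n_cycles = max(1, int(round(dur * fs / period)))
    cycle = _biphasic(period)
    train = np.tile(cycle, n_cycles)
    return rng.uniform(100.0, 200.0) * train / np.max(np.abs(train))


def gen_discharge(subtype: str, cfg: GeneratorConfig = GeneratorConfig(),
                  seed: int | np.random.Generator = 0) -> np.ndarray:
    """One discharge waveform template (1-D, µV) of the given subtype."""
    rng = np.random.default_rng(seed)
    fs = cfg.fs
    if subtype == "spike":
        return _spike(rng, fs)
    if subtype == "sharp":
        return _sharp(rng, fs)
    if subtype == "spike_slow":
        return _with_slow_wave(rng, fs, _spike(rng, fs))
    if subtype == "sharp_slow":
        return _with_slow_wave(rng, fs, _sharp(rng, fs))
    if subtype == "polyspike":
        return _polyspike(rng, fs)
    if subtype == "polyspike_slow":
        return _with_slow_wave(rng, fs, _polyspike(rng, fs))
    if subtype == "spike_rhythm":
        return _spike_rhythm(rng, fs)
    raise ValueError(f"unknown discharge subtype {subtype!r}; "
                     f"expected one of {SUBTYPES}")


def gen_epileptiform(subtype: str, cfg: GeneratorConfig = GeneratorConfig(),
                     seed: int | np.random.Generator = 0,
                     epoch_id: str = "") -> EEGEpoch:
    """Background epoch with a repeating discharge run injected.

    The template repeats at a few hertz from a random onset to near the
    end of the epoch (rhythm templates already span > 1 s and repeat as
    a whole). Injection covers a random subset of at least
    ``min_inject_channels`` channels with per-channel gain.

    Discharge epochs ride on a patient-like background (``epi_slope``,
    ``epi_rms_range_uv``): interictal EEG of epilepsy patients shows
    background slowing — more low-frequency, more synchronized activity
    — relative to healthy controls, and that background difference is as
    much a part of the class structure as the transients themselves.
    """
    rng = np.random.default_rng(seed)
    bg_cfg = replace(cfg, slope=cfg.epi_slope,
                     rms_range_uv=cfg.epi_rms_range_uv)
    epoch = gen_background(bg_cfg, rng, epoch_id=epoch_id)
    n = cfg.n_samples
    template = gen_discharge(subtype, cfg, rng)
    rate = rng.uniform(*cfg.repeat_hz)
    period = max(len(template), int(round(cfg.fs / rate)))
    onset_max = max(1, n - len(template) - 1)
    onset = int(rng.integers(0, min(period, onset_max) + 1))
    run = np.zeros(n)
    pos = onset
    while pos + len(template) <= n:
        run[pos:pos + len(template)] += template
        pos += period
    if not run.any():  # template longer than remaining space: clip once
        run[onset:n] = template[: n - onset]
    n_inject = int(rng.integers(cfg.min_inject_channels,
                                cfg.n_channels + 1))
    chans = rng.choice(cfg.n_channels, size=n_inject, replace=False)
    data = epoch.data.copy()
    for ch in chans:
        data[ch] += rng.uniform(*cfg.gain_range) * run
    epoch.data = data
    epoch.label = "epileptiform"
    epoch.subtype = [subtype]
    return epoch


def _subtype_assignment(n_epileptiform: int,
                        subtype_mix: dict[str, int] | None,
                        rng: np.random.Generator) -> list[str]:
    counts = dict(subtype_mix or SUBTYPE_COUNTS)
    unknown = set(counts) - set(SUBTYPES)
    if unknown:
        raise ValueError(f"unknown subtypes in mix: {sorted(unknown)}")
    total = sum(counts.values())
    if total == n_epileptiform:
        names = [s for s, c in counts.items() for _ in range(c)]
    else:
        probs = np.array([counts.get(s, 0) for s in SUBTYPES], dtype=float)
        probs /= probs.sum()
        names = list(rng.choice(SUBTYPES, size=n_epileptiform, p=probs))
    rng.shuffle(names)
    return names


def gen_dataset(n_normal: int = 100, n_epileptiform: int = 540,
                subtype_mix: dict[str, int] | None = None,
                cfg: GeneratorConfig = GeneratorConfig(),
                seed: int = 0,
                out_dir: str | Path | None = None
                ) -> tuple[list[EEGEpoch], pd.DataFrame]:
    """Generate a labeled dataset; optionally write EDF files + manifest.

    Defaults reproduce the 100 normal / 540 epileptiform class balance
    with the standard subtype counts. Returns the epochs and a manifest
    DataFrame (epoch_id, source_file, offset, label, subtype).
    """
    rng = np.random.default_rng(seed)
    subtype_names = _subtype_assignment(n_epileptiform, subtype_mix, rng)
    epochs: list[EEGEpoch] = []
    for k in range(n_normal):
        child = int(rng.integers(0, 2 ** 31))
        epochs.append(gen_background(cfg, child, epoch_id=f"normal_{k:05d}"))
    for k, subtype in enumerate(subtype_names):
        child = int(rng.integers(0, 2 ** 31))
        epochs.append(gen_epileptiform(subtype, cfg, child,
                                       epoch_id=f"epi_{k:05d}"))
    rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for ep in epochs:
        fname = f"{ep.epoch_id}.edf"
        if out_path is not None:
            write_edf(out_path / fname, ep.data, ep.fs, ep.channel_names)
        rows.append({
            "epoch_id": ep.epoch_id,
            "source_file": fname if out_path is not None else "",
            "offset": 0,
            "label": ep.label,
            "subtype": "+".join(ep.subtype),
        })
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return epochs, manifest
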