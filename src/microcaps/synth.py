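"""Synthetic single-channel EEG in the Bonn ASCII dialect.

Emulates the statistical signatures of the three clinical states the
classifier separates:

* background — 1/f^beta ("pink") broadband activity plus a posterior
  alpha-band (8-12 Hz) sinusoid of random phase, as in eyes-closed scalp
  EEG of healthy subjects;
* interictal — background with sporadic Poisson-timed biphasic sharp
  transients (epileptiform spikes between seizures);
* ictal — a high-amplitude rhythmic spike-and-wave train at 3-5 Hz over
  attenuated background, the hallmark of a generalized seizure.

Amplitudes are scaled to ADC-like integer units and written one value per
line, 4096 points per file at 173.61 Hz, so the reader ingests synthetic
and real directories identically. Everything is a pure function of
(config, seed).

This generator targets the statistical structure the pipeline needs for
testing — class-dependent amplitude, spectral content and transients — not
physiological realism: there is no neural-mass dynamics, no inter-subject
variability, no artifacts, and class differences are more pronounced than
in clinical recordings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .bonn import BONN_FILE_LEN, BONN_FS, Recording, write_bonn_file

__all__ = [
    "SynthConfig",
    "gen_background",
    "gen_interictal",
    "gen_ictal",
    "gen_recording",
    "gen_dataset",
    "CLASS_TAGS",
]

logger = logging.getLogger(__name__)

CLASS_TAGS = ("background", "interictal", "ictal")


@dataclass
class SynthConfig:
    """Generator parameters.

    Amplitude multipliers are relative to the unit-sd background; the
    final signal is scaled by ``adc_scale`` and rounded to integers,
    mimicking 12-bit acquisition. Defaults give an ictal class that is
    clearly (but not degenerately) separable from background, comparable
    to the contrast between Bonn sets A and E.
    """

    fs: float = BONN_FS
    file_len: int = BONN_FILE_LEN
    n_files_per_class: int = 100
    classes: tuple[str, ...] = CLASS_TAGS
    # background
    pink_exponent: float = 1.0
    alpha_freq_range: tuple[float, float] = (8.0, 12.0)
    alpha_amplitude: float = 0.7
    # interictal
    spike_rate_hz: float = 1.5
    spike_width_ms: float = 70.0
    interictal_multiplier: float = 3.0
    # ictal
    rhythm_freq_range: tuple[float, float] = (3.0, 5.0)
    ictal_multiplier: float = 6.0
    ictal_background_atten: float = 0.5
    # output scaling
    noise_sd: float = 1.0
    adc_scale: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.file_len < 2:
            raise ValueError("fs must be positive and file_len >= 2")
        if self.interictal_multiplier <= 1 or self.ictal_multiplier <= self.interictal_multiplier:
            raise ValueError(
                "need ictal_multiplier > interictal_multiplier > 1"
            )
        unknown = set(self.classes) - set(CLASS_TAGS)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}")


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise via spectral shaping of white noise, unit sd."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]  # avoid div-by-zero at DC
    spectrum = spectrum / freqs ** (exponent / 2.0)
    x = np.fft.irfft(spectrum, n)
    return (x - x.mean()) / x.std()


def _background_core(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-sd pink noise + alpha sinusoid, before any class scaling."""
    t = np.arange(cfg.file_len) / cfg.fs
    x = _pink_noise(cfg.file_len, cfg.pink_exponent, rng)
    f_alpha = rng.uniform(*cfg.alpha_freq_range)
    phase = rng.uniform(0, 2 * np.pi)
    x = x + cfg.alpha_amplitude * np.sin(2 * np.pi * f_alpha * t + phase)
    x = x / x.std() * cfg.noise_sd
    return x


def gen_background(cfg: SynthConfig, seed: int) -> Recording:
    """Normal-state EEG: pink noise with an alpha component."""
    rng = np.random.default_rng(seed)
    x = _background_core(cfg, rng)
    return Recording(x, fs=cfg.fs, set_label="background", source_id=f"synth-bg-{seed}")


def _spike_shape(width_pts: int) -> np.ndarray:
    """Biphasic triangular transient: sharp positive peak then a smaller
    negative undershoot, peak amplitude 1."""
    up = max(2, width_pts // 3)
    down = max(2, width_pts - up)
    pos = np.concatenate([np.linspace(0, 1, up), np.linspace(1, -0.4, down // 2)])
    rest = np.linspace(-0.4, 0, max(2, down - down // 2))
    return np.concatenate([pos, rest])


def gen_interictal(cfg: SynthConfig, seed: int) -> Recording:
    """Between-seizure EEG: background plus Poisson-timed sharp spikes."""
    rng = np.random.default_rng(seed)
    x = _background_core(cfg, rng)
    duration = cfg.file_len / cfg.fs
    n_spikes = rng.poisson(cfg.spike_rate_hz * duration)
    width_pts = max(4, int(round(cfg.spike_width_ms / 1000.0 * cfg.fs)))
    shape = _spike_shape(width_pts) * cfg.interictal_multiplier * cfg.noise_sd
    for _ in range(n_spikes):
        start = rng.integers(0, max(1, cfg.file_len - shape.size))
        polarity = rng.choice((-1.0, 1.0))
        x[start : start + shape.size] += polarity * shape
    return Recording(x, fs=cfg.fs, set_label="interictal", source_id=f"synth-ii-{seed}")


def gen_ictal(cfg: SynthConfig, seed: int) -> Recording:
    """Seizure EEG: rhythmic spike-and-wave at 3-5 Hz over attenuated
    background, scaled by the ictal multiplier."""
    rng = np.random.default_rng(seed)
    bg = _background_core(cfg, rng) * cfg.ictal_background_atten
    t = np.arange(cfg.file_len) / cfg.fs
    f = rng.uniform(*cfg.rhythm_freq_range)
    phase = rng.uniform(0, 2 * np.pi)
    # slow wave plus a sharpened (odd-harmonic-rich) spike component
    wave = np.sin(2 * np.pi * f * t + phase)
    spike = np.sign(np.sin(2 * np.pi * f * t + phase)) * np.abs(
        np.sin(2 * np.pi * f * t + phase)
    ) ** 0.2
    train = 0.6 * wave + 0.4 * spike
    train = train / train.std()
    x = bg + cfg.ictal_multiplier * cfg.noise_sd * train
    return Recording(x, fs=cfg.fs, set_label="ictal", source_id=f"synth-ic-{seed}")


_GENERATORS = {
    "background": gen_background,
    "interictal": gen_interictal,
    "ictal": gen_ictal,
}


def gen_recording(class_tag: str, cfg: SynthConfig, seed: int) -> Recording:
    try:
        return _GENERATORS[class_tag](cfg, seed)
    except KeyError:
        raise ValueError(f"unknown class {class_tag!r}") from None


def _file_seed(master_seed: int, class_tag: str, index: int) -> int:
    """Stable per-file sub-seed below 2**31."""
    ss = np.random.SeedSequence(
        [master_seed, CLASS_TAGS.index(class_tag), index]
    )
    return int(ss.generate_state(1)[0] % (2**31 - 1))

def gen_class_recordings(cfg: SynthConfig, class_tag: str) -> list[Recording]:
    """All recordings of one class (in-memory; quantized like the files)."""
    out = []
    for i in range(cfg.n_files_per_class):
        rec = gen_recording(class_tag, cfg, _file_seed(cfg.seed, class_tag, i))
        out.append(
            Recording(
                np.round(rec.samples * cfg.adc_scale),
                fs=cfg.fs,
                set_label=class_tag,
                source_id=f"{class_tag}{i:03d}.txt",
            )
        )
    return out


def gen_dataset(cfg: SynthConfig, out_dir) -> dict[str, list[Path]]:
    """Write one directory per class in the Bonn ASCII layout.

    Each file holds file_len integer-quantized amplitudes, one per line.
    The config is serialized alongside as synth_config.json. Returns the
    written paths per class.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[Path]] = {}
    for class_tag in cfg.classes:
        class_dir = out_dir / class_tag
        class_dir.mkdir(exist_ok=True)
        paths = []
        for rec in gen_class_recordings(cfg, class_tag):
            path = class_dir / rec.source_id
            write_bonn_file(path, rec.samples)
            paths.append(path)
        written[class_tag] = paths
        logger.info("class %s: wrote %d files to %s", class_tag, len(paths), class_dir)
    with open(out_dir / "synth_config.json", "w") as fh:
        cfg_dict = asdict(cfg)
        json.dump(cfg_dict, fh, indent=2)
    return written
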