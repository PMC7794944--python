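"""Seeded two-class synthetic pulse-plethysmograph (PuPG) generator.

Real PuPG records are 10 s, 1 kHz single-channel traces of finger pulse
pressure: a quasi-periodic train of systolic peaks, each followed by a
smaller dicrotic wave, riding on slow baseline wander and contaminated by
50 Hz powerline pickup and wideband circuit noise.  The generator emulates
exactly that structure with a two-Gaussian beat template:

    x(t) = sum_beats [ A_s g(t; t_b + t_peak, w_s) + A_d g(t; t_b + t_peak + d, w_d) ]
           + wander + powerline + noise,        g = Gaussian bump

The hypertension class differs from the normal class by a damped dicrotic
wave (smaller ``dicrotic_amp``, shorter ``dicrotic_delay_s``) and broader
noise bandwidth, which yields the broader spectral content (higher roll-off
and flatness) that separates the classes in real recordings.

Reproducibility contract: every signal draws from its own RNG stream keyed
by ``(seed, class, index)``, so datasets are bit-identical for a fixed seed
regardless of generation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

__all__ = [
    "ClassMorphology",
    "SynthConfig",
    "Signal",
    "generate_signal",
    "generate_dataset",
    "load_manifest",
    "load_signal_file",
]

LABELS = ("normal", "hypertension")


class ConfigurationError(ValueError):
    """Raised when a generator/pipeline configuration is invalid."""


@dataclass(frozen=True)
class ClassMorphology:
    """Per-class beat morphology and noise-bandwidth parameters.

    Amplitudes are in (dimensionless) sensor units, times in seconds,
    rates in beats per minute.
    """

    heart_rate_bpm: float = 72.0
    heart_rate_jitter_bpm: float = 3.0  # per-beat SD of the instantaneous rate
    systolic_amp: float = 1.0
    systolic_width_s: float = 0.06
    systolic_peak_time_s: float = 0.15  # peak latency after beat onset
    dicrotic_amp: float = 0.35
    dicrotic_delay_s: float = 0.30  # dicrotic peak delay after systolic peak
    dicrotic_width_s: float = 0.08
    noise_bandwidth_hz: float = 100.0  # low-pass corner of the wideband noise


def _default_morphology() -> dict:
    # Hypertension: dicrotic wave halved and earlier, noise band +30%.
    return {
        "normal": ClassMorphology(),
        "hypertension": ClassMorphology(
            heart_rate_bpm=78.0,
            dicrotic_amp=0.175,
            dicrotic_delay_s=0.22,
            noise_bandwidth_hz=130.0,
        ),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic two-class PuPG dataset."""

    n_per_class: int = 10
    duration_s: float = 10.0
    fs: float = 1000.0
    powerline_amp: float = 0.02
    powerline_freq_hz: float = 50.0
    noise_sd: float = 0.02
    wander_amp: float = 0.10
    wander_freq_hz: float = 0.25
    seed: int = 0
    morphology: dict = field(default_factory=_default_morphology)

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ConfigurationError("fs and duration_s must be positive")
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        for label, m in self.morphology.items():
            if not 0 <= m.dicrotic_amp < m.systolic_amp:
                raise ConfigurationError(
                    f"{label}: need 0 <= dicrotic_amp < systolic_amp"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def with_contrast(self, contrast: float) -> "SynthConfig":
        """Rescale the between-class dicrotic-notch contrast.

        ``contrast=1`` keeps the defaults; ``contrast=0`` makes the
        hypertension morphology identical to normal; values > 1 exaggerate
        the difference.  Used for separability/monotonicity studies.
        """
        normal = self.morphology["normal"]
        hyper = self.morphology["hypertension"]
        blend = lambda a, b: a + contrast * (b - a)  # noqa: E731
        new_hyper = replace(
            hyper,
            dicrotic_amp=max(0.0, blend(normal.dicrotic_amp, hyper.dicrotic_amp)),
            dicrotic_delay_s=blend(normal.dicrotic_delay_s, hyper.dicrotic_delay_s),
            noise_bandwidth_hz=blend(
                normal.noise_bandwidth_hz, hyper.noise_bandwidth_hz
            ),
            heart_rate_bpm=blend(normal.heart_rate_bpm, hyper.heart_rate_bpm),
        )
        morph = {"normal": normal, "hypertension": new_hyper}
        return replace(self, morphology=morph)


@dataclass
class Signal:
    """A single-channel PuPG record."""

    samples: np.ndarray
    fs: float
    id: str = ""
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"signal {self.id!r} contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size


def _gaussian_bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _rng_for(cfg: SynthConfig, class_label: str, index: int) -> np.random.Generator:
    class_code = LABELS.index(class_label)
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), class_code, int(index)])
    )


def generate_signal(cfg: SynthConfig, class_label: str, index: int = 0) -> Signal:
    """Generate one synthetic PuPG record for ``class_label``.

    The output is bit-identical for identical ``(cfg, class_label, index)``.
    """
    if class_label not in cfg.morphology:
        raise ConfigurationError(f"unknown class label {class_label!r}")
    m: ClassMorphology = cfg.morphology[class_label]
    rng = _rng_for(cfg, class_label, index)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    x = np.zeros(n)

    # Beat train: successive onsets from the jittered instantaneous rate.
    onset = 0.0
    guard = 4.0 * max(m.systolic_width_s, m.dicrotic_width_s) + m.dicrotic_delay_s
    while onset < cfg.duration_s + guard:
        rate = m.heart_rate_bpm + m.heart_rate_jitter_bpm * rng.standard_normal()
        rate = max(rate, 30.0)
        sys_center = onset + m.systolic_peak_time_s
        x += m.systolic_amp * _gaussian_bump(t, sys_center, m.systolic_width_s)
        x += m.dicrotic_amp * _gaussian_bump(
            t, sys_center + m.dicrotic_delay_s, m.dicrotic_width_s
        )
        onset += 60.0 / rate

    if cfg.wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += cfg.wander_amp * np.sin(2 * np.pi * cfg.wander_freq_hz * t + phase)
    if cfg.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += cfg.powerline_amp * np.sin(2 * np.pi * cfg.powerline_freq_hz * t + phase)
    if cfg.noise_sd > 0:
        noise = rng.standard_normal(n)
        nyq = cfg.fs / 2.0
        if 0 < m.noise_bandwidth_hz < nyq:
            b, a = butter(4, m.noise_bandwidth_hz / nyq, btype="low")
            noise = filtfilt(b, a, noise)
            noise /= noise.std()
        x += cfg.noise_sd * noise

    return Signal(samples=x, fs=cfg.fs, id=f"{class_label}_{index:04d}", label=class_label)


def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write ``2 * n_per_class`` signal files plus a manifest CSV.

    Each signal file is plain text, one sample per line; the manifest has
    columns ``id,path,label`` with paths relative to the manifest location.
    Returns the manifest as a DataFrame (also written to
    ``out_dir/manifest.csv``).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc

    rows = []
    for label in LABELS:
        for i in range(cfg.n_per_class):
            sig = generate_signal(cfg, label, i)
            rel = f"{sig.id}.txt"
            np.savetxt(out_dir / rel, sig.samples, fmt="%.10g")
            rows.append({"id": sig.id, "path": rel, "label": label})
    manifest = pd.DataFrame(rows, columns=["id", "path", "label"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_signal_file(path: str | Path, fs: float, id: str = "", label: str = "unlabeled") -> Signal:
    """Read a plain-text signal file (one sample per line, or time,value CSV)."""
    data = np.loadtxt(path, delimiter=None if _is_whitespace_delimited(path) else ",")
    if data.ndim == 2:  # time,value layout: keep the value column
        data = data[:, -1]
    return Signal(samples=data, fs=fs, id=id, label=label)


def _is_whitespace_delimited(path: str | Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return "," not in first


def load_manifest(manifest_path: str | Path, fs: float) -> list[Signal]:
    """Load every signal referenced by a manifest CSV (id,path,label)."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    missing = {"id", "path", "label"} - set(table.columns)
    if missing:
        raise IOError(f"manifest {manifest_path} lacks columns {sorted(missing)}")
    signals = []
    for row in table.itertuples(index=False):
        p = manifest_path.parent / row.path
        signals.append(load_signal_file(p, fs=fs, id=str(row.id), label=str(row.label)))
    if not signals:
        warnings.warn(f"manifest {manifest_path} lists no signals")
    return signals
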