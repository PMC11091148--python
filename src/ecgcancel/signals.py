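"""1-D signal container, synthetic ECG/audio generators, noise and
preprocessing stages, and CSV I/O.

The synthetic ECG is a quasi-periodic sum of Gaussian bumps — one per
P/Q/R/S/T wave per beat — on the beat grid implied by the heart rate,
plus optional Gaussian baseline noise.  It is not a physiological
simulator; it exists to exercise separation, binarization and matching
with signals that have realistic gross structure (sharp QRS complex,
slow P/T waves, strong autocorrelation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import DegenerateInputError, FormatError, ParameterError

__all__ = [
    "Signal1D",
    "SyntheticEcgSpec",
    "DEFAULT_WAVES",
    "generate_synthetic_ecg",
    "generate_synthetic_audio",
    "add_awgn",
    "notch_filter",
    "match_lengths",
    "read_signal",
    "write_signal",
]


@dataclass
class Signal1D:
    """A sampled real-valued waveform.

    Parameters
    ----------
    samples : array-like
        The sample values, at least two, all finite.
    fs : float
        Sampling rate in Hz, strictly positive.
    label : str
        Free-text provenance tag.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ParameterError(
                f"signal must be 1-D with >= 2 samples, got shape {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("signal contains non-finite samples")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ParameterError(f"sampling rate must be > 0, got {self.fs}")
        self.fs = float(self.fs)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal length in seconds."""
        return self.n / self.fs


# Per-wave (amplitude, width sigma in s, offset from the R peak in s).
# Amplitudes are relative to the R wave; widths/offsets are typical adult
# surface-ECG values at rest.
DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (0.15, 0.020, -0.200),
    "Q": (-0.10, 0.008, -0.025),
    "R": (1.00, 0.010, 0.000),
    "S": (-0.20, 0.008, 0.025),
    "T": (0.30, 0.040, 0.250),
}


@dataclass
class SyntheticEcgSpec:
    """Parameters of the Gaussian-bump PQRST generator.

    Defaults mirror a common single-lead acquisition protocol:
    20 s records sampled at 500 Hz.
    """

    fs: float = 500.0
    duration: float = 20.0
    heart_rate: float = 60.0
    wave_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WAVES)
    )
    baseline_noise_sd: float = 0.01  # relative to the peak amplitude
    seed: int = 0

    def validate(self) -> int:
        """Check invariants; return the integer sample count."""
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ParameterError(f"fs must be > 0, got {self.fs}")
        if not (np.isfinite(self.heart_rate) and self.heart_rate > 0):
            raise ParameterError(f"heart_rate must be > 0, got {self.heart_rate}")
        n_exact = self.fs * self.duration
        n = int(round(n_exact))
        if abs(n_exact - n) > 1e-6 or n < 2:
            raise ParameterError(
                f"fs*duration must be an integer sample count >= 2, got {n_exact}"
            )
        if self.baseline_noise_sd < 0:
            raise ParameterError("baseline_noise_sd must be >= 0")
        for name, (_, width, _) in self.wave_params.items():
            if width <= 0:
                raise ParameterError(f"wave {name!r} width must be > 0, got {width}")
        return n


def generate_synthetic_ecg(spec: SyntheticEcgSpec) -> Signal1D:
    """Build a quasi-periodic PQRST signal from `spec`.

    Deterministic given ``spec.seed``.  With ``baseline_noise_sd = 0``
    the output is exactly periodic with period ``60 / heart_rate``.
    """
    n = spec.validate()
    t = np.arange(n) / spec.fs
    period = 60.0 / spec.heart_rate
    # Beats three periods beyond each edge make interior samples see the
    # full (symmetric) set of Gaussian tails, preserving exact periodicity.
    first = int(np.floor(t[0] / period)) - 3
    last = int(np.ceil(t[-1] / period)) + 3
    clean = np.zeros(n)
    for amp, width, offset in spec.wave_params.values():
        for k in range(first, last + 1):
            center = k * period + offset
            clean += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    if spec.baseline_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        sd = spec.baseline_noise_sd * np.max(np.abs(clean))
        clean = clean + rng.normal(0.0, sd, size=n)
    return Signal1D(clean, spec.fs, label=f"synthetic-ecg(seed={spec.seed})")


def generate_synthetic_audio(n: int, fs: float, seed: int) -> Signal1D:
    """An audio-like fixture: a few seeded random sinusoids plus
    low-pass-filtered white noise, exactly zero-mean.

    No claim of acoustic realism is made; the generator only provides a
    wide-band signal uncorrelated with the ECG generator's output.
    """
    if n < 2:
        raise ParameterError(f"n must be >= 2, got {n}")
    if fs <= 0:
        raise ParameterError(f"fs must be > 0, got {fs}")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    x = np.zeros(n)
    n_tones = 5
    freqs = rng.uniform(0.02 * fs, 0.40 * fs, size=n_tones)
    amps = rng.uniform(0.3, 1.0, size=n_tones)
    phases = rng.uniform(0, 2 * np.pi, size=n_tones)
    for f, a, ph in zip(freqs, amps, phases):
        x += a * np.sin(2 * np.pi * f * t + ph)
    b, a_ = sps.butter(4, 0.3)
    x += 0.5 * sps.lfilter(b, a_, rng.standard_normal(n))
    x -= x.mean()
    return Signal1D(x, fs, label=f"synthetic-audio(seed={seed})")


def add_awgn(x: Signal1D, snr_db: float, seed: int) -> Signal1D:
    """Add white Gaussian noise at the requested signal-to-noise ratio.

    SNR is defined on total mean-square power.  ``snr_db = inf`` is the
    zero-noise flag and returns a copy of the input.
    """
    if np.isinf(snr_db) and snr_db > 0:
        return Signal1D(x.samples.copy(), x.fs, label=x.label)
    px = float(np.mean(x.samples**2))
    if px == 0.0:
        raise DegenerateInputError("cannot set an SNR for a zero-power signal")
    pn = px / 10.0 ** (snr_db / 10.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(pn), size=x.n)
    return Signal1D(x.samples + noise, x.fs, label=f"{x.label}+awgn({snr_db}dB)")


def notch_filter(x: Signal1D, f0: float = 50.0, q_factor: float = 30.0) -> Signal1D:
    """Second-order IIR notch for power-line interference removal.

    Unity gain (within 1 dB) at DC and Nyquist; deep rejection at f0.
    """
    if not (0 < f0 < x.fs / 2):
        raise ParameterError(
            f"notch frequency must lie in (0, fs/2)=(0, {x.fs / 2}), got {f0}"
        )
    b, a = sps.iirnotch(f0, q_factor, fs=x.fs)
    y = sps.lfilter(b, a, x.samples)
    return Signal1D(y, x.fs, label=f"{x.label}+notch({f0}Hz)")


def match_lengths(a: Signal1D, b: Signal1D) -> tuple[Signal1D, Signal1D]:
    """Truncate both signals to the shorter length. No resampling; sample
    values are never altered."""
    n = min(a.n, b.n)
    if a.n == b.n:
        return a, b
    return (
        Signal1D(a.samples[:n], a.fs, a.label),
        Signal1D(b.samples[:n], b.fs, b.label),
    )


def write_signal(x: Signal1D, path, format: str = "csv") -> None:
    """Serialize a signal; CSV dialect is one sample per line with a
    single ``fs=<Hz>`` header line."""
    if format != "csv":
        raise FormatError(f"unsupported write format {format!r}; only 'csv' is supported")
    with open(path, "w") as fh:
        fh.write(f"fs={float(x.fs)!r}\n")
        for v in x.samples:
            fh.write(f"{float(v)!r}\n")


def read_signal(path, format: str = "csv", fs: float | None = None) -> Signal1D:
    """Read a signal written by :func:`write_signal`.

    The ``fs=<Hz>`` header is optional; an explicit ``fs`` argument
    overrides it (default 1 Hz when neither is present).  A WFDB reader
    is not provided; only the CSV dialect is understood.
    """
    if format != "csv":
        raise FormatError(f"unsupported read format {format!r}; only 'csv' is supported")
    values: list[float] = []
    file_fs = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if lineno == 1 and line.startswith("fs="):
                try:
                    file_fs = float(line[3:])
                except ValueError:
                    raise FormatError(f"{path}: line 1: bad sampling-rate header {line!r}")
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-numeric token {line!r}")
    effective_fs = fs if fs is not None else (file_fs if file_fs is not None else 1.0)
    if len(values) < 2:
        raise FormatError(f"{path}: fewer than 2 samples")
    return Signal1D(np.asarray(values), effective_fs, label=str(path))
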