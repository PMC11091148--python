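"""Enroll / verify / evaluate workflows and the synthetic study population.

The evaluation protocol, per subject: acquisition 0 enrolls (with the
subject's key), the remaining acquisitions probe under the same key.
All unordered template pairs are scored once; same-subject pairs are
genuine, cross-subject pairs imposter.

Synthetic subjects differ in heart rate and PQRST morphology (seeded
per-subject jitter of wave amplitudes, widths and offsets); acquisitions
of one subject share morphology and differ only in the baseline-noise
realization, emulating repeat recordings in one session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bss import BssConfig
from .errors import ParameterError
from .matching import ROCCurve, ScoreSet, build_scores, roc
from .signals import (
    DEFAULT_WAVES,
    Signal1D,
    SyntheticEcgSpec,
    add_awgn,
    generate_synthetic_audio,
    generate_synthetic_ecg,
    notch_filter,
)
from .template import CancellableTemplate, generate_key, generate_template

__all__ = [
    "RunConfig",
    "SubjectRecord",
    "make_subject",
    "make_population",
    "enroll_subject",
    "evaluate_population",
]


@dataclass
class RunConfig:
    """Resolved hyperparameters of one enroll/verify/evaluate run."""

    bss: BssConfig = field(default_factory=BssConfig)
    snr_db: float | None = None  # AWGN on probe ECGs; None = clean
    notch: tuple[float, float] | None = None  # (f0, q_factor)
    output_choice: str = "y1"
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ParameterError(
                f"threshold must lie in (0, 1), got {self.threshold}"
            )
        if self.output_choice not in ("y1", "y2"):
            raise ParameterError(f"bad output_choice {self.output_choice!r}")

    def describe(self) -> dict:
        return {
            "q": self.bss.q,
            "l1": self.bss.l1,
            "l2": self.bss.l2,
            "max_iter": self.bss.max_iter,
            "conv_tol": self.bss.conv_tol,
            "ridge": self.bss.ridge,
            "snr_db": self.snr_db,
            "notch": self.notch,
            "output_choice": self.output_choice,
            "threshold": self.threshold,
            "seed": self.seed,
        }


@dataclass
class SubjectRecord:
    subject_id: str
    ecg_spec: SyntheticEcgSpec
    audio_seed: int
    key_seed: int


def make_subject(
    subject_index: int,
    seed: int,
    fs: float = 500.0,
    duration: float = 20.0,
) -> SubjectRecord:
    """Draw one synthetic subject's physiology and credentials.

    Heart rate is uniform on [55, 95] bpm; wave amplitudes/widths get
    +-20%/+-10% multiplicative jitter and offsets +-10 ms shifts, all
    from a stream keyed on (seed, subject_index) so populations are
    reproducible and subjects mutually distinct.
    """
    rng = np.random.default_rng([seed, subject_index])
    hr = float(rng.uniform(55.0, 95.0))
    waves = {}
    for name, (amp, width, offset) in DEFAULT_WAVES.items():
        waves[name] = (
            amp * float(rng.uniform(0.8, 1.2)),
            width * float(rng.uniform(0.9, 1.1)),
            offset + float(rng.uniform(-0.010, 0.010)),
        )
    ecg_spec = SyntheticEcgSpec(
        fs=fs,
        duration=duration,
        heart_rate=hr,
        wave_params=waves,
        baseline_noise_sd=0.01,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return SubjectRecord(
        subject_id=f"subj-{subject_index:03d}",
        ecg_spec=ecg_spec,
        audio_seed=int(rng.integers(0, 2**31 - 1)),
        key_seed=int(rng.integers(0, 2**31 - 1)),
    )


def acquire(
    subject: SubjectRecord,
    acquisition: int,
    config: RunConfig,
    noisy: bool = False,
) -> tuple[Signal1D, Signal1D]:
    """One (ECG, audio) acquisition; repeat acquisitions re-draw only the
    baseline noise.  AWGN at ``config.snr_db`` is applied when ``noisy``."""
    spec = replace(
        subject.ecg_spec, seed=(subject.ecg_spec.seed + acquisition) % 2**31
    )
    ecg = generate_synthetic_ecg(spec)
    audio = generate_synthetic_audio(ecg.n, ecg.fs, seed=subject.audio_seed)
    if config.notch is not None:
        ecg = notch_filter(ecg, *config.notch)
    if noisy and config.snr_db is not None:
        ecg = add_awgn(
            ecg, config.snr_db, seed=(subject.ecg_spec.seed + 7919 * (acquisition + 1)) % 2**31
        )
    return ecg, audio


def make_population(
    n_subjects: int, seed: int, fs: float = 500.0, duration: float = 20.0
) -> list[SubjectRecord]:
    if n_subjects < 2:
        raise ParameterError(
            f"need at least 2 subjects for genuine and imposter pairs, got {n_subjects}"
        )
    return [make_subject(i, seed, fs=fs, duration=duration) for i in range(n_subjects)]


def enroll_subject(
    subject: SubjectRecord, config: RunConfig, acquisition: int = 0
) -> CancellableTemplate:
    ecg, audio = acquire(subject, acquisition, config, noisy=False)
    key = generate_key(ecg.n, subject.key_seed, key_id=f"{subject.subject_id}/key")
    return generate_template(
        ecg,
        audio,
        key,
        cfg=config.bss,
        output_choice=config.output_choice,
        subject_id=subject.subject_id,
    )


def probe_subject(
    subject: SubjectRecord, config: RunConfig, acquisition: int
) -> CancellableTemplate:
    ecg, audio = acquire(subject, acquisition, config, noisy=True)
    key = generate_key(ecg.n, subject.key_seed, key_id=f"{subject.subject_id}/key")
    return generate_template(
        ecg,
        audio,
        key,
        cfg=config.bss,
        output_choice=config.output_choice,
        subject_id=subject.subject_id,
    )


def evaluate_population(
    n_subjects: int,
    n_acquisitions: int,
    config: RunConfig,
    fs: float = 500.0,
    duration: float = 20.0,
) -> tuple[ScoreSet, ROCCurve]:
    """Build all templates for the synthetic population and score them."""
    if n_acquisitions < 2:
        raise ParameterError(
            f"need >= 2 acquisitions per subject for genuine pairs, got {n_acquisitions}"
        )
    subjects = make_population(n_subjects, config.seed, fs=fs, duration=duration)
    enrolled = [enroll_subject(s, config) for s in subjects]
    probes = [
        probe_subject(s, config, acq)
        for s in subjects
        for acq in range(1, n_acquisitions)
    ]
    scores = build_scores(enrolled, probes)
    return scores, roc(scores)
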