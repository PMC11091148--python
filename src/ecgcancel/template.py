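"""Cancellable template generation: binarization, keyed XOR, revocation.

A template is produced by running the ECG/audio pair through the
decorrelation separator, thresholding one distorted output at its median
(balanced, affine-invariant bits), and XOR-ing the bit stream with a
user-specific key of the same length.  XOR with an independent uniform
key whitens the bits, so templates are revocable (re-key and re-enroll)
and the stored record carries no usable trace of the raw ECG.

Keys here come from a seeded PRNG so that enrollments are reproducible;
a deployment would draw key bits from OS entropy instead and store them
in a separate credential channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .bss import BssConfig, separate
from .errors import DegenerateInputError, ParameterError, RevocationError
from .signals import Signal1D, match_lengths

__all__ = [
    "UserKey",
    "CancellableTemplate",
    "binarize",
    "generate_key",
    "xor_encrypt",
    "generate_template",
    "revoke",
    "save_templates",
    "load_templates",
]


def _as_bits(bits) -> np.ndarray:
    arr = np.asarray(bits)
    if arr.ndim != 1 or arr.size < 1:
        raise ParameterError(f"bit vector must be 1-D and non-empty, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ParameterError("bit vector entries must be 0 or 1")
    return arr.astype(np.uint8)


@dataclass
class UserKey:
    """A user-specific secret bit vector, same length as the template."""

    bits: np.ndarray
    key_id: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.bits = _as_bits(self.bits)

    @property
    def n(self) -> int:
        return self.bits.size


@dataclass
class CancellableTemplate:
    """A revocable binary template; never stores the raw ECG samples."""

    bits: np.ndarray
    subject_id: str
    key_id: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bits = _as_bits(self.bits)

    @property
    def n(self) -> int:
        return self.bits.size


def binarize(y: Signal1D) -> np.ndarray:
    """Threshold a signal at its median: bit = 1 where sample > median.

    Median thresholding gives near-balanced bits for continuous-valued
    inputs and is invariant to affine rescaling of the signal.
    """
    med = float(np.median(y.samples))
    if np.max(y.samples) == np.min(y.samples):
        raise DegenerateInputError(
            "constant signal cannot be binarized (zero-variance template)"
        )
    return (y.samples > med).astype(np.uint8)


def generate_key(n: int, seed: int, key_id: str | None = None) -> UserKey:
    """Seeded i.i.d. uniform key bits; reproducible given the seed."""
    if n < 1:
        raise ParameterError(f"key length must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    bits = rng.integers(0, 2, size=n, dtype=np.uint8)
    return UserKey(bits=bits, key_id=key_id if key_id is not None else f"key-{seed}", seed=seed)


def xor_encrypt(bits, key: UserKey) -> np.ndarray:
    """Elementwise XOR with the key; applying it twice restores the input."""
    b = _as_bits(bits)
    if b.size != key.n:
        raise ParameterError(f"bit/key length mismatch: {b.size} != {key.n}")
    return np.bitwise_xor(b, key.bits)


def generate_template(
    ecg: Signal1D,
    audio: Signal1D,
    key: UserKey,
    cfg: BssConfig | None = None,
    output_choice: str = "y1",
    subject_id: str = "",
) -> CancellableTemplate:
    """Full chain: length matching -> separation -> binarize -> XOR.

    ``output_choice`` selects which distorted separator output becomes
    the template; y1 (anchored to the ECG observation) is the default.
    Separation non-convergence is recorded in provenance, not fatal.
    """
    if output_choice not in ("y1", "y2"):
        raise ParameterError(f"output_choice must be 'y1' or 'y2', got {output_choice!r}")
    if cfg is None:
        cfg = BssConfig()
    ecg_m, audio_m = match_lengths(ecg, audio)
    if key.n != ecg_m.n:
        raise ParameterError(
            f"key length {key.n} != matched signal length {ecg_m.n}"
        )
    result = separate(ecg_m, audio_m, cfg)
    y = result.y1 if output_choice == "y1" else result.y2
    bits = binarize(y)
    enc = xor_encrypt(bits, key)
    provenance = {
        "output_choice": output_choice,
        "converged": result.converged,
        "iterations": result.iterations,
        "cost_initial": result.cost_trajectory[0],
        "cost_final": result.cost_trajectory[-1],
        "bss": {
            "q": cfg.q,
            "l1": cfg.l1,
            "l2": cfg.l2,
            "max_iter": cfg.max_iter,
            "conv_tol": cfg.conv_tol,
            "ridge": cfg.ridge,
        },
        "key_seed": key.seed,
    }
    return CancellableTemplate(
        bits=enc, subject_id=subject_id, key_id=key.key_id, provenance=provenance
    )


def revoke(
    ecg: Signal1D,
    audio: Signal1D,
    old: CancellableTemplate,
    new_seed: int,
    cfg: BssConfig | None = None,
) -> CancellableTemplate:
    """Issue a fresh template for the same subject under a new key.

    The new key must come from a different seed; a template identical to
    the old one (seed collision) raises RevocationError.
    """
    old_seed = old.provenance.get("key_seed")
    if old_seed is not None and new_seed == old_seed:
        raise RevocationError(
            f"new key seed {new_seed} matches the revoked key's seed"
        )
    ecg_m, audio_m = match_lengths(ecg, audio)
    new_key = generate_key(ecg_m.n, new_seed)
    if new_key.key_id == old.key_id:
        new_key.key_id = f"{new_key.key_id}-revoked"
    fresh = generate_template(
        ecg,
        audio,
        new_key,
        cfg=cfg,
        output_choice=old.provenance.get("output_choice", "y1"),
        subject_id=old.subject_id,
    )
    if fresh.n == old.n and np.array_equal(fresh.bits, old.bits):
        raise RevocationError("revocation produced a template identical to the old one")
    return fresh


# ---------------------------------------------------------------------------
# template store: one JSON record per line, bits hex-packed little-endian
# within each byte.

def _bits_to_hex(bits: np.ndarray) -> str:
    return np.packbits(bits, bitorder="little").tobytes().hex()


def _hex_to_bits(hexstr: str, n: int) -> np.ndarray:
    raw = np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8)
    return np.unpackbits(raw, bitorder="little")[:n]


def save_templates(templates: list[CancellableTemplate], path) -> None:
    with open(path, "w") as fh:
        for t in templates:
            rec = {
                "subject_id": t.subject_id,
                "key_id": t.key_id,
                "n_bits": int(t.n),
                "bits_hex": _bits_to_hex(t.bits),
                "provenance": t.provenance,
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def load_templates(path) -> list[CancellableTemplate]:
    out: list[CancellableTemplate] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            out.append(
                CancellableTemplate(
                    bits=_hex_to_bits(rec["bits_hex"], rec["n_bits"]),
                    subject_id=rec["subject_id"],
                    key_id=rec["key_id"],
                    provenance=rec.get("provenance", {}),
                )
            )
    return out
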