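"""Correlation-score matching and EER/ROC/AROC evaluation.

Templates are compared with the normalized correlation coefficient
R_xy = Cv(x, y) / (sigma_x sigma_y); binary templates are mapped
{0,1} -> {-1,+1} first so that independent balanced bit streams score
near zero.  Verification accepts when the score strictly exceeds the
operating threshold.  Genuine/imposter score sets yield the ROC by a
full threshold sweep, the AROC by trapezoidal integration, and the EER
at the (linearly interpolated) crossing of FAR and FRR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .signals import Signal1D
from .template import CancellableTemplate

__all__ = [
    "ScoreSet",
    "ROCCurve",
    "VerifyResult",
    "correlation_score",
    "build_scores",
    "roc",
    "verify",
    "export_roc_csv",
]

DEFAULT_THRESHOLD = 0.5  # midpoint of the admissible 0.05-0.95 band


@dataclass
class ScoreSet:
    genuine: list[float] = field(default_factory=list)
    imposter: list[float] = field(default_factory=list)


@dataclass
class ROCCurve:
    points: list[tuple[float, float]]  # (FPR, TPR), swept from strict to lax
    thresholds: list[float]
    eer: float
    aroc: float


@dataclass
class VerifyResult:
    match: bool
    score: float
    threshold: float


def _as_score_vector(x) -> np.ndarray:
    """Coerce a template/signal/array to a +-1 or float vector."""
    if isinstance(x, CancellableTemplate):
        return x.bits.astype(np.float64) * 2.0 - 1.0
    if isinstance(x, Signal1D):
        return x.samples.astype(np.float64)
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ParameterError(f"expected a 1-D vector, got shape {arr.shape}")
    if np.isin(arr, (0.0, 1.0)).all():
        # binary data is centered onto +-1 before scoring
        return arr * 2.0 - 1.0
    return arr


def correlation_score(x, y) -> float:
    """Normalized correlation in [-1, 1]; symmetric, affine-invariant."""
    a = _as_score_vector(x)
    b = _as_score_vector(y)
    if a.size != b.size:
        raise ParameterError(f"length mismatch: {a.size} != {b.size}")
    if a.size < 2:
        raise ParameterError("need at least 2 samples to correlate")
    a = a - a.mean()
    b = b - b.mean()
    sa = float(np.sqrt(np.mean(a**2)))
    sb = float(np.sqrt(np.mean(b**2)))
    if sa == 0.0 or sb == 0.0:
        raise DegenerateInputError("zero-variance input to correlation score")
    r = float(np.mean(a * b) / (sa * sb))
    return float(np.clip(r, -1.0, 1.0))


def build_scores(
    enrolled: list[CancellableTemplate], probes: list[CancellableTemplate]
) -> ScoreSet:
    """Score every unordered pair of distinct templates exactly once.

    The enrolled and probe lists are pooled (the same object appearing in
    both is counted once); same-subject pairs are genuine, cross-subject
    pairs are imposter.
    """
    pool: list[CancellableTemplate] = []
    seen: set[int] = set()
    for t in list(enrolled) + list(probes):
        if not isinstance(t, CancellableTemplate):
            raise ParameterError("build_scores expects CancellableTemplate instances")
        if not t.subject_id:
            raise ParameterError("every template needs a subject_id")
        if id(t) not in seen:
            seen.add(id(t))
            pool.append(t)
    scores = ScoreSet()
    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            s = correlation_score(pool[i], pool[j])
            if pool[i].subject_id == pool[j].subject_id:
                scores.genuine.append(s)
            else:
                scores.imposter.append(s)
    if not scores.genuine or not scores.imposter:
        raise ParameterError(
            f"need both genuine and imposter pairs, got {len(scores.genuine)} genuine "
            f"and {len(scores.imposter)} imposter"
        )
    return scores


def _rates_at(scores: ScoreSet, t: float) -> tuple[float, float]:
    g = np.asarray(scores.genuine, dtype=np.float64)
    i = np.asarray(scores.imposter, dtype=np.float64)
    tpr = float(np.mean(g >= t))
    fpr = float(np.mean(i >= t))
    return fpr, tpr


def roc(scores: ScoreSet) -> ROCCurve:
    """Full threshold sweep over all distinct scores plus sentinels.

    TPR(t) = fraction of genuine scores >= t, FPR(t) likewise for
    imposters.  AROC is the trapezoidal area under (FPR, TPR); the EER is
    found where FAR = FPR crosses FRR = 1 - TPR, interpolating linearly
    between adjacent thresholds when the empirical step functions do not
    meet exactly.
    """
    g = np.asarray(scores.genuine, dtype=np.float64)
    i = np.asarray(scores.imposter, dtype=np.float64)
    if g.size == 0 or i.size == 0 or not (
        np.all(np.isfinite(g)) and np.all(np.isfinite(i))
    ):
        raise ParameterError("score set must be non-empty and finite")
    all_scores = np.concatenate([g, i])
    lo = float(all_scores.min()) - 1.0
    hi = float(all_scores.max()) + 1.0
    thresholds = np.concatenate([[lo], np.unique(all_scores), [hi]])
    fprs = np.empty_like(thresholds)
    tprs = np.empty_like(thresholds)
    for k, t in enumerate(thresholds):
        fprs[k], tprs[k] = _rates_at(scores, float(t))
    # sweep strict -> lax: descending threshold makes (FPR, TPR) ascend
    order = np.argsort(-thresholds)
    pts_f = np.concatenate([[0.0], fprs[order], [1.0]])
    pts_t = np.concatenate([[0.0], tprs[order], [1.0]])
    aroc = float(np.trapezoid(pts_t, pts_f))

    far = fprs
    frr = 1.0 - tprs
    d = far - frr  # +1 at the lax end, -1 at the strict end
    eer = None
    for k in range(len(thresholds)):
        if d[k] == 0.0:
            eer = float(far[k])
            break
    if eer is None:
        # thresholds ascend, d descends from +1 to -1: find the sign flip
        for k in range(len(thresholds) - 1):
            if d[k] > 0.0 > d[k + 1]:
                alpha = d[k] / (d[k] - d[k + 1])
                eer = float(far[k] + alpha * (far[k + 1] - far[k]))
                break
    if eer is None:  # pragma: no cover - sentinels guarantee a crossing
        raise ParameterError("FAR/FRR curves do not cross")
    points = list(zip(pts_f.tolist(), pts_t.tolist()))
    return ROCCurve(points=points, thresholds=thresholds.tolist(), eer=eer, aroc=aroc)


def verify(
    probe: CancellableTemplate,
    enrolled: CancellableTemplate,
    threshold: float = DEFAULT_THRESHOLD,
) -> VerifyResult:
    """Accept iff the correlation score strictly exceeds the threshold."""
    score = correlation_score(probe, enrolled)
    return VerifyResult(match=score > threshold, score=score, threshold=threshold)


def export_roc_csv(curve: ROCCurve, scores: ScoreSet, path) -> None:
    """Write threshold/FPR/TPR rows with EER/AROC in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# eer={curve.eer!r} aroc={curve.aroc!r}\n")
        fh.write(f"# n_genuine={len(scores.genuine)} n_imposter={len(scores.imposter)}\n")
        fh.write("threshold,fpr,tpr\n")
        for t in curve.thresholds:
            fpr, tpr = _rates_at(scores, float(t))
            fh.write(f"{t!r},{fpr!r},{tpr!r}\n")
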