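"""2x2 convolutive blind source separation by output decorrelation.

Model
-----
Two zero-mean sources s1, s2 reach two sensors through a fully connected
LTI system with unit direct paths:

    x1(k) = s1(k) + (h12 * s2)(k)
    x2(k) = (h21 * s1)(k) + s2(k)

Separation applies the mirrored structure with FIR weights of order q:

    y1(k) = x1(k) + sum_i w1(i) x2(k - i)
    y2(k) = x2(k) + sum_i w2(i) x1(k - i)

and chooses w1, w2 to minimize the decorrelation cost

    C = sum_{l = l1..l2} r_{y1y2}(l)^2,

the sum of squared output cross-correlations over a window of lags.
Expanding r_{y1y2}(l) in terms of sample correlation estimates of the
observations gives a closed form that is affine in w1 at fixed w2 (and
vice versa), so C is minimized by alternating exact linear least-squares
solves — each sub-step can only lower the cost.  When the sources are
truly independent and q >= the mixing order, the global minimizer is
w1 = -h12, w2 = -h21 (zero-padded), i.e. the mixing is undone up to the
usual filtering ambiguity on the direct paths.

All correlations use the biased 1/N estimator on mean-centered data,
which keeps implied autocorrelation matrices positive semi-definite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import NumericalError, ParameterError
from .signals import Signal1D

__all__ = [
    "MixingSystem",
    "BssConfig",
    "CorrelationWorkspace",
    "SeparationResult",
    "convolutive_mix",
    "xcorr_lag",
    "build_workspace",
    "predicted_xcorr",
    "cost",
    "update_weights",
    "separate",
]


@dataclass
class MixingSystem:
    """Cross-coupling FIR filters of a 2x2 mixer with unit direct paths."""

    h12: np.ndarray
    h21: np.ndarray

    def __post_init__(self) -> None:
        self.h12 = np.atleast_1d(np.asarray(self.h12, dtype=np.float64))
        self.h21 = np.atleast_1d(np.asarray(self.h21, dtype=np.float64))
        if self.h12.ndim != 1 or self.h21.ndim != 1:
            raise ParameterError("mixing filters must be 1-D coefficient vectors")
        if self.h12.size != self.h21.size:
            raise ParameterError(
                f"h12 and h21 must share the order p: {self.h12.size - 1} != {self.h21.size - 1}"
            )
        if not (np.all(np.isfinite(self.h12)) and np.all(np.isfinite(self.h21))):
            raise ParameterError("mixing coefficients must be finite")

    @property
    def p(self) -> int:
        """Mixing filter order."""
        return self.h12.size - 1


@dataclass
class BssConfig:
    """Hyperparameters of the iterative separator.

    q : separation FIR order (q+1 taps per weight vector).
    l1, l2 : inclusive cross-correlation lag window.
    conv_tol : relative cost-change threshold (1e-4 = 0.01%).
    ridge : relative Tikhonov term on the normal equations; scaled by the
        mean diagonal of psi^T psi so the solution is scale-invariant.
    """

    q: int = 4
    l1: int = -25
    l2: int = 25
    max_iter: int = 100
    conv_tol: float = 1e-4
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ParameterError(f"q must be >= 0, got {self.q}")
        if self.l2 < self.l1:
            raise ParameterError(f"need l1 <= l2, got ({self.l1}, {self.l2})")
        if self.max_iter < 1:
            raise ParameterError(f"max_iter must be >= 1, got {self.max_iter}")
        if not self.conv_tol > 0:
            raise ParameterError(f"conv_tol must be > 0, got {self.conv_tol}")
        if self.ridge < 0:
            raise ParameterError(f"ridge must be >= 0, got {self.ridge}")

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.l1, self.l2 + 1)

    @property
    def n_lags(self) -> int:
        return self.l2 - self.l1 + 1


@dataclass
class CorrelationWorkspace:
    """Sample correlation statistics of one observation pair.

    r_x1x2[j]           = r_{x1x2}(l_j)
    q_plus_x2x2[i, j]   = r_{x2x2}(l_j + i),  i = 0..q
    q_minus_x1x1[i, j]  = r_{x1x1}(l_j - i),  i = 0..q
    r_x2x1[m + q, j]    = r_{x2x1}(l_j + m),  m = -q..q
    """

    r_x1x2: np.ndarray
    q_plus_x2x2: np.ndarray
    q_minus_x1x1: np.ndarray
    r_x2x1: np.ndarray
    cfg: BssConfig


@dataclass
class SeparationResult:
    w1: np.ndarray
    w2: np.ndarray
    y1: Signal1D
    y2: Signal1D
    cost_trajectory: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def convolutive_mix(
    s1: Signal1D, s2: Signal1D, mix: MixingSystem
) -> tuple[Signal1D, Signal1D]:
    """Apply the 2x2 convolutive mixer: x1 = s1 + h12*s2, x2 = h21*s1 + s2.

    Causal FIR convolution, outputs truncated to the input length.
    """
    if s1.n != s2.n:
        raise ParameterError(f"source lengths differ: {s1.n} != {s2.n}")
    x1 = s1.samples + sps.lfilter(mix.h12, [1.0], s2.samples)
    x2 = sps.lfilter(mix.h21, [1.0], s1.samples) + s2.samples
    fs = s1.fs
    return (
        Signal1D(x1, fs, label="mix-x1"),
        Signal1D(x2, fs, label="mix-x2"),
    )


def xcorr_lag(a: np.ndarray, b: np.ndarray, l: int) -> float:
    """Biased sample cross-correlation (1/N) sum_k a(k) b(k+l).

    Symmetric under (a, b, l) -> (b, a, -l); |l| must be < the length.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size != b.size:
        raise ParameterError(f"lengths differ: {a.size} != {b.size}")
    n = a.size
    if abs(l) >= n:
        raise ParameterError(f"|lag| {abs(l)} must be < length {n}")
    if l >= 0:
        s = float(a[: n - l] @ b[l:])
    else:
        s = float(a[-l:] @ b[: n + l])
    return s / n


def _xcorr_range(a: np.ndarray, b: np.ndarray, lmin: int, lmax: int) -> np.ndarray:
    return np.array([xcorr_lag(a, b, l) for l in range(lmin, lmax + 1)])


def build_workspace(x1, x2, cfg: BssConfig) -> CorrelationWorkspace:
    """Estimate every correlation statistic the cost expansion needs.

    Signals are mean-centered here, once, before estimation.
    """
    a = np.asarray(x1.samples if isinstance(x1, Signal1D) else x1, dtype=np.float64)
    b = np.asarray(x2.samples if isinstance(x2, Signal1D) else x2, dtype=np.float64)
    if a.size != b.size:
        raise ParameterError(f"lengths differ: {a.size} != {b.size}")
    n = a.size
    need = 2 * (cfg.q + max(abs(cfg.l1), abs(cfg.l2)))
    if n < max(need, 2):
        raise ParameterError(
            f"signals of length {n} too short for q={cfg.q}, lags [{cfg.l1}, {cfg.l2}]"
        )
    a = a - a.mean()
    b = b - b.mean()
    q, l1, l2 = cfg.q, cfg.l1, cfg.l2
    lags = cfg.lags

    r_x1x2 = _xcorr_range(a, b, l1, l2)
    # autocorrelations over the extended ranges the Q matrices index
    r_bb = _xcorr_range(b, b, l1, l2 + q)
    r_aa = _xcorr_range(a, a, l1 - q, l2)
    r_ba = _xcorr_range(b, a, l1 - q, l2 + q)

    q_plus = np.empty((q + 1, cfg.n_lags))
    q_minus = np.empty((q + 1, cfg.n_lags))
    for i in range(q + 1):
        q_plus[i] = r_bb[(lags + i) - l1]
        q_minus[i] = r_aa[(lags - i) - (l1 - q)]
    r_x2x1 = np.empty((2 * q + 1, cfg.n_lags))
    for m in range(-q, q + 1):
        r_x2x1[m + q] = r_ba[(lags + m) - (l1 - q)]
    return CorrelationWorkspace(r_x1x2, q_plus, q_minus, r_x2x1, cfg)


def _a_matrix(w: np.ndarray, grouped_by_first: bool) -> np.ndarray:
    """The (2q+1) x (q+1) banded matrix of shifted copies of the partner
    weight vector that linearizes the bilinear term w1^T r_{x2x1}(l) w2.

    With rows indexed by m = -q..q:
      grouped_by_first=True  (A(w2), acts on w1): A[m+q, i] = w2[i - m]
      grouped_by_first=False (A(w1), acts on w2): A[m+q, j] = w1[j + m]
    Both reproduce sum_{i,j} w1(i) w2(j) r_{x2x1}(l + i - j).
    """
    q = w.size - 1
    A = np.zeros((2 * q + 1, q + 1))
    for m in range(-q, q + 1):
        for c in range(q + 1):
            idx = c - m if grouped_by_first else c + m
            if 0 <= idx <= q:
                A[m + q, c] = w[idx]
    return A


def predicted_xcorr(ws: CorrelationWorkspace, w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Closed-form output cross-correlation r_{y1y2} over the lag window.

    r_y1y2 = r_x1x2 + Q+^T w1 + Q-^T w2 + (bilinear term), built purely
    from the workspace statistics; with w1 = w2 = 0 this is r_x1x2.
    """
    w1 = np.asarray(w1, dtype=np.float64)
    w2 = np.asarray(w2, dtype=np.float64)
    qp1 = ws.cfg.q + 1
    if w1.size != qp1 or w2.size != qp1:
        raise ParameterError(
            f"weights must have q+1 = {qp1} taps, got {w1.size} and {w2.size}"
        )
    bilinear = ws.r_x2x1.T @ (_a_matrix(w2, grouped_by_first=True) @ w1)
    return (
        ws.r_x1x2
        + ws.q_plus_x2x2.T @ w1
        + ws.q_minus_x1x1.T @ w2
        + bilinear
    )


def cost(r_y1y2: np.ndarray) -> float:
    """Decorrelation cost: the squared 2-norm of the cross-correlation
    vector over the configured lags."""
    r = np.asarray(r_y1y2, dtype=np.float64)
    if r.size == 0:
        raise ParameterError("empty cross-correlation vector")
    return float(r @ r)


def _ridge_solve(psi: np.ndarray, rhs: np.ndarray, ridge: float) -> np.ndarray:
    """Solve the regularized normal equations for w = argmin ||rhs + psi w||."""
    G = psi.T @ psi
    qp1 = G.shape[0]
    scale = np.trace(G) / qp1
    lam = ridge * scale if scale > 0 else ridge
    try:
        if lam == 0:
            w = np.linalg.solve(G, -psi.T @ rhs)
        else:
            w = np.linalg.solve(G + lam * np.eye(qp1), -psi.T @ rhs)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "singular normal equations; set BssConfig.ridge > 0"
        ) from exc
    if not np.all(np.isfinite(w)):
        raise NumericalError(
            "non-finite weight solution; set BssConfig.ridge > 0"
        )
    return w


def update_weights(
    ws: CorrelationWorkspace, w1: np.ndarray, w2: np.ndarray, cfg: BssConfig
) -> tuple[np.ndarray, np.ndarray]:
    """One alternating pass of the coupled closed-form solutions.

    w1 is refreshed against the current w2, then w2 against the *new* w1;
    each solve is the exact least-squares minimizer of the predicted
    cross-correlation norm in its own block, so neither sub-step can
    increase the cost.
    """
    w1 = np.asarray(w1, dtype=np.float64)
    w2 = np.asarray(w2, dtype=np.float64)
    psi1 = ws.q_plus_x2x2.T + ws.r_x2x1.T @ _a_matrix(w2, grouped_by_first=True)
    rhs1 = ws.r_x1x2 + ws.q_minus_x1x1.T @ w2
    w1_new = _ridge_solve(psi1, rhs1, cfg.ridge)
    psi2 = ws.q_minus_x1x1.T + ws.r_x2x1.T @ _a_matrix(w1_new, grouped_by_first=False)
    rhs2 = ws.r_x1x2 + ws.q_plus_x2x2.T @ w1_new
    w2_new = _ridge_solve(psi2, rhs2, cfg.ridge)
    return w1_new, w2_new


def _apply_weights(x1: np.ndarray, x2: np.ndarray, w1, w2) -> tuple[np.ndarray, np.ndarray]:
    y1 = x1 + sps.lfilter(w1, [1.0], x2) if np.any(w1) else x1.copy()
    y2 = x2 + sps.lfilter(w2, [1.0], x1) if np.any(w2) else x2.copy()
    return y1, y2


def separate(x1: Signal1D, x2: Signal1D, cfg: BssConfig | None = None) -> SeparationResult:
    """Run the iterative decorrelation separator.

    Starts from w1 = w2 = 0 (so the initial cost is ||r_x1x2||^2, the
    observation cross-correlation energy) and alternates the coupled
    least-squares updates until the relative cost change falls below
    ``cfg.conv_tol`` or ``cfg.max_iter`` passes are spent.  Failure to
    converge is flagged on the result, not raised.
    """
    if cfg is None:
        cfg = BssConfig()
    if x1.n != x2.n:
        raise ParameterError(f"observation lengths differ: {x1.n} != {x2.n}")
    ws = build_workspace(x1, x2, cfg)
    qp1 = cfg.q + 1
    w1 = np.zeros(qp1)
    w2 = np.zeros(qp1)
    c_prev = cost(predicted_xcorr(ws, w1, w2))
    trajectory = [c_prev]
    converged = False
    iterations = 0
    tiny = np.finfo(np.float64).tiny
    for iterations in range(1, cfg.max_iter + 1):
        w1, w2 = update_weights(ws, w1, w2, cfg)
        c = cost(predicted_xcorr(ws, w1, w2))
        trajectory.append(c)
        if abs(c_prev - c) <= cfg.conv_tol * max(c_prev, tiny):
            converged = True
            break
        c_prev = c
    y1, y2 = _apply_weights(x1.samples, x2.samples, w1, w2)
    return SeparationResult(
        w1=w1,
        w2=w2,
        y1=Signal1D(y1, x1.fs, label="bss-y1"),
        y2=Signal1D(y2, x2.fs, label="bss-y2"),
        cost_trajectory=trajectory,
        iterations=iterations,
        converged=converged,
    )
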