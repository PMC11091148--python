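# Methods

## Signal model and separation

The pipeline treats an ECG/audio pair as observations of a 2×2 linear
time-invariant convolutive system with unit direct paths:

    x1(k) = s1(k) + (h12 * s2)(k)
    x2(k) = (h21 * s1)(k) + s2(k)

with `h12`, `h21` causal FIR filters of order `p` and sources assumed
zero-mean and statistically independent.  Separation applies the
mirrored adaptive structure `y1 = x1 + w1 * x2`, `y2 = x2 + w2 * x1`
with FIR weights of order `q` and minimizes the decorrelation cost

    C(w1, w2) = Σ_{l=l1}^{l2} r_{y1y2}(l)²,

the energy of the output cross-correlation over a lag window.  All
correlations are biased (1/N) sample estimates on mean-centered data;
the biased estimator keeps implied autocorrelation matrices positive
semi-definite.  Expanding `r_{y1y2}(l)` gives

    r_y1y2 = r_x1x2 + [Q⁺_x2x2]ᵀ w1 + [Q⁻_x1x1]ᵀ w2 + bilinear(w1, w2)

where `Q⁺_x2x2[i, j] = r_x2x2(l_j + i)` and `Q⁻_x1x1[i, j] = r_x1x1(l_j − i)`
(`i = 0..q`), and the bilinear term Σ_{i,j} w1(i) w2(j) r_x2x1(l + i − j)
is linearized through a banded (2q+1)×(q+1) matrix of shifted copies of
the partner weight vector.  The two index conventions (`+i` for the
partner autocorrelation, `−i` for the own-channel one) fall out of the
expansion of E[(x1 + w1ᵀx2)(x2 + w2ᵀx1)ᵀ] and are locked in place by a
test that compares the closed form against explicitly filtering the
signals and correlating the outputs (agreement within an O(q/N) edge
term on random instances).

Because the expansion is affine in each weight block, the cost is
minimized by alternating exact least-squares solves of the coupled
normal equations

    w1 = −(ψ1ᵀψ1)⁻¹ ψ1ᵀ (r_x1x2 + [Q⁻_x1x1]ᵀ w2)
    w2 = −(ψ2ᵀψ2)⁻¹ ψ2ᵀ (r_x1x2 + [Q⁺_x2x2]ᵀ w1)

with `ψ` the weight-grouped design matrices.  Each sub-step is the exact
minimizer of its own block, so the cost trajectory is non-increasing on
every run — an invariant the tests assert unconditionally.

### Numerical choices

- **Initialization** `w1 = w2 = 0`: the first predicted cross-correlation
  is exactly `r_x1x2`, giving a deterministic baseline cost.
- **Convergence** when the relative change of `C` between successive
  alternating passes falls below `conv_tol = 1e-4` (0.01%).  Exhausting
  `max_iter` flags `converged = False` on the result instead of raising.
- **Regularization**: the normal equations get a Tikhonov term
  `ridge × mean-diagonal(ψᵀψ)` (default `ridge = 1e-8`).  Scaling the
  ridge by the mean diagonal keeps the solution invariant when both
  inputs are rescaled; an exactly singular system with `ridge = 0`
  raises a numerical error advising a positive ridge.  A zero partner
  signal degenerates gracefully to pass-through (`y1 = x1`, `w1 = 0`).
- **Defaults** `q = 4`, lags `l1 = −25 .. l2 = 25`, `max_iter = 100`:
  desk-scale runs at n = 10⁴ samples converge in a handful of
  iterations, well under a second.

### Identifiability caveat

With two *white* sources of identical (flat) spectra, the lag-0
"rotation" direction of the 2×2 decorrelation criterion is only weakly
constrained by second-order statistics — the classic limitation of
SOS-based separation, which needs spectral diversity to pin down an
instantaneous mixing angle.  In practice the finite-sample cost minimum
can therefore drift along that direction by more than the per-tap
sampling error suggests; the drift shrinks with sample size (the
recovery error reported by `scripts/acceptance.py` is an order of
magnitude smaller at 10× the sample count) and is absent for inputs
with distinct spectra, such as the ECG/audio pairs the pipeline actually
separates.  The implementation has been cross-checked against a
derivative-free minimization of the brute-force cost to confirm the
drift is a property of the objective, not of the solver.

## Template generation

- **Binarization**: `bit_k = 1` iff `y_k > median(y)`.  The median
  threshold yields balanced bits for continuous inputs and is invariant
  to affine rescaling of the separator output (which is only defined up
  to the direct-path convention anyway).  Constant signals are rejected:
  a zero-variance template cannot be scored.
- **Key**: i.i.d. uniform bits, same length as the template, from a
  seeded PRNG (`numpy` PCG64).  Seeding makes enrollments reproducible
  for testing; a deployment should draw keys from OS entropy and manage
  them as credentials, which is out of scope here.
- **XOR**: elementwise; an involution, so the same key re-applied
  recovers the pre-encryption bits.  XOR with an independent uniform key
  whitens the bit stream: templates of the same subject under different
  keys are statistically uncorrelated, which is simultaneously the
  revocation mechanism and the non-invertibility argument (the stored
  bits carry no linear trace of the ECG's sign structure without the
  key).  This is a statistical property, not a cryptographic proof.
- **Output choice**: `y1` by default — the output anchored on the ECG
  observation, so the template is a keyed, distorted ECG rather than a
  distorted audio signal.
- **Store**: one JSON record per enrollment (subject id, key id,
  hex-packed bits — little-endian within each byte — and generation
  parameters including the key seed).  Storing the key seed makes the
  toy verify workflow self-contained; a real system would never co-locate
  key material with templates.

## Matching and evaluation

Bits are mapped {0,1} → {−1,+1} before scoring so balanced independent
templates score near zero; the score is the normalized correlation
(population standard deviations), clipped to [−1, 1].  Verification
accepts on score **strictly greater** than the threshold; the default
threshold 0.5 is the midpoint of the wide band that separates genuine
from imposter scores in the evaluations here.

`build_scores` pools enrollment and probe templates and scores every
unordered pair of distinct templates exactly once; same-subject pairs
are genuine.  The ROC sweeps all distinct scores (plus sentinels beyond
the extremes): `TPR(t)` / `FPR(t)` are the fractions of genuine /
imposter scores ≥ t.  AROC is the trapezoidal area under (FPR, TPR) —
cross-checked against scikit-learn's AUC in the tests — and the EER is
read at the crossing of FAR = FPR and FRR = 1 − TPR, linearly
interpolated between adjacent thresholds because the empirical step
functions need not intersect exactly.

## Synthetic data: what it does and does not emulate

The ECG generator sums one Gaussian bump per P/Q/R/S/T wave per beat on
the grid implied by the heart rate, plus white baseline noise.  Defaults
mirror a common single-lead protocol: 500 Hz, 20 s records (n = 10⁴).
Wave amplitudes (0.15, −0.1, 1, −0.2, 0.3 relative to R), widths
(σ = 20, 8, 10, 8, 40 ms) and offsets (−200, −25, 0, +25, +250 ms from
the R peak) are textbook adult resting-ECG figures; baseline noise is 1%
of the peak amplitude.  The audio generator sums five seeded random
sinusoids with low-pass-filtered noise — an explicitly synthetic
stand-in that claims no acoustic realism, only wide-band structure
uncorrelated with the ECG.

The study population draws per-subject heart rates uniformly from
55–95 bpm and jitters wave parameters (±20% amplitude, ±10% width,
±10 ms offset) per subject; acquisitions of one subject share morphology
and differ only in the baseline-noise realization.  Not modelled:
heart-rate variability within a record, baseline wander, electrode
artifacts, arrhythmia, multi-lead geometry, or any genuine ECG↔audio
correlation.  Consequently a clean synthetic study separates genuine
from imposter scores completely (EER 0, AROC 1); passing it shows the
pipeline's bookkeeping and key-whitening work, not that the method
reaches any particular accuracy on real recordings.

A structural property worth knowing: a resting ECG spends more than half
of each cycle on a flat baseline, and the median binarization threshold
lies inside that baseline's noise cloud.  Fresh per-acquisition noise —
of any amplitude — therefore re-randomizes the baseline bits, which
caps genuine scores well below 1 (around 0.45–0.7 here, cf. the
`genuine_mean_clean` and 10 dB gap figures the acceptance script
computes).  Identity information survives in the bits covering the
deflections, so clean populations still separate perfectly; but a
binarization with a dead zone or beat-gated sampling would be needed to
push genuine scores toward 1 under acquisition noise.  The 10 dB AWGN
robustness figure is likewise duty-cycle-limited for the same reason.

## Noise and preprocessing stages

- **AWGN**: noise power = total signal power (mean square) /
  10^(SNR/10); `snr_db = inf` is the documented zero-noise flag.  The
  mean-square reference is the conventional choice; a peak-power
  reference would report substantially milder noise at the same nominal
  SNR.
- **Notch filter**: second-order IIR (`scipy.signal.iirnotch`), default
  50 Hz / Q = 30 for power-line interference; unity gain within 1 dB at
  DC and Nyquist.
- **Length matching**: truncation to the shorter signal, never
  resampling, never altering sample values.

## I/O

CSV is the interchange format: one sample per line, optional single
`fs=<Hz>` header.  Parsing errors name the offending line.  No reader
for binary waveform-database formats is bundled; external records should
be exported to CSV first.

## Known limitations

- Two sources, two sensors only; no frequency-domain separation, no
  handling of more mixtures, and the permutation/scaling ambiguity is
  fixed only by the unit-direct-path convention.
- Key management is simulated (seeded PRNG, seed stored alongside the
  template); there is no cryptographic hardening, fuzzy extraction, or
  formal security analysis.
- The synthetic evaluation protocol (first acquisition enrolls, rest
  probe, all unordered pairs scored) is this package's own; it is not a
  replication of any published dataset protocol.
- Authentication quality on real ECGs is untested here; the PhysioNet
  readers needed for such a study are deliberately out of scope.
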