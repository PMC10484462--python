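# Methods

## Model overview

The package has three layers.

1. **Kernels and the 1D map** (`kernels`, `plasticity`).  BTSP is modelled
   as a per-event update of bounded synaptic weights,
   w ← clip(w + P(1−w) f_P(Δθ) − D w f_D(Δθ), 0, 1).  The spatial kernels
   f_P, f_D are either (a) skew-t temporal kernels (location μ, scale σ,
   skewness λ, ν degrees of freedom, in seconds relative to plateau onset)
   converted to track coordinates at constant running speed v and wrapped
   around the circular track of length L, or (b) the symmetric pair
   f_P = 1 + cos θ, f_D = 1 − cos θ used for all closed-form work.
2. **Trace theory** (`theory`).  Closed-form steady-state moments of the
   learned matrix, the memory-trace amplitude and variance profile as a
   function of memory age η, the SNR-based structural capacity, the
   spatial Fourier statistics of the quenched variability, and the Turing
   threshold of the matched ring model with and without that variability.
3. **Dynamics** (`networks`).  A rate network on the learned matrix with
   transfer function φ (zero below threshold, x² on [0,1], 2√(x−3/4)
   above) and global-inhibition offset W₀, plus the N-discretized ring
   model; bump seeding, slot-averaged amplitude readout, shuffle-null
   thresholds, bisection for bifurcation points, and capacity counting.

A reference implementation of the eligibility-trace/instructive-signal
biophysical model (`biophys`) serves as ground truth for validating the 1D
map on virtual-track protocols.

## Parameters that matter

| parameter | meaning | default / typical | notes |
|---|---|---|---|
| P, D | potentiation/depression learning rates | 0.3/0.3 (cosine), 2.365/2.57 (fitted skew-t) | for cosine kernels and P=D≤½ the update never clips |
| L, v | track length, running speed | 187 cm, 25 cm/s | set the time→phase conversion of kernels |
| N | phase slots (encoded positions) | 32–256 | spatial resolution of the representation |
| M, s | cells per slot, sparseness | varied; sM is the active population per position | capacity grows like ln(sM)/s² |
| W_max, W₀ | weight rescaling, inhibitory offset | 40, −0.25 | w̄ = W₀ + W_max(w − μ_w) |
| I₀ | uniform drive | 0.9 | chosen so the uniform state sits on the expansive branch: r₀≈0.573, φ₀′≈1.51, Turing point 2/φ₀′≈1.32 (the drive is not prescribed by the source material; this value keeps W₁⁰ an order of magnitude supercritical at the reference learning rates) |
| κ | input scaling | sM in simulations; √(sM) when comparing with the SNR theory | |
| τ, dt, T_end | integrator | 1, τ/20, 200τ with early exit at ‖dr/dt‖∞ < 10⁻⁶·max r | halving dt moves steady states < 0.1% |

## Synthetic data

All inputs are generated: virtual-track lap protocols (plateau positions
per lap) and environment sequences.  An environment is an independent
uniform permutation of the M·N cells over N phase slots (global remapping;
exactly M cells per slot) plus an i.i.d. Bernoulli(s) activity mask.  Each
environment draws from its own RNG sub-stream so a sequence can be
extended without reshuffling its history.  What this emulates: one-shot
plasticity per environment, statistically equivalent circular
environments, ideal place-field tiling.  What it does not: irregular
tiling and field widths, correlated environments, variable running speed,
multi-lap online dynamics, and any interaction between recall activity and
further plasticity.  Passing tests therefore validate the mathematics of
the idealized model, not quantitative predictions for real recordings.

## Estimators

* Ordered trace statistics restrict to cell pairs active in the probed
  environment, exclude self-connections, and bin by the N discrete phase
  differences.  The amplitude is the first cosine coefficient obtained by
  least squares of the binned mean profile on {1, cos, sin}: identical to
  the discrete Fourier coefficient 2⟨cos Δθ·w⟩ when all bins are
  populated, and unbiased at M = 1 where the Δθ = 0 bin contains only the
  excluded self-connections.
* At M = 1 the sampled phase differences exclude Δθ = 0 altogether, which
  shifts the effective kernel moments by O(1/N); `grid_kernel_moments`
  provides the exact discrete moments (with the grand mean then matching
  simulation to machine precision).
* Bump amplitude is the first-Fourier-mode modulus of the slot-averaged
  steady-state rate profile (empty slots dropped).  The bump threshold is
  max(5 × shuffle-null, 0.1 × r₀): the factor 5 clears the extreme-value
  tail of the null across hundreds of orderings at desk scale (the null
  scales ∝ 1/√(sMN), so a fixed multiple larger than ~6 would reject
  genuine bumps at small scale), and the absolute floor keeps numerically
  uniform states from registering.  Both knobs are exposed
  (`threshold_factor`, `min_rel_amplitude`).
* Capacity is reported as the retrievable/non-retrievable boundary age
  located by integer bisection (retrievability is monotone in age up to
  boundary noise); retrieval additionally requires the state to be a bump
  in exactly one stored ordering.

## Quenched noise and the ring reduction

The ring model matched to age η uses W₁^η = W_max (sM/κ) a_η and additive
quenched connectivity noise of standard deviation W_max (sM/κ) √V_η(Δθ).
Measured slot-level disorder of learned matrices matches this scale well
at desk size: it is dominated by binomial slot-occupancy fluctuations
(CV = √((1−s)/sM)), which multiply the whole connectivity profile, with
the slot-averaged weight variance V_η/(sM) a smaller contribution.  Both
contributions vanish as sM grows, which is why quenched variability
disappears in the large-population limit for κ = sM.  Because the even
kernels give w_ij = w_ji up to a decaying initial-condition term, matched
ring noise is drawn **symmetrically** by default in comparisons
(`draw_ring_noise(kind="symmetric")`); a circulant option reproduces the
translation-invariant profile assumed by the Fourier-mode formulas, and
an asymmetric i.i.d. option is also available.

The Fourier statistics of a noise profile √V(θ)·z(θ) on N grid points are
var(α₁) = (A+3C/4)/2N, var(β₁) = (A+C/4)/2N, var(α_{j≠1}) = (A+C/2)/2N,
lag-1 covariance B/4N, lag-2 covariance C/8N.  The expected first-mode
modulation ⟨R⟩ = E[2√(α₁²+β₁²)] is computed by a 1D angular quadrature
over the two (unequal) variances — exact, with the Rayleigh closed form
recovered when they are equal.  The noisy Turing threshold is
2/φ₀′ − ⟨R⟩.  Empirically the shift is robust for pair-wise (and
symmetric) noise, where the bump can lock to the most assistive location;
for strictly circulant noise the linear first-mode shift is
sign-symmetric across realizations and the mean onset moves much less.

## Numerical choices

* Skew-t density via scipy's Student-t pdf/cdf (ν need not be integer);
  wrap sums truncated when the enclosed temporal tail mass is below
  `wrap_tol` (default 10⁻⁸), capped at 10⁴ terms.
* Circular moments by trapezoid rule on a uniform periodic grid
  (spectrally accurate); closed forms for cosine kernels.
* Skew-t kernels are kept in temporal-density units (s⁻¹) by default, so
  the fitted learning rates P, D ≈ 2.4–2.6 produce peak one-shot weight
  changes of ≈ 0.55 from w = 0, matching the biophysical model; a
  unit-peak normalization is available.
* Biophysical model: explicit Euler at dt = 10 ms; ET and IS are
  first-order low-pass filters of normalized input rate and plateau
  indicator, each rescaled to unit peak within a lap so their product
  lives on the [0,1] domain anchoring the normalized sigmoid gains.  The
  exact trace kinetics of the original model are not public in detail;
  this stand-in is validated through the map-comparison harness
  (Pearson r ≈ 0.997 on the position × initial-weight grid).
* Turing points by bisection with two classifiers: `growth`
  (amplitude of a small seed grows ×3 — an unbiased probe of linear
  stability, used for clean rings) and `amplitude` (final amplitude above
  0.25 r₀ — the operational notion for noisy rings, where the uniform
  state is never exact).
* Degenerate inputs: slots with no active cells are flagged missing (never
  zero-filled); environments with all-zero masks leave the matrix
  untouched; ⟨F²⟩ ≥ 1 (non-contracting map) raises instead of returning a
  spurious steady state.

## Problem sizes

Desk-scale defaults throughout: steady-state and trace validation at
N = 64–128 with up to 20 replicates; ring experiments at N = 64–128;
network-vs-ring comparison at N = 128, M = 60, s = 0.1, n = 500 (the
sparse-coding regime, at half the spatial resolution of the full-scale
study); capacity-vs-resolution sweep at sM = 6 (s = 0.2, M = 30),
W_max = 8, N ∈ {8, …, 128}.  W_max = 8 places the large-N capacity in the
regime where the Turing crossing, rather than the N-independent trace-SNR
floor, is binding — the regime in which quenched variability visibly
assists bump formation as N decreases.  The full test suite runs in about
four minutes on one CPU.

## Known limitations

* The variance recursion (A_η, B_η, C_η) is implemented for the cosine
  kernel pair only; general kernels get the trace amplitude via the
  kernel-projection formula but no variance profile.
* The network's bump amplitudes exceed the Gaussian-noise ring model's by
  ~3–5% at small η at desk scale: the learned disorder is structured
  (shared-cell correlations, occupancy fluctuations) and assists bumps
  slightly more than i.i.d. noise; the exact slot-level projection of the
  learned matrix tracks the network much more closely.
* Asymmetric (temporally causal) BTSP rules, sequence/dynamic attractors,
  amplitude equations for the weakly nonlinear branch, and interleaving of
  recall dynamics with further plasticity are out of scope.
* The mixed-attractor regime (s ≳ 0.3) is characterized only by existence
  checks (states supra-threshold in ≥ 2 orderings), not by a theory.
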