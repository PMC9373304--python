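# Methods

## Model and assumptions

A bleach stack is treated as observations of a linear time-invariant
system: each flattened frame advances by a fixed operator,
x_{k+1} = A x_k. Pure mono-exponential photobleaching at a finite set
of rates satisfies this exactly — each kinetic component contributes
one real eigenvalue λ = exp(−k·Δt) — and small periodic specimen
motion appears as complex-conjugate eigenvalue pairs rather than
corrupting the decay estimates. The decomposition assumes a constant
frame interval Δt, a static region geometry over the movie, and decay
kinetics well approximated by a low-rank sum of exponentials. It is
*not* a model fit: with a truncation rank below the number of true
kinetic components, the recovered rates are weighted mixtures and are
expected to deviate from the underlying rate constants by a few
percent to tens of percent, most visibly for the fastest component.

## Exact DMD implementation

* Reshaping is row-major per frame; columns of the space–time matrix
  are frames in acquisition order. The reshape is exactly invertible.
* The SVD of X₁ is the deterministic economy-size LAPACK SVD (no
  randomized variant), so repeated runs are bit-identical.
* Automatic rank selection uses the optimal singular-value hard
  threshold for unknown noise: τ = ω(β)·median(σ) with
  ω(β) = λ*(β)/√μ_β, where β is the aspect ratio of X₁, λ*(β) the
  known-noise threshold coefficient and μ_β the Marchenko–Pastur
  median computed by quadrature. Singular values below 10⁻¹²·σ₁ never
  count (and are likewise excluded from the pseudoinverse); a
  user-supplied rank always overrides.
* Modes are the *exact* modes Φ = X₂V′Σ′⁻¹W, normalized to unit column
  norm with the scale folded into the amplitudes, so reconstructions
  are invariant to the normalization.
* Amplitudes solve Φb = x₁ in least squares, anchoring the expansion
  at the first snapshot; the discrete form λ^(k−1) is used at sample
  times (the continuous form e^{ωt} agrees there and is exposed only
  through ω itself).
* Mode order is deterministic: oscillatory modes first (descending
  |Im ω|, +Im member of each conjugate pair first), then the rest by
  descending Re ω (slowest decay first). Eigensolver output order is
  not reproducible across platforms, so tests and users should match
  modes by eigenvalue, not position — the fixed sort merely makes a
  given machine's output stable.
* Phase convention: each mode/amplitude pair is flipped so Re(b) ≥ 0.
  Eigenvectors are phase-ambiguous; only products φ_j·b_j matter. For
  thresholding, the orientation-invariant *contribution map*
  Re(φ_j·b_j) (the mode's share of the first frame) is used, which is
  positive in contributing regions under any phase convention.
* The principal complex logarithm defines ω = log λ/Δt; oscillations
  faster than π/Δt alias.

## Synthetic bleach stacks

The generator emulates a standard validation movie: an 8-bit
160×120-pixel stack, 100 frames at Δt = 1 s, with a rectangle (10 px
margin) of initial mean 190 enclosing a non-overlapping circle
(r = 18 px) and ellipse (semi-axes 26 × 13 px), also at 190, over a
background of mean 10; the three regions bleach mono-exponentially at
0.01, 0.05 and 0.15 s⁻¹. Regions are listed outer-to-inner; an inner
region overrides the pixels it covers, and partially overlapping
regions are rejected. Ground truth consists of the disjoint region
masks (outer minus inner) and the per-pixel rate map.

Noise is photon shot noise by default: each pixel is an independent
Poisson draw with mean F(p)·exp(−k(p)·t), where F is 190 in the
regions and 10 in the background, then clipped to the bit range. The
background is modelled as dim fluorescence from the same bleachable
pool as the specimen and fades at the base (slowest region) rate. This
choice is deliberate: it keeps the stack's temporal structure at
exactly one component per decay rate, which is what makes automated
rank selection return the number of kinetic species and keeps the
mode-weight histograms cleanly bimodal. A *static* noise floor of
nonzero mean is itself a fourth space–time component: with
`background_rate=0` (or the additive constant-floor Poisson and
uniform noise options, which are also provided) the automatic rank
rises by one and the extra component bleeds measurably into the
rank-3 mode maps — useful for studying exactly that failure mode, but
not the clean validation condition. A noiseless mode rounds the
expected intensities directly.

What the generator does **not** emulate: optics (PSF blur, uneven
illumination), sample drift, detector read noise or gain, partial-
volume effects at region boundaries (masks are hard), and multi-
channel acquisition. Passing tests on these stacks therefore
demonstrates correctness of the decomposition and segmentation
machinery under shot-noise-limited, motion-free conditions, not
robustness to optical artefacts.

## Segmentation and scoring

All histogram thresholds are delegated to `skimage.filters` with 256
bins over the map's min–max range (Li and Mean operate on raw values).
Foreground is strictly above the threshold. The Minimum method
iteratively smooths the histogram with a 3-tap mean until exactly two
maxima remain and takes the valley between them; failure to reach
bimodality raises, as does a constant map. Multi-class Otsu maximizes
between-class variance over the requested class count. Jaccard and
Dice are defined as 1 when both masks are empty and 0 when exactly one
is; `evaluate_modes` matches each decaying mode to the ground-truth
region of maximal Jaccard, since mode numbering is solver-dependent.

One caveat found while validating: on maps whose off-region cluster is
nearly noise-free (a huge, tight histogram spike), Yen's entropic-
correlation criterion places its threshold inside the spike's tail and
annexes several hundred background pixels (J ≈ 0.7 where
valley-seeking methods reach 1.000); Otsu's discrete argmax can
likewise sit one bin into the tail and admit a single stray pixel
(J = 0.999). These are properties of the criteria on spike-dominated
histograms, not implementation defects.

## Pixel-wise decay fitting

The comparator fits I(t) = A·exp(−(t/τ)^h) + C per pixel, h ≡ 1 for
mono-exponential and h ∈ (0.1, 4] for stretched. Bounds: A, C ≥ 0,
τ ∈ [Δt/10, 100·m·Δt]; first frame is t = 0.

The stack fitter profiles the nonlinear parameters on a grid — 96
log-spaced τ values (48 × 12 (τ, h) cells for stretched), solving the
2×2 linear system for (A, C) in closed form for all pixels
simultaneously — and polishes the best cell with a vectorized damped
Gauss–Newton in (A, log τ[, h], C), accepting per-pixel steps only
when they lower the SSE. The global grid stage exists because local
least squares from heuristic initial guesses degenerates on low-SNR
traces into a spike at the τ lower bound (rate pinned at its maximum),
which stretches the rate-map histogram and destroys downstream
thresholding. The stretched fit also evaluates the mono optimum at
h = 1 and keeps whichever is better, so stretched RMSE never exceeds
mono RMSE. `fit_pixel` adds a bounded `scipy.optimize.least_squares`
polish for full single-trace precision.

Pixels whose bleach amplitude — mean of the first five frames minus
mean of the last five — is below twice a robust noise floor
(1.4826·median|ΔI|/√2 across successive frames, floored at 0.5, the
quantization granularity) are marked non-bleaching without fitting, as
are pixels whose *fitted* amplitude falls below the same bound; both
carry A = 0, C = trace mean, rate 0. A plain max–min range test cannot
flag pure-noise traces (the range of 100 noise samples exceeds any
2σ bound), hence the first-minus-last form. On noiseless 8-bit data
the per-pixel least-squares optimum itself is biased by quantization
by up to ~1% in rate (verified against an independent unbounded
fitter); unquantized traces are recovered to optimizer precision.

## Problem sizes and determinism

Default analyses run on the 160×120×100 stack (19 200 pixel traces);
the test suite uses that stack where the published numbers demand it
and 48×36 stacks elsewhere. All randomness flows from a single integer
seed through `numpy.random.default_rng`; identical configurations give
bit-identical stacks, decompositions and metric tables.

## Known limitations

* Rank-3 rate estimates are biased relative to the simulated constants
  (≈ −0.010/−0.053/−0.157 for 0.01/0.05/0.15 s⁻¹); this is inherent to
  describing all pixels as one linear system and is why the pixel-wise
  fitter is kept as the unbiased (but segmentation-weaker) comparator.
* No motion correction: drift is absorbed into oscillatory modes and
  classified, not removed.
* No bi-exponential pixel model (known to be unstable at low SNR) and
  no rate-distribution models.
* Streaming/compressed/randomized DMD variants and control inputs are
  out of scope; stacks must fit in memory as float64.
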