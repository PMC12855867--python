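# Methods

This note documents the models, parameter choices and numerical decisions
behind `plasmonet`, in the order data flows through the package.

## Sensor optics (transfer matrix)

Reflectivity of the planar multilayer is computed with the 2×2
characteristic-matrix (Abelès) formalism. Conventions: indices are
n + ik with k ≥ 0 for absorbing media under the e^{−iωt} time convention;
the longitudinal wavevector takes the Im ≥ 0 branch so evanescent and
absorbed waves decay. Layer admittances are k_z/(k₀n²) for p-polarisation
and k_z/k₀ for s. The default interface model at λ = 690 nm is

| layer | n | thickness |
|---|---|---|
| glass | 1.5133 | semi-infinite |
| gold | 0.13322 + 3.9722i | 50 nm |
| medium gap | 1.3350 | 50 nm |
| membrane | 1.4985 | 7.5 nm |
| cytosol | 1.36 | semi-infinite |

with the background stack ending in semi-infinite medium after the gold.
Fabricated sensors of this kind often carry a ~50 nm ITO adhesion
underlayer between glass and gold; the default simulation omits it (it is
an adhesion aid, not part of the optical design, and which variant a given
published curve includes is not always stated), but
`cell_stack(include_ito=True)` adds it. Only p-polarisation excites
surface plasmons; s-polarisation is kept as the no-resonance control.

Numerical choices: curves are sampled on a closed uniform grid (default
65°–80°, 0.01°); the derivative uses second-order central differences;
minima are located by grid argmin plus local quadratic refinement
(sub-grid accuracy, validated against the closed-form two-media dispersion
angle to < 0.01°). The operating angle is the reflectivity crossing between
the two minima; crossings landing exactly on a grid node are accepted, and
candidates where either derivative is below 10⁻⁴ per degree are rejected
(both gradients must be functional). Identical curves raise an error.

## Synthetic recordings

No raw movies are distributed with the imaging study, so the generator is
the package's test bed. It is the *minimal* structure reproducing the
reported phenomenology, not a biophysical model:

    s_i(t) = A_cond · A_i · b_i(t) · (1 + m·cos θ_i(t)) + σ·ξ_i(t)
    dθ_j/dt = 2π(f + df_j) + κ Σ_i w_ij sin(θ_i − θ_j) + √(2D(t))·η_j(t)

- **Burst envelope** b_i: raised-cosine-edged square wave (default rate
  0.05 Hz, duty 0.5, per-cell onset jitter ±0.2 s), with an optional floor
  so plateau phases keep a residual oscillation. A condition listed in
  `burst_suppressed_conditions` pins the envelope at the floor — the
  generator's rendering of calcium-channel block abolishing bursting.
- **Phases**: Kuramoto oscillators at f = 5 Hz (inside the 1–15 Hz network
  band), Euler–Maruyama at the sampling step (fs = 100 Hz ≫ dynamics;
  steps with κ·max in-strength/fs > 0.1 are rejected as unstable).
  `w_ij` is the directed influence of cell i on cell j and doubles as the
  ground-truth adjacency. Per-cell frequency detuning `df` gives directed
  edges a reproducible lead–lag sign: with symmetric dynamics the
  stationary phase-difference distribution is symmetric and the mean-vector
  angle carries no information, so a faster upstream cell is what makes
  "i leads j" well defined. `burst_phase_noise_boost` multiplies D inside
  bursts, producing burst-synchronised but spike-incoherent activity (ACC
  high while PLF dips — the amplitude/phase dissociation).
- **Transduction**: I_roi = I₀(1 + g_roi·s_roi) with opposite-sign
  gradients for cells and background (defaults ∓0.5), so a shared
  resonance shift yields anticorrelated intensities. Background ROIs are
  Dirichlet-weighted mixtures of the noiseless cell sources plus their own
  sensor noise, reflecting the interference interpretation of extracellular
  signal rather than independent oscillators. The linearisation was checked
  against the full transfer-matrix reflectivity at the operating angle:
  relative error < 0.5% for medium index shifts up to 10⁻⁴.
- **Scene rendering**: pixel = baseline + Σ_i K_i(x)·g(x)·s_i(t) + noise,
  K_i = 1 inside cell i and Gaussian (default 5 µm scale) outside; the
  default scene is six 7–8 µm cells on an 85 µm × 91 µm field at 1 µm
  pixels (7735 grid channels).
- **Patch traces**: renewal event times (refractory 50 ms + exponential
  gap chosen so the *realised* event rate equals the requested spikes/s,
  matching how firing rates are reported), downward Gaussian deflections
  (amplitude 3 pA, FWHM 2 ms by default) on zero-median noise at 10 kHz.
  A quoted action-current width of 0.02 ms is sub-sample at 10 kHz
  digitisation and is treated as a suspected typo for 2 ms; both widths
  are accepted via config. Default noise is **uniform** (bounded support):
  with Gaussian noise the baseline − 3×MAD threshold sits near 2σ and any
  sampling rate produces a large background crossing rate, which is a
  property of the rule, not the detector implementation; a `gaussian`
  option exists to study exactly that failure mode.

What the generator does *not* emulate: ion-channel biophysics, electrode
double layers, slow drift, photobleaching, mechanical/perfusion artifacts,
or spatially heterogeneous gradients within one cell. Passing tests
therefore certify the estimators under the stated statistical structure,
not performance on arbitrary real recordings.

## Preprocessing

Band-pass filtering is a 4th-order Butterworth applied forward–backward
(zero net phase, |H|² magnitude; odd-reflection padding sized from the low
band edge). Named presets: 1–15 Hz (network analysis), 0.1–15 Hz
(condition-amplitude and field-potential analysis) with 0.1–1 / 1–10 /
10–15 Hz sub-bands, and 0.1–5 Hz (calcium imaging). The band is an
explicit parameter of every stage because the two analyses legitimately
use different bands. Envelope smoothing is a centred moving average with
edge-truncated windows (default 1 s — the window is otherwise unspecified
upstream, so results that depend on it carry it as a parameter).
Condition standardisation divides each cell by the standard deviation of
its concatenation across all conditions. Downsampling strides for integer
ratios (caller has already band-limited) and uses a polyphase rational
resampler otherwise. An all-zero trace has an undefined phase and is
flagged, not silently zeroed.

## Connectivity and surrogates

Estimators follow the definitions in the README. Decisions the definitions
leave open:

- **Window handling**: traces are filtered once over their full length,
  then windowed (10 s, 1 s step), avoiding per-window filter transients;
  the Hilbert decomposition is computed per window. N = window length × fs.
- **Directed tie rule**: mean-vector angles of exactly 0 or π zero both
  directions. The lead/lag sign convention (positive angle of
  ⟨e^{i(θ_i−θ_j)}⟩ means i leads j, edge i→j) is documented and consistent
  between the generator and the estimator.
- **Surrogate pairing**: the k-th surrogate of channel i is compared with
  the k-th surrogate of channel j; each channel's surrogate destroys
  cross-channel phase structure while preserving its own spectrum. A fresh
  ensemble (default 99) is drawn per window; retention requires strict
  exceedance in ≥ ⌈level·n⌉ ensembles (95 of 99). Fewer than 20 surrogates
  triggers a warning (the null is under-resolved).
- **IAAFT convergence**: the iteration alternates spectrum matching and
  rank ordering, ending on rank ordering (exact value multiset). A
  surrogate retires when its spectrum mismatch stops improving by > 1% per
  sweep — the empirical fixed-point criterion; the residual relative RMS
  magnitude mismatch at the fixed point scales roughly as 1/N (~3×10⁻³ at
  N = 1000). When a tighter spectrum is required, `refine_surrogate`
  anneals over swaps of rank-neighbouring values (small spectral moves,
  geometric cooling, multiset preserved) down to a requested tolerance
  (10⁻³ at N = 1000 in ≈ 10 s). The significance filter uses the plain
  IAAFT fixed point: the null only needs spectrum-preserving,
  cross-structure-destroying permutations, and the residual is immaterial
  there.
- **Degenerate nulls**: surrogates of tones commensurate with the sampling
  grid can reassemble an exactly locked tone (the multiset is periodic), in
  which case strict exceedance cannot distinguish signal from surrogate;
  any incommensurate frequency or additive noise removes the degeneracy.
- **Aggregation over windows**: when a single recovered adjacency is
  needed, an edge counts as present if it is retained in > 50% of windows.
  At the 95% level each window retains a false edge with p ≈ 0.05, so
  per-window degree-0 claims cannot hold over many windows; the consensus
  rule makes "silent node disconnected" a stable statement.
- **Renormalisation**: mean off-diagonal strength per window, min–max
  scaled jointly over all windows and conditions supplied; a degenerate
  range (max = min) is an error, not a silent 0/1.
- **Zero-variance channels**: Pearson/ACC rows are zeroed and the channel
  reported; global–local maps mark them NaN (undefined, not zero).

## Events and statistics

Baseline = median, noise = raw MAD by default ("3 × noise" is read
literally; the 1.4826 Gaussian-consistency factor is an option). Events are
below-threshold excursions; an excursion starting within the 50 ms
refractory of the current event *merges* into it and the event follows the
deepest point — noise fragments a single deflection into several crossings,
and first-crossing semantics would mis-time such events. Event time is the
excursion minimum; amplitude is extremum − baseline. Detection is invariant
under positive affine maps of the trace. A zero-MAD trace demands an
explicit noise floor. Windowed rates count events in [t, t + 10 s) every
2 s. Condition comparisons use paired t-tests with Bonferroni adjustment
(p_adj = min(1, p·m)); zero-variance differences are reported as undefined
rather than given a fabricated p-value.

## Pipeline

One master seed fans out to per-stage generators through fixed
`SeedSequence([seed, stage_id])` counters, so stages are individually
reproducible and a rerun of the same config is byte-identical. Every run
writes a JSON manifest (package version, full config, band, conditions).
The demo scenario uses six cells in a feed-forward chain with downstream
detuning, cell 5 silent, amplitudes (1, 2, 0.3) for baseline/glucose/
nifedipine, nifedipine decoupled and burst-suppressed, and intra-burst
phase-noise boost 8 — the configuration under which amplitude and phase
coupling visibly dissociate.

## Problem sizes

The test suite and acceptance script use desk-scale sizes chosen to keep
runs fast while leaving comfortable statistical margins: null calibration
uses 120 window×seed replicates of six white-noise channels (bound
0.05 + 3·√(0.05·0.95/120) ≈ 0.11); parameter recovery uses a 30 s
recording (21 windows); phenomenology uses 60 s per condition (51
windows); detector statistics use 100–300 s segments at the published
condition rates (0.88, 1.57, 0.26 spikes/s) as generator inputs.

## Known limitations

- The optics module is a 1-D planar model: no objective/beam vectorial
  effects, no surface-plasmon propagation anisotropy, no intensity →
  resonance-angle inversion.
- The generator's phase dynamics are first-order Kuramoto with white phase
  noise; real bursting electrophysiology has relaxation structure the
  model does not attempt.
- Directed PLF orientation requires a frequency asymmetry (or any
  mechanism producing a consistent mean lag); for identical oscillators
  with symmetric noise the direction of an edge is undefined in principle.
- The significance filter calibrates the pairwise null; it does not
  correct for multiple comparisons across edges or windows.
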