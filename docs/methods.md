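# Methods

## Physical setting and scope

The package models 3D excitation of a liver-sized region at 7 T with a
remote 32-element transmit body array.  Everything operates on *relative*
channel-wise B1+ maps (no absolute µT/V calibration), in the small-tip-angle
regime around a 10° nominal flip, and with off-resonance neglected: the
total pulse length is held near 1 ms precisely so that ΔB0 phase accrual
between subpulses stays negligible, which is why no B0 map enters the
design.  Image reconstruction, respiratory handling, electromagnetic body
simulation, and scanner safety hardware are all out of scope; the per-channel
power limits and VOP-based local-SAR metric are implemented as evaluation
checks in relative units.

## Synthetic data model

**Phantom.** An elliptic-cylinder body (transversal semiaxes 80 × 60 mm on
the default 48 × 48 × 40 grid at 4 mm isotropic — the resolution of the
relative-mapping scan) with an ellipsoidal, right-offset liver-like ROI
(semiaxes 38/42/55 mm, ≈0.37 L, ~5 700 voxels).  Coordinates are
isocenter-origin, meters, right-handed, voxel-centered.  The ROI center is
jittered ±3 mm per seed to emulate subject variability.  Channel numbering
is 1-based at interfaces (matching scanner conventions), 0-based internally.

**Element fields.** Element e at position p_e on three rings of 10/12/10
elements (radius 320 mm, ring offsets ∓110/0 mm — a remote array, well
outside the body) contributes

    map_e(r) = d^{-1} · exp(−d/λ_att) · exp(−i·2π·d/λ_RF + iφ_e) · s_e(r),

with d = |r − p_e|, in-tissue RF wavelength λ_RF = 130 mm, amplitude
attenuation λ_att = 220 mm, and a seeded per-element phase offset φ_e
(cable/feed variation).  s_e(r) = exp(ρ(g_re + i·g_im)) is a per-element
smooth complex log-normal modulation (unit-variance Gaussian fields with
15 mm correlation length, ρ = 0.7) standing in for the scattering and
standing-wave structure that differentiates measured in-tissue element
fields on the half-wavelength scale.  Without s_e the geometric fields are
so regular that 28 static degrees of freedom co-phase them almost perfectly
(ROI CV below 1%), a regime measured torso maps do not exhibit; with it the
default phantom lands where body pTx operates in practice: zero-phase CV
≈ 0.5 with hundreds of sub-half-median dropout voxels, phase-only shim CV
≈ 9–13%, magnitude+phase ≈ 6%, 2 kT-points ≈ 4–5% at matched power, and
8-group phase shimming ≈ 22–31%.  These levels were fixed once from a
realism scan across seeds; they are qualitative stand-ins, not fits to any
measured dataset.  The whole map set is normalized so the ROI-median
root-sum-of-squares is 1 (relative units).

**What the generator does not emulate.** Full-wave electromagnetics (no
conservation or reciprocity constraints), realistic organ geometry, B0
structure, respiratory motion, RPE undersampling artifacts, or coupled
element behavior.  Consequently, passing the directional checks here shows
the *machinery* behaves correctly (estimators invert their forward model,
optimizers beat their baselines, more channels/subpulses help), not that any
specific in vivo CV value would be reproduced.

**Calibration scan.** n+2 complex GRE images: all channels on (equal
magnitude, zero phase), all off (noise only), then each channel alone:

    I(r) = R(r) · sin(α(r)) · e^{i·arg B(r)} + n(r),  α = flip_scale·|B(r)|,

with a smooth two-lobe receive profile R and i.i.d. complex Gaussian noise
(σ per component).  A guard rejects flip scales whose peak flip violates
sin(α) ≈ α beyond 1% (≈14°); analyses here use a 5° peak.

**VOPs.** Random rank-3 Hermitian PSD matrices Q_v, each scaled so the
median of b^H Q_v b over random unit-norm b is 1, giving a common relative
scale.  They stand in for body-model-derived VOP compressions; 157 matrices
mirrors that scale of compression.

## Relative-map estimation

    map_ch(r) = (I_ch(r) − bias) / Σ_ch' (I_ch'(r) − bias)

Any common complex factor — notably the receive profile — cancels in the
ratio; in floating point the cancellation is exact up to rounding (~1e−10
absolute), which is what the tests assert.  `bias` is the complex spatial
mean of the all-off image: zero for noiseless data, and an estimate of any
DC offset otherwise.  (Subtracting the all-off *magnitude* mean instead
would inject a real-axis offset, since zero-mean complex noise has a Rayleigh
magnitude mean; the complex mean is the bias-free choice.)  Normalizing by
the channel sum rather than the all-on image makes Σ_ch map_ch = 1 an exact
invariant at every valid voxel.  Voxels with |denominator| below
`noise_floor_factor` (default 3) times the all-off noise estimate are masked
invalid and excluded from every downstream ROI statistic.

For noisy stacks an optional isotropic complex Gaussian pre-filter
(`smooth_sigma_vox`) is applied to all images before the ratio.  The filter
width was set by a bias/variance scan on the default generator: 0.6 voxels
minimizes the total median error (≈4% of the ROI-median channel magnitude at
per-image SNR 20, vs ≈8% unsmoothed; noiseless bias ≈3%).  The default is 0,
keeping the ratio exact.

Dead channels are detected as channels whose ROI-median relative magnitude
falls below `noise_floor_factor` times the recorded ratio-noise level
(σ̂ / median |denominator|) — i.e. channels whose "map" is statistically
indistinguishable from noise over the denominator.  Detection degrades when
a live channel's share (≈1/n_channels) itself approaches that noise level,
i.e. at very low calibration SNR.

**Reference basis for design.**  Sum-normalized maps satisfy Σ_ch map_ch = 1
at every voxel, so their equal-weight combination is flat *by construction*
and cannot be shimmed meaningfully: the true field is map_ch times the
structured, dropout-carrying channel sum.  Before any shim or pulse design,
the maps are therefore re-expressed with the per-voxel root-sum-of-squares
as the reference (`rsos_basis`): dividing each channel by RSoS(map) yields
B_ch / RSoS(B) exactly — a pure change of reference with no new unknowns —
whose denominator is smooth and interference-free, so the full zero-phase
interference structure (CV, dropouts) survives and designs homogenize the
flip angle relative to a smooth envelope.  This is also the image on which
the ROI is drawn.

## Static shimming

Cost = CV − w·η over the ROI, with w = 0 by default: the reported outcomes
are CV-based, and η is logged alongside.  Phase-only mode constrains equal
magnitudes on active channels; magnitude+phase optimizes log-magnitudes too
(positivity built in).  Optimization is L-BFGS with analytic gradients from
100 pseudo-random phase starts (start 0 is always the zero-phase shim;
an optional injected start lets the magnitude+phase run begin at the
phase-only solution, which guarantees the nested feasible set can only
improve).  Both CV and η are invariant under a global phase and positive
rescaling, so solutions are gauge-fixed (first active channel real-positive)
and normalized to a requested total power.  ROIs above 4 000 voxels are
deterministically subsampled inside the optimizer; all reported metrics are
recomputed on the full ROI from the returned weights.

## kT-point design

**Units.** A single scalar (10°/unit field/ms by default) converts relative
field × duration to degrees; weights and powers are in relative units
throughout.

**Timing.** Multi-point pulses split a 920 µs on+blip budget: subpulse
duration = round((920 − (n−1)·80)/n) µs, giving 420/253/170/120/87 µs for
2–6 points (round, not floor — 86.67 → 87); the single-subpulse static case
uses the full 1 000 µs.  Blips are ideal instantaneous k-space jumps
contributing time but no RF.

**Solver.** Variable exchange for the magnitude target: with the target
phase θ fixed, the ridge solve (AᴴA + βI)⁻¹Aᴴ(m_d e^{iθ}) is closed-form;
θ is then replaced by the phase of Ab.  Both half-steps decrease the joint
objective, so the trace is asserted monotone.  θ converges slowly
(O(100) iterations) and the zero-phase-field initialization is a poor
attractor on dropout-laden maps, so designs run from multiple random
target-phase starts (the multi-start layer) and keep the best final
objective.  A singular β = 0 system falls back to a tiny ridge with a
warning.

**Placement.** Greedy: starting from the k-space origin (which is always
kept and played last), repeatedly add the candidate from a symmetric 7×7×7
Cartesian grid spanning ±π/(2·ROI extent) per axis whose re-solved weights
most reduce the objective; candidate scoring uses two warm-started exchange
iterations via incrementally assembled Gram blocks (τ²·Bᴴdiag(e^{iΔk·r})B),
so the tall matrix is never rebuilt per candidate; ties break toward smaller
‖k‖.  Local: finite-difference gradient descent with backtracking on the
non-origin locations, clipped to the grid extent, re-solving weights after
every accepted move; when a power target is set, β is updated
multiplicatively every 50 iterations toward it.  Dead-channel columns are
removed before solving and zeros re-inserted on output.  Design solves may
subsample the ROI to 3 000 voxels (seeded); metrics are recomputed on the
full ROI.

**L-curves.** 27 log-spaced β in [1e−10, 1e3] by default, swept descending
with the k-locations and target phase warm-started from the previous β;
every stored (power, CV) pair is recomputed from the stored pulse.  Warm
starting changes the local optimum slightly: at sampled β the CV agrees with
an independent cold design to well under 2% at the modest refinement depths
used.  At very small β the fit can overfit the design subsample, so the
low-β branch is flat rather than strictly decreasing in CV.

**Matched-power comparisons.** The reference power is what the phase-only
shim needs to produce the 10° mean ROI flip; the kT design is matched to it
by bisecting β (warm-started, ~10 solves) rather than interpolating the
L-curve, which is more robust near the steep branch.

## Evaluation

The Bloch oracle integrates rigid rotations at a 1 µs raster per voxel
(RF rotation about the in-plane axis at the field's phase; inter-subpulse
z-rotation by (k_j − k_{j+1})·r), with FA = arccos(M_z).  It is independent
of the linearization: small-tip predictions agree to ~0.02% median at 10°
and the oracle reproduces the sin(θ)/θ transverse shortfall at 90°.
Integrated RF power is Σ|b|²τ (blips contribute nothing).  Relative peak
local SAR is the subpulse-duration-weighted time average of b_jᴴQ_v b_j,
maximized over VOPs and scaled by duty cycle.  Channel grouping sums member
maps with zero relative phase and sums their power budgets, so the total
available power is constant across 8/16/20/32-channel configurations; the
8/16/20 memberships are schematic ring-adjacent defaults and are editable.
A per-channel average-power checker mirrors a 6.6 W/10 s and 3.3 W/6 min
supervision policy in relative units.  A SAR-penalized solve variant
replaces the Tikhonov term with a softmax-weighted (log-sum-exp smoothed)
combination of VOP quadratic forms, re-weighted each exchange iteration.

## Numerical choices and degenerate inputs

- Population (not sample) standard deviation in CV.
- All-destructive shims (zero mean field) raise an error rather than NaN;
  zero-denominator voxels in η are excluded with a warning count.
- Complex volumes are stored as magnitude/phase NIfTI pairs (phase wrapped
  to (−π, π]); channel order always comes from the JSON sidecar.
- Angles are degrees at interfaces and radians internally; k in rad/m;
  durations integer µs at interfaces.
- Every random element flows from a named integer seed; pipelines derive
  per-stage seeds from the single config seed, and identical configs
  reproduce all outputs bit-identically.

## Known limitations

- The field model is geometric, not electromagnetic: SAR numbers are
  relative orderings only, and absolute CV levels depend on the roughness
  calibration above.
- Variable exchange finds local optima; reported designs are best-of-starts,
  not global.  The 100 pseudo-random starting phases are screened on the
  cheap origin-only (static) problem and only the best three seed the full
  greedy + local pipeline, trading exhaustiveness for tractability.
- The greedy/local settings (grid extent, step sizes, iteration depths) are
  exposed configuration, and the analysis-scale defaults favor robustness
  over exhaustive refinement; problem sizes used in the shipped analyses are
  the default grid (~5 700 ROI voxels), 100 shim starts, and 100 screened /
  3 retained design starts with 5 refinement iterations per β.
- The estimator's pre-smoothing trades a small structural bias for noise
  suppression; with it disabled the estimator is exactly unbiased but ~2×
  noisier at SNR 20.
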