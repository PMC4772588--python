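# Methods

## The measurement problem

FM1-43 partitions into recycling synaptic vesicles; on depolarization the
dye is released and a bouton's fluorescence drops by a fraction that
reports its exocytic activity. The analysis task is: given a single-channel
time-lapse (baseline frames, then a stimulation window), find the boutons,
reject mobile trafficking organelles, extract each bouton's
baseline-normalized intensity trace, split the population into weak and
strong unloading profiles, and compare destaining rates between groups
(e.g. genotypes). This package implements that pipeline together with a
simulator that provides exact ground truth.

## Simulator

Each frame before noise is

    I_t(p) = bleach(t) · [ B + Σ_i A_i · u_i(t) · G(p; c_i + d_t, σ_i) ]

with background `B`, per-bouton amplitude `A_i`, isotropic Gaussian `G`
evaluated at pixel centres and truncated at 4σ, global drift `d_t` (a 2-D
Gaussian random walk), and `bleach(t) = (1 − r)^t`. The unloading factor
`u_i(t)` is 1 during baseline and decays to `1 − depth_i` across the
stimulation window — linearly by default (reaching the plateau exactly at
the last stimulation frame), or exponentially with time constant
`tau_frames`. Shot noise is Poisson on the clean image, read noise is
additive Gaussian, and the result is rounded to integer camera counts and
clipped at zero, in that order.

Drift is applied *analytically*: every object is rendered at its drifted
sub-pixel centre rather than by resampling a rendered frame. This is exact
(no interpolation blur), and since the background is spatially constant the
two formulations are equivalent for everything the pipeline measures.

Key defaults (all configurable in `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| field, pixel size | 512×512 px, 160 nm/px | conventional widefield camera sampling |
| timebase | 1 frame/s; 30 baseline + 300 stimulation frames | 5-min high-K⁺ depolarization at 1 Hz |
| unloading depths | weak 0.18, strong 0.35 | the two canonical destaining profiles |
| bouton size | full width 300–800 nm, uniform | physiological bouton sizes; rendered σ = size/2.355 (FWHM→σ) |
| amplitude | mean 300, CV 0.2, background 100 | peak SNR ≈ 25 over shot+read noise, typical for FM imaging |
| bleaching | 2×10⁻⁴ per frame | ~6 % loss over a full movie, careful illumination |
| read noise / shot noise | SD 4 / Poisson | sCMOS-like counts |
| trafficking speed | 400 nm/frame, ballistic | guarantees > 500 nm net displacement within 3 frames |
| drift step | 20 nm/frame random walk | a few pixels of cumulative drift per movie |
| minimum separation | 2000 nm | keeps measurement annuli uncontaminated |

The acquisition frame rate, field size and camera model are conventions,
not constraints of the method; none of the acceptance quantities depend on
them beyond SNR.

What the simulator does **not** emulate: optics-accurate PSFs (boutons are
ideal Gaussians), focus drift and z-motion, inhomogeneous background
(neurites, debris), bouton-to-bouton distance below the separation limit,
vesicle-level release stochasticity, and photobleaching that differs
between bound and free dye. Passing tests therefore demonstrate the
*algorithmic* correctness and calibration of the pipeline, not robustness
to every artifact of real recordings.

## Detection

Scale-normalized LoG responses `−σ² ∇²(G_σ * I)` are computed on a
geometric ladder of ≥ 3 scales spanning σ ∈ [300, 800] nm (converted to
pixels; a lower bound under 1 px is rejected as unresolvable). For a
Gaussian blob the response peaks at the blob's own σ with value A/2, so
the reported `amplitude` is twice the best response and `sigma_nm` is the
sub-scale-refined best scale. Candidates are local maxima over the
(scale, y, x) neighbourhood, thresholded at `k × robust SD` of their scale
plane (robust SD = 1.4826 × MAD; default k = 5). The threshold is computed
per scale because smoothing makes the noise variance strongly
scale-dependent, and it is floored at 1 % of the peak response so that the
noise-free limit (MAD → 0) does not promote numerical ripple to
detections; this caps the usable per-frame dynamic range at about 100:1.
Positions are refined by a 3-point quadratic fit in x and y;
non-maximum suppression uses the detection scale as its radius with
deterministic tie-breaking (response, then position).

Note on conventions: the *simulator* treats "bouton size 300–800 nm" as a
full-width scale (rendered σ = size/2.355 ≈ 127–340 nm), while the
*detector's* `sigma_range_nm` is the Gaussian σ of its matched filter
directly. The detector's ladder therefore brackets the rendered sizes from
above; because the LoG response decays slowly in σ-mismatch, recall and
localization are unaffected at the default SNR (measured: recall ≈ 0.99,
precision ≈ 1.0, RMS error ≈ 0.09 px).

Drift is estimated per frame against frame 0 by upsampled
cross-correlation (sub-pixel factor 20) on difference-of-Gaussians
band-passed frames, and corrected by bilinear translation with
border fill set to the frame median.

## Tracking and photometry

Linking is greedy mutual nearest neighbour, frame to frame: a track end
and a spot are linked when each is the other's closest admissible partner,
the frame gap is ≤ `max_gap` (3) and the displacement is strictly below
`max_disp_nm` (500). Ties break on distance, then spot amplitude, then
position, so linking is deterministic and order-free. Singleton tracks are
discarded.

The motion rule is applied a second time as a classifier: a track is
**stationary** iff every pair of observations at most 3 frames apart is
displaced by strictly less than 500 nm (net displacement, not path
length); exactly 500 nm ⇒ trafficking. Analysable tracks must additionally
start by frame 3 and span ≥ 90 % of the movie (both configurable).

Intensities are measured on the **raw** movie at drift-adjusted positions
(the drift-corrected movie is used only for detection and tracking):
resampling shifts the peak flux between pixels depending on the fractional
shift and would add ~3 % spurious baseline variability. The per-frame
value is a partial-pixel-weighted disk mean (radius = 2σ̂ of the track's
median detected scale, min 2 px) minus the median of a background annulus
(radius + 2 to radius + 5 px); anti-aliased disk weights avoid the jumps a
hard mask produces as boundary pixels flip in and out. Gap positions are
linearly interpolated; frames where the disk leaves the image are flagged
missing rather than raising.

## Kinetics

RI(t) = raw(t) / mean(raw over baseline); at least 5 baseline points and a
positive baseline mean are required, and the baseline mean of RI is 1 by
construction (asserted to 1e-9 in tests). Three gates follow:

1. **Responder**: `slope_drop = (baseline_slope − post_slope) ×
   stim_duration` must be ≥ `responder_threshold`. `post_slope` is fitted
   by OLS over the first half of the stimulation window ("the decrease of
   signal immediately after stimulation"). The literal criterion value of
   0.25 would exclude genuinely weak boutons (their whole depth is 0.18),
   so the default threshold is 0.05 and 0.25 remains available.
   Noise sensitivity: SD(slope_drop) ≈ SD(RI) · √(12/n_b³) · D for n_b
   baseline frames and stimulation duration D, so with short baselines the
   gate is noisy and marginal responders may be dropped — visible as
   occasional `non_responder` labels on deep traces in the worked example.
2. **Variability**: baseline stdev/mean must be < 0.5.
3. **Baseline stability**: |fitted baseline slope| accumulated over the
   baseline window must be ≤ 0.1 RI (no canonical value exists; 0.1 is
   config-exposed).

Gated traces are clustered by Ward-linkage agglomerative clustering
(scipy) on the scalar plateau **depth**, cut at k = 2; the cluster with
the larger mean depth is *strong*. Depth = 1 − mean RI over the final
quarter of the stimulation window. Under the default linear full-window
decay the plateau window still contains part of the ramp, so the measured
depth is `mean((t−s)/(D−1))` over that window ≈ 0.88 × the true depth
(e.g. 0.307 for a true 0.35); this bias is a property of the convention,
identical for both classes, and irrelevant to classification. If all
features are identical the clustering degenerates to a single class with a
warning. Classification is deterministic and invariant to input order and
to global intensity scaling.

## Statistics

*Permutation test.* Statistic = difference of group means, two-sided via
|T|. When C(n+m, n) ≤ 200 000 all assignments are enumerated and
p = #{|T_perm| ≥ |T_obs|}/N (the identity assignment keeps p > 0);
otherwise B seeded label permutations give p = (b+1)/(B+1). Permuted
statistics are compared with a 1e-12 absolute tolerance so exact ties are
counted. Measured calibration: type-I error 0.043 at α = 0.05 over 1000
null replicates (n = 8 per group); Monte-Carlo agrees with enumeration to
0.002 at B = 100 000.

*Regression comparison.* Post-stimulation RI points of all traces are
pooled and fitted by OLS with design `RI ~ time + group + time:group`,
time origin at stimulation onset (so intercepts are the RI at stimulation
onset). The slope difference is tested by the F test of the interaction
term(s). Pooling treats points as independent; an alternative
`per_trace_slope_test` permutes per-trace OLS slopes and is provided as a
robustness mode. Measured calibration: null rejection 0.046 at α = 0.05
(1000 replicates of 8 traces/group × 50 frames, RI noise 0.05); power
0.975 for a true slope ratio of 2 at the same cohort size.

*EM report.* Per metric (AZ length, presynaptic area, vesicle density): a
two-group permutation test, with raw p values plus a Benjamini–Hochberg
q-value column. Per group: Pearson r (two-sided t-based p) of vesicle
density vs AZ length. The EM simulator draws (AZ length, density) from a
bivariate normal with the configured correlation, area independently,
rejects non-positive draws, and recomputes density as
round(density·area)/area so count/area/density are exactly consistent.

## Numerical and degenerate-input choices

- Seeds: every stochastic routine takes an explicit seed or Generator;
  identical config + seed is bit-reproducible, including CSV outputs.
- Constant frames make drift estimation a degenerate-input error;
  constant images yield zero detections; identical cluster features
  collapse to one class with a warning; zero-variance correlation inputs
  are errors rather than NaN.
- Movies are written as uint16 multi-page TIFF (floats rounded/clipped)
  with a flat-YAML sidecar; unknown config keys are errors to catch typos.
- Frame windows are half-open; coordinates are 0-based (x, y) = (column,
  row) with pixel centres at integers.

## Problem sizes used in tests and the acceptance script

Detection is scored on a 512×512, 50-frame, 60-bouton movie at default
noise; tracking on 512×512, 40 frames, 100 boutons, plus a separate
noise-free trafficking-only run; kinetics on 10 seeded cohorts of 100+100
traces with per-trace depth jitter SD 0.03; calibration studies use 1000
null replicates. These desk-scale conditions exercise every code path with
tight Monte-Carlo error while keeping a full run around half a minute.

## Known limitations

- The detector assumes isotropic Gaussian puncta; overlapping or
  anisotropic emitters are not deconvolved, and boutons closer than the
  NMS radius merge.
- The responder gate inherits the baseline-slope noise amplification
  described above; with very long stimulation windows relative to the
  baseline, gating on depth (or disabling the gate) is preferable.
- Pooled regression understates uncertainty when traces are few and
  point-level noise is correlated within a trace; use the per-trace slope
  mode in that regime.
- Bleaching is not explicitly corrected; at the default rate it biases
  measured depths by < 0.02 RI and the baseline-stability gate rejects
  traces where it would matter.
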