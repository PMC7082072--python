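# Methods

## The biological pattern

Adult mouse retinas grade cone opsin expression along the dorsal-ventral
(D-V) axis. Two cone subtypes underlie the pattern: S-only cones (high,
position-independent S-opsin, no M-opsin) and co-expression-competent (CEC)
cones (graded M- and/or S-opsin). Measured along the axis: the fraction of
cones expressing S-opsin switches on with an extremely sharp Hill
transition (coefficient ~30), the M-expressing fraction declines gradually
(coefficient ~2–3), and the S-only subtype rises from ~1% of cones
dorsally to ~20–30% ventrally. The transitions of different retinas line up
when aligned at the S-opsin midpoint, suggesting one upstream positional
signal — thyroid hormone (T3) acting through the Thrβ2 receptor.

`conefate` implements (a) the image-to-table analysis used to quantify the
pattern and (b) a hybrid deterministic–stochastic model that reproduces it
from a single T3 gradient, plus a synthetic-retina generator that stands in
for the (non-public) experimental images.

## Synthetic retina generator

The generator (`conefate.synthetic`) samples a 6 × 0.8 mm strip of ~24,000
cones on a jittered hexagonal lattice (spacing 15 µm, jitter 15% of
spacing). Each cone is S-only with probability given by a normalized
monotone Hill interpolant running 1% (dorsal) → 25% (ventral end),
midpoint 3100 µm, coefficient 5; otherwise CEC.

Intensities (arbitrary units) are multiplicative log-normal draws around
position-dependent means:

* **S-only cones** — mean 250 (CV 0.25), position-independent; M at
  background (5).
* **CEC cones, S channel** — CV 0.25 around a continuous mean built by
  *inverting the log-normal threshold relation*: the mean at position y is
  chosen so that P(S > τ), with τ = 10 the expressing threshold, equals the
  target sharp Hill curve (midpoint 3000 µm, n = 30, floored by the S-only
  contribution). Ventral of the switch's saturation point the mean ramps
  linearly to 100. This construction makes the *classified* S-expressing
  fraction follow the configured Hill transition exactly while keeping the
  per-cell intensity field continuous — no on/off jump — so the joint
  (S, M) intensity distribution forms a connected CEC manifold, as in real
  retinas.
* **CEC cones, M channel** — broad cell-to-cell variability (CV 1.3)
  around a mean declining from 160 toward background (decreasing Hill in
  y, unnormalized, midpoint 830 µm, exponent 2). The *M-expressing
  fraction* then declines gradually across the whole strip with an
  effective Hill coefficient ~2.8; its exact value at any y is available in
  closed form (`cec_m_expressing_fraction`) for oracle tests. A consequence
  of this threshold-based construction is that the M *intensity* midpoint
  sits dorsal of the M *fraction* midpoint; we accept this trade-off in
  favor of matching the fraction transition, which is the fitted,
  quantitative observable.

Every positional law is exposed as a deterministic interpolant so sampled
tables can be tested against exact binomial expectations. Rendering places
an isotropic Gaussian blob (σ = 1.5 µm) per expressing channel with peak
amplitude equal to the cell intensity, over constant background with
additive Gaussian noise; planted ground truth rides along in the tile
metadata. Retina-to-retina variability is emulated by resampling any
parameter subset from truncated normals (`sample_retina_params`).

What the generator does **not** emulate: optical blur anisotropy, uneven
illumination, tissue distortion, rod contamination, or temporal-nasal
gradients. Passing tests on synthetic tiles therefore demonstrates the
correctness of the measurement chain, not robustness to every imaging
artifact.

## Segmentation

Per channel: percentile normalization (1st/99.5th), opening by
reconstruction with a disk of one third of the expected cell radius,
peak seeding (minimum separation 6 µm, prominence 0.05 of the normalized
range), then an independent morphological Chan-Vese active contour per
seed (3 µm circular initialization, ≤ 200 iterations on a 12 µm window).
Accepted regions are refined to the half-maximum level of their seed peak —
the boundary convention used for outer-segment areas — and validated: area
in [5, 80] µm², solidity ≥ 0.8, interior mean ≥ background + 3 SD, no
border contact. Channels are reconciled by mask IoU ≥ 0.3. The pipeline is
fully deterministic; on default synthetic tiles recall and precision
against planted cells exceed 0.9. Low-resolution tiles instead get a
25 × 25 px binned density map of S-only / M-only / co-expressing pixels,
each bin normalized by its expressing-pixel count.

## Profiling

Classification thresholds default to 10 intensity units (≈ background mean
plus 3 SD of the default background model). Expressing-fraction profiles
use 100 µm D-V bins; empty bins are flagged, never silently dropped. Hill
fits are unweighted nonlinear least squares over (base, amplitude,
midpoint, n) with direction auto-detected from the end means, multi-start
over n ∈ {1, 5, 20, 50}, bounds n ∈ [0.3, 150], and an honest degenerate
flag when the dynamic range is under 5%. Clustering runs HDBSCAN
(scikit-learn implementation) on raw (S, M) pairs of cells expressing at
least one opsin — cones expressing neither are invisible to
immunofluorescence — with minimum cluster size 1% of cells and single-
cluster results allowed. Transition statistics fit the S-expressing
fraction to locate the midpoint, fit the CEC fraction with the decreasing
Hill family, and differentiate it analytically at the midpoint.

## Hybrid simulator

Geometry: a 5000 × 1000 µm strip, depth 5 µm (entering only via voxel
volume), tiled by 330 columns × 72 rows = 23,760 cones. The row pitch
(1000/72 ≈ 13.9 µm) is slightly wider than the ideal hexagonal pitch so the
strip tiles to exactly this count; within-row neighbors remain nearest
neighbors at the spacing 5000/330 ≈ 15.15 µm.

**T3 field.** Relative concentration on a 50 µm grid, forward-Euler
5-point diffusion (D = 100 µm²/t.u., stability-checked), dorsal/ventral
rows pinned at 1 and 0, zero-flux sides, initialized at the analytic linear
ramp (the adult gradient is maintained, not developed).

**Exchange.** Per macro step (Δt = 0.05 t.u.) each cone exchanges molecules
with its voxel using the exact one-step law of the linear uptake/release
process: each held molecule survives with probability e^(−k_out Δt) and
arrivals are Poisson with the integrated intensity, giving the stationary
mean k_in·c/k_out (= 100·c molecules at the defaults) independent of step
size. Uptake is capped so voxels never go negative; molecule bookkeeping is
exactly conservative.

**Per-cell network.** Nine reactions sampled by the exact direct-method
SSA: T3–receptor binding/unbinding (k_on = 0.025, k_off = 10,
200 receptors → ~40 active dorsally, ~0 ventrally); an irreversible
first-event-wins fate race U→S (rate k_fateS,max·K_f^h/(K_f^h + A^h),
h = 5, K_f = 17, k_fateS,max = 2/3) against U→C (k_fateC = 2); constitutive
S production in S-only cones (β_S = 200, so mean counts β_S/φ = 200 with
degradation φ = 1); in CEC cones M production activated by active receptor
(β_M = 120, K_M = 100, h = 1 — a gentle, near-linear response that yields
the gradual M decline) and S production promoted by inactive receptor and
repressed by active receptor (β = 150, K = 12, h = 16 — the steep
de-repression that yields the sharp S switch). Receptor conservation is
asserted after every sweep.

Cells start undifferentiated with zero opsin but with their *fast* species
(free T3, receptor occupancy) drawn from the local stationary law;
starting those pools empty would let every cone race through the fate
decision during the loading transient and inflate the dorsal S-only
fraction several-fold. Runs last t_end = 8 t.u. (opsins equilibrate on the
1/φ = 1 t.u. scale; undecided cells are ~e^(−16) and reported in metadata).
Randomness is one counter-based stream per (seed, cell, macro step)
(splitmix64), so results are independent of cell processing order, and the
hot loop is a numba kernel checked against a reference Python sampler and
closed-form stationary laws.

**Calibration.** Binding, exchange and the fate branching ratio were first
placed by mean-field algebra (`mean_field_summary`): ventral
P(S-only) = k_fateS,max/(k_fateS,max + k_fateC) = 0.25; dorsal repression
set for ~1%; the S de-repression threshold K placed so the emergent S
transition midpoint sits mid-strip. Because receptor-number fluctuations
pass through steep Hill functions (Jensen's inequality), the realized
dorsal fraction runs above the mean-field value, so K_fate was refined by
a stochastic scan (`scripts/calibrate_defaults.py`) to put the pooled
dorsal-mm fraction at 1.0%. The general-purpose fitting loop
(`conefate.calibrate.calibrate`) is a log-space Nelder-Mead over chosen
rate parameters against Hill-fit target curves ("mean retina"), evaluated
on width-reduced strips for speed; its recovery of perturbed rates within
20% is exercised in the tests.

**Emergent steepness.** The simulated S-expressing transition fits to
n ≈ 16–20 — sharper than every other simulated transition (M fits to
n ≈ 10 under the same threshold) but below the experimental ~30. The
limit is physical within this model: receptor-occupancy noise
(sd ≈ 4 of 200 copies) smears the de-repression switch even at h = 16, and
raising copy numbers further to sharpen it scales the event count (and
runtime) linearly. The quantitative acceptance checks on the ~30
coefficient therefore run on the synthetic mean retina, which encodes the
measured transition directly; the simulator is held to the ordering
n_S > n_M and to the fate-fraction targets.

**Knockout.** ΔThrβ2 is modeled as k_on = 0: no receptor ever activates,
so M production is zero everywhere and both the S-expressing density and
the S level are flat along the axis. In this reaction scheme
knockout CEC cones express S at the repression-free (ventral-like) level;
a knockout level matching the mid-strip wild type would require additional
regulation outside the modeled network, and is not reproduced.

## Ensemble comparison

Retina-to-retina variability is simulated by redrawing parameters from
normal distributions per run (`variability_ensemble`) and summarizing each
run by its transition statistics. Distributions are compared by the overlap
coefficient ∫min(f, g) of Gaussian KDEs sharing a pooled Silverman
bandwidth. On defaults, the simulation ensemble's statistics overlap those
of synthetic retinas whose fate and expression transitions shift together
(coupled, as the shared-gradient model predicts) and the overlap degrades
when the transitions shift independently — the package's version of the
coupling argument, asserted qualitatively (no significance claim).

## Problem sizes and numerical choices

Default test and acceptance workloads are sized for a single CPU: Hill-fit
checks use the full ~24,000-cell synthetic strip; simulation-heavy checks
use width-reduced strips (100–500 µm, cell count proportional) except the
acceptance fate fractions, which pool twelve full 23,760-cone runs
(~6 s each after JIT compilation). Tolerances follow the noise scale of
each estimate: binomial envelopes (4σ) for sampled fractions, 1e-4
relative error for noiseless fit recovery, 1e-6 for the PDE steady state,
3–4σ Monte-Carlo bands for SSA moments. Ties and degenerate fits carry
explicit flags; fraction bins with no cells are excluded from fits rather
than imputed.

## Known limitations

* The reaction network is a minimal reconstruction: one hormone, one
  receptor, no transcriptional intermediates, no development-time dynamics
  of the gradient.
* Emergent simulated S-transition steepness saturates near n ≈ 20 at
  practical receptor copy numbers (above).
* The generator's M intensity decline places the intensity midpoint dorsal
  of the fraction midpoint (threshold-model trade-off, above).
* Segmentation assumes well-separated outer segments of roughly circular
  shape; densely overlapping mosaics or strongly anisotropic optics are out
  of scope, as are z-stacks and tile stitching.
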