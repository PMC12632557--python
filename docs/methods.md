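# Methods

`argokit` analyses ratiometric genetic pulse-chase experiments: a protein of
interest carries a tandem RFP::GFP tag, and an inducible recombination pulse
excises the GFP coding sequence so that protein synthesised afterwards is
RFP-only. At a presynaptic punctum, RFP reports total protein and GFP
reports protein made before the pulse, so the punctum GFP/RFP ratio is a
readout of protein age. This note describes the models the package
implements, the synthetic-data generator used to validate them, and the
numerical and design choices that a maintainer would want to know.

## The measurement model

For a punctum imaged at age `T` after a pulse at age `T0` (chase time
`dt = T - T0`), the observed ratio is modelled as

    r = gamma * O_app * (1 - a (1 - q)) + af

* `O(dt)` — fraction of the pulse-labelled (old) pool remaining, set by the
  turnover kinetics (below). Controls (no pulse) have `O = 1`.
* `gamma` — GFP:RFP brightness per molecule. GFP has the higher quantum
  yield, so `gamma > 1` and steady-state ratios sit well above 1.
* `a`, `q` — fraction of punctum protein in acidic compartments and the
  residual GFP brightness there. GFP is pH-quenched in late endosomes and
  lysosomes while RFP is comparatively pH-resistant, so rising `a` lowers
  the steady-state ratio; this is the imaging signature of sorting into the
  lysosomal degradative route.
* `O_app = O / g_rel` — synapse growth between pulse and imaging
  (`g_rel >= 1`) dilutes the old pool with new, RFP-only protein. A pulse
  given before a growth phase therefore yields a shorter *apparent*
  half-life from the ratio than from GFP alone.
* `af` — autofluorescence background expressed on the ratio scale.

Per-animal turnover datapoints are the arithmetic mean ratio over all
puncta of one neuron, normalised by the mean ratio of an age-matched
non-pulsed control cohort. On that normalised scale the expected trajectory
is

    y(dt) = b + (1 - b) * O_app(dt),      b = af / (gamma (1-a(1-q)) + af)

so the background enters only as the plateau `b`, and the steady-state
factors (`gamma`, quenching) cancel between the pulsed and control arms.

## Turnover kinetics

Three generative kinetic models are supported:

* **one-phase** — `O(dt) = exp(-k dt)`; half-life `ln 2 / k`.
* **two-phase (two pools)** — `O(dt) = f exp(-k_fast dt) + (1-f) exp(-k_slow dt)`:
  two chronically distinct pools, one fast and one slow (possibly inert).
* **shutoff** — one-phase decay at rate `k` that stops at a fixed
  `shutoff_age`: turnover machinery fails at a specific age, freezing the
  remaining pool.

The two-phase and shutoff models both produce trajectories that plateau
above background; they separate in a pulse-at-different-ages design. The
two-pool model predicts the same value at equal time-since-pulse for any
pulse age; the shutoff model predicts *no* turnover for pulses given after
the shutoff age, and `discrimination.model2_shutoff_time(k, f_remaining) =
-ln(f_remaining)/k` converts an observed terminal plateau into the implied
shutoff delay. With the reference fast-phase rate `k = 0.7535 / day` and
61% remaining, the delay is 0.656 ≈ 0.66 days. (Note: solving the same
expression with 60% remaining gives 0.678 d, not 0.66 d; the printed 0.66
is consistent with the 61% slow-pool fraction. The implementation is
generic in `f_remaining` and does not attempt to resolve that rounding.)

## Decay fitting

`decay.fit_one_phase` / `fit_two_phase` do unweighted least squares with
every animal as an individual point (`scipy.optimize.least_squares`,
bounded: rates in [0, 50]/day, fraction in [0, 1], `y0` free). The plateau
is normally **constrained** to the measured background on the normalised
scale; leaving it free is the diagnostic for a retained pool (a free-plateau
95% CI that excludes the measured background indicates biphasic turnover).

* Initialisation: `k` from a log-linear regression of `y - plateau`;
  the two-phase fit warm-starts from the one-phase solution with rate
  splitting, which also guarantees its SS never exceeds the nested model's.
* Uncertainty: asymptotic Wald intervals from the Jacobian with Student-t
  critical values (df = n − p). Half-life CIs transform the rate interval;
  rates below 10⁻³/day are reported as "essentially infinite" half-life
  (unresolvable within a ≤ 7-day chase). A profile-likelihood CI on the
  rate (`profile_ci_rate`) is available for boundary cases where the upper
  limit is unbounded.
* Goodness of fit: R² against the mean-only model.
* Degenerate two-phase solutions are flagged, not raised:
  `rates_collapsed` when the two rates are indistinguishable and
  `boundary_fraction` when `f` sticks at 0 or 1.

**Model comparison** uses the extra sum-of-squares F test
(`F = [(SS0-SS1)/(df0-df1)] / (SS1/df1)`). Simulation shows the test is
*conservative* here (type-I ≈ 2% at nominal 5%): under a one-phase null the
extra two-phase parameters are non-identifiable (any `f` with equal rates
gives the same curve), a standard regularity violation for tests on the
number of exponential components.

**Outlier elimination** follows the ROUT procedure: a robust fit with a
Lorentzian (Cauchy) merit function, a robust residual SD (RSDR) from the
68.27th percentile of |residuals| with the small-sample factor `n/(n-p)`,
a Benjamini–Hochberg false-discovery step at rate `Q` on two-sided t
p-values, and a final ordinary fit on the inliers. Outliers are removed
once, with per-neuron-class presets Q = 5% (DA9), 1% (NSM), 3% (VD/DD) —
chosen to mirror each dataset's recombination error rates.

## The synthetic-data generator

`synthetic.simulate_ratio_cohort` emulates a cohort design (pulse age,
daily chase timepoints, animals per timepoint, age-matched controls) at the
punctum-table level; `simulate_truth_puncta` + `render_image_stack` produce
two-channel z-stacks (isotropic 3-D Gaussian spots on additive per-channel
autofluorescence, Poisson photon noise and Gaussian read noise) with a
ground-truth sidecar, for validating the segmentation path.

Defaults are chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| `gamma` (GFP:RFP yield) | 2.6 | calibration constant; puts the A0 control ratio above 2 |
| quench `q` | 0.2 | calibration constant (no printed value) |
| acidic fraction `a(age)` | 0.05 at A0 → 0.35 at A2, flat after | calibration; reproduces the steady-state ratio decline over early adulthood |
| `af` (ratio-scale background) | 0.15 | gives a normalised plateau `b ≈ 0.07` |
| per-animal ratio CV | 0.15 | lognormal, per the dispersion treatment of the source data |
| per-punctum ratio CV | 0.20 | intraneuronal scatter |
| per-animal brightness CV | 0.40 | cancels in the ratio, not in raw channels |
| punctum amounts | lognormal, sigma 0.5 | heavy-tailed punctum intensities |
| growth factor | 1 → 2.2 over A0→A2 (size), 1 → 1.4 (count) | presynapses grow >100% in early adulthood, then are stable |
| pixel / z-step | 0.108 µm / 0.4 µm | 6.5 µm sensor at 60×; acquisition z-step |
| pulse delay | 4 h | recombination completes hours after the heat pulse |
| ages | float days of adulthood, A0 = final larval stage | larval stages map to negative offsets |

The acidification/quench numbers are calibration constants, not
measurements: no numeric acidic fractions or quench depths are printed in
the source work.

Scatter is multiplicative lognormal (mean exactly 1) applied per animal and
per punctum to the whole observed ratio; per-punctum acidic fractions draw
from a Beta distribution around `a(age)` (concentration 30). With all noise
terms off the generator is exactly deterministic, which the trivial
invariants exploit (k = 0 ⇒ normalised ratio ≡ 1; at `dt = ln2/k` the
normalised ratio is exactly `b + (1-b)/2`).

The table-level model places the background additively on the *ratio*
scale, while the image path places it per channel; the two agree after
normalisation to the control cohort, which is the only scale the decay fits
see. Truth puncta are placed one per jittered grid slot (minimum spacing
2 µm by default) — en-passant boutons are discrete varicosities — so that
noise-free rendered scenes are segmentable one-to-one; plain uniform
placement is used when the requested density cannot honour the spacing.

What the generator does *not* emulate: optical PSF structure beyond
isotropic Gaussians, axon curvature (synthetic axons are straight and
axis-aligned), photobleaching, transport packets, and day-to-day imaging
drift. Passing tests therefore validate the analysis pipeline against its
own generative assumptions, not microscope physics.

## Image quantification

`quant.quantify_stack` mirrors the standard punctum workflow: max-intensity
z-projection; isodata (iterative intermeans) automatic threshold on the RFP
channel (strictly-above mask); 8-connected particle analysis; components
with area strictly below the floor removed (0.1 µm² for DA9/NSM, 0.2 µm²
for VD/DD presets); both channels measured with the identical ROI; the
normalised axial position taken from the centroid x within the half-open
presynaptic region. Background is estimated by translating the punctum
ROIs perpendicular to the axon (default shift: twice the median punctum
diameter), re-shifting once on collision, and summarising shifted-ROI means
with a 95% t-interval; division by the control-cohort mean converts it to
the normalised plateau. The bright-punctum bias of global thresholding is
inherited deliberately: the dimmest puncta of a heavy-tailed brightness
distribution fall below an intermeans threshold exactly as they do in the
standard particle-analysis workflow.

## Recovery benchmarks (`validation`, `scripts/acceptance.py`)

The package's calibration benchmarks regenerate cohorts from reference
best-fit models — one-phase half-lives of 3.0 d (pulse at A2), 1.7 d
(apparent, pulse at A0) and 23.4 d (slowed-turnover mutant, low noise), and
the two-pool model (39% fast at 0.7535/day, inert remainder) — under the
standard design: daily imaging over a five-day chase, 15 animals per
timepoint, plateau constrained to the generating background. Problem sizes
are 200–800 cohorts per benchmark, chosen so the Monte-Carlo error of the
reported median is a few per cent of the target. Two protocol choices:

* Cohorts are generated directly from the best-fit decay models with zero
  pulse-completion lag: a half-life fitted from a real experiment already
  absorbs the lag, so re-applying it would double-count.
* No outlier elimination inside the benchmarks: the generator produces no
  contaminant animals, and on clean right-skewed noise a trimming step only
  biases the recovered rates. ROUT remains part of the general pipeline and
  has its own calibration tests.

Known estimator property: the two-phase fast-fraction benchmark recovers a
median of ≈ 36% against a generating 39%. The deficit is the `k_slow ≥ 0`
boundary: noise that tilts the late trajectory downward is absorbed by
`k_slow > 0`, which takes fraction from the fast pool, while upward noise
cannot credit it back. Fixing `k_slow = 0` in a diagnostic refit removes
the bias entirely; the free-rate fit is retained because it is what the
method specifies.

## Limitations

* The per-animal datapoint is treated as exchangeable within a timepoint;
  no hierarchical (mixed-effects) modelling of punctum-within-animal
  structure is attempted, matching the unweighted-least-squares convention.
* Group hypothesis testing (ANOVA and nonparametric families) is out of
  scope; the package stops at fits, CIs, F-model comparison and the
  qualitative two-model discrimination.
* Segmentation is 2-D on the projection; no deconvolution, no curved-axon
  straightening, no 3-D segmentation.
* The recombination scorer assumes a bimodal per-animal ratio distribution
  and declines to split unimodal data (labelling by absolute level
  instead); intermediate animals within a relative margin (default 10%) of
  the split point are left unscored.
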