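# Methods

This note documents the models, parameter choices, and numerical
decisions behind the package, and what the synthetic-data validation
does and does not establish.

## Data model and preprocessing

Gaze is represented as raw samples — (t_ms, x_px, y_px, valid) at the
recording rate — not as detected fixations. Every windowed metric in the
package is computable on samples, and sample-level dwell (inside-sample
count × sample period) avoids committing to a fixation-detection
algorithm. A dispersion-based detector (I-DT; dispersion threshold 1° of
visual angle, minimum duration 100 ms) is provided for fidelity
experiments comparing the two representations, but no pipeline stage
depends on it.

Conventions: pixel coordinates are 0-based, origin top-left, y downward;
after normalization gaze lives on the unit square. Time is milliseconds
from stimulus onset and all windows are half-open [start, end), so bin
edges are counted exactly once. Tracking loss is kept explicit
(valid=False with NaN coordinates) so the duration of missing runs is
well-defined; a trial is excluded when a maximal invalid run strictly
exceeds 2 s (run duration = run length × nominal sample period, so the
boundary case of exactly 2 s is kept).

## The constrained gaze-state HMM

One model per stimulus is fitted to the pooled sequences of *all*
observers. Pooling across the groups that are later compared keeps the
state space common to both groups; fitting per group would make the
downstream contrasts partly an artifact of different state inventories.
Per-group fitting remains available (fit on any trial subset) for
sensitivity analysis.

Emissions are full-covariance 2-D Gaussians; K defaults to 14. The
likelihood saturates as K grows (`model_selection_curve` documents this
diagnostic) but K is a fixed design choice, not auto-selected.

Constraints, applied after every M-step:

* **Area**: the 2-SD ellipse area A = 4π√detΣ is clamped into
  [0.001, 0.05] of the unit image by multiplying Σ by (A_target/A)
  (isotropic, since A scales linearly under Σ → sΣ). The 2-SD level is a
  convention choice; the bound level is configurable.
* **Axes**: principal-axis lengths (√eigenvalues, pooled over both axes
  of all states) are clipped to mean ± N·SD with N = 2 by default;
  covariances are rebuilt from the clipped spectrum in the original
  eigenbasis.

Clamping can lower the EM objective, so monotonicity is only expected
between iterations where no clamp fired; every clamp event is counted on
the fitted model (`clamp_events`) and surfaced as a pipeline warning.

Tracking-loss gaps split each trial into independent valid segments: the
chain restarts at the initial distribution after a gap and no transition
is counted across one. Because a pooled fit then involves on the order of
a thousand short segments, the E-step runs in a packed time-major layout
(segments sorted by length; the forward and backward recursions act on
the prefix of segments still active at each time step). This keeps the
per-iteration cost at O(T·K²) vectorized work. The implementation is
verified in the test suite against exhaustive path enumeration (T ≤ 8)
and against an independent HMM library on shared parameters (posteriors,
Viterbi paths, and multi-sequence log-likelihoods).

Initialization per restart: k-means++ on the pooled samples for means,
isotropic covariance (area ≈ 1% of the image), and uniform initial and
transition rows averaged with a Dirichlet(1) draw. Ten restarts by
default; the final (post-clamp) log-likelihood selects the winner.
Convergence: relative log-likelihood change < 1e-6 or 500 iterations.
States that lose essentially all responsibility retain their previous
parameters for that iteration, and a 1e-12 ridge keeps covariances
invertible in unconstrained mode.

## Windowed metrics

State-distribution metrics use the natural logarithm throughout so the
identity Neff = exp(H) holds exactly as written and Hnorm = H/ln K.
"Total variation" is concretized as ½·L1 between the current and
previous window's distributions (undefined for the first window). Switch
rate counts differing adjacent Viterbi states over adjacent *valid*
sample pairs; pairs straddling a gap are dropped and segments pool their
pairs. Windows with no valid samples propagate as missing rows rather
than zeros.

Depth-point engagement uses the union of a stimulus's ROIs with
half-open membership (consistent with the grid binning, so ROIs
partition space exactly). An entry is a valid inside sample whose
previous valid sample was outside, or a trial's first valid sample if
inside. Dwell ratio divides by valid in-window time, not nominal window
length, so tracking loss does not masquerade as disengagement. First-hit
latency is reported on cumulative windows only and uses the ROI union
(restricting to the single most-selected ROI is a configuration away:
pass a one-ROI set).

## Depth-ROI derivation

The grid is fixed at 32 × 16; responses on the right/bottom image edge
clamp into the last cell, and responses more than 1 px outside the image
are rejected with a count. The per-cell threshold defaults to
max(2, ⌈0.05 · respondents⌉) and "reaching" the threshold means ≥;
connectivity defaults to 8 (diagonal cells merge). All three are exposed
because no principled value is forced by the method; the defaults are
what we judged a reasonable consensus criterion for ~20–50 respondents.
Components are ranked by support with ties broken by the smaller
row-major first-cell index, and at most six are kept.

## Statistics

Ratings: the composite is the mean of the four 10-point dimensions;
z-scoring is per participant (n−1 SD) and separately per stimulus set,
so participant-specific bias and scale cancel. Tertile assignment per
artwork (high/medium/low; medium excluded from contrasts) reconciles a
three-group design of equal sizes with per-artwork grouping; ties are
broken by participant ID so assignment is reproducible.

Signed-rank: zero differences are dropped; the null distribution of W⁺
is computed exactly up to 25 nonzero pairs by dynamic programming over
doubled midranks — this handles ties exactly, which textbook exact
tables and scipy's exact method do not — and by the tie-corrected normal
approximation beyond. The two-sided p doubles the smaller tail (the null
is symmetric even with ties). The rank-biserial effect size is
(W⁺ − W⁻)/(W⁺ + W⁻).

Between-group contrasts per window use the Mann–Whitney test with
r = 2U/(n₁n₂) − 1. Two calibration choices matter. First, the asymptotic
p-value omits the continuity correction: at the per-window trial counts
used here the corrected test is noticeably conservative. Second, the
pooled design ("between_pooled") converts values to within-artwork
fractional ranks before pooling. Artworks differ strongly in baseline
engagement level, and observers contribute one trial per artwork, so
pooling raw values yields a balanced stratified sample in which the
plain rank test under-rejects (simulated type-I rate drifted to ~0.02 at
long windows); ranking within the artwork stratum first restores the
nominal level (~0.05 across windows in 400 null replicates). The
per-artwork design applies the plain test within each artwork.

Welch's t uses Satterthwaite df; Cohen's d uses the pooled SD and a
normal-approximation CI, SE(d) = √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))).
Sample-size planning uses the normal-approximation formula
n = ⌈((z₁₋α + z_power)/d)²⌉. No multiple-testing correction is applied
across windows by default (per-window statistics are reported as such);
a Holm adjustment is available behind a flag.

The report stage estimates a divergence onset as the earliest cumulative
window whose effect size exceeds a threshold (default θ = 0.2) there and
in every later window — a deliberately simple operationalization of
"emerges and is maintained".

## The synthetic generator: what it emulates, and what it does not

Each trial is a first-order Markov chain over k_true states (default 6)
with isotropic Gaussian emissions; state centres are placed per stimulus
with a minimum separation. Cohorts: before the divergence onset
(default 6 s) both share one sticky transition matrix (stay probability
0.93, chosen so expected state dwell ≈ 0.3 s at 50 Hz, a realistic
fixation-dwell scale); after onset the high-like cohort's rows receive
occupancy_boost (default 0.15) extra mass split over the depth states,
renormalized. The cohort difference enters *only* through transitions,
so the pre-onset null is exact by construction. Missing samples are
i.i.d. at 2%. Localization responses are true depth centres plus
isotropic pointing noise (20 px), with lognormal report timings whose
medians differ by cohort (high-like faster recognition, larger reported
distances). Ratings are a cohort effect plus participant bias and
multiplicative scale plus noise on four correlated dimensions,
discretised to 1–10.

Desk-scale defaults (50 Hz, 16+16 observers, 12 stimuli) keep a full
pipeline run in minutes on one CPU; 300 Hz and other sizes are
configuration. A single master seed expands into per-trial substreams
keyed by participant × stimulus index, so any subset of trials is
bit-reproducible in isolation.

Deliberate omissions: no saccade kinematics or main-sequence structure,
no microsaccades, no calibration drift, no spatial correlation in
tracking loss, and no participant-level variation in the emission model.
Consequently, passing the validation suite shows that the pipeline
recovers a transition-level divergence under its own assumptions — it
does not show robustness to oculomotor structure absent from the
generator.

One structural consequence deserves emphasis: because the injected
divergence is a *cohort* (participant-level) property and ratings'
cohort effect is constant across stimuli, within-participant
normalization removes the rating signal that would link rating-derived
per-artwork groups to the gaze cohorts. Synthetic-data validation
therefore contrasts the ground-truth cohorts directly
(`cohort_assignments`); on real data the same contrast functions accept
rating-derived assignments (`normalize_ratings` → `assign_groups`). The
paired (within-participant) design is correspondingly validated on
constructed tables with artwork-level effects, which is the structure it
is designed to detect.

## Validation problem sizes

The shipped validation suite uses: 3-state recovery at 32 trials × 30 s
× 50 Hz with 10 restarts over 10 seeds (matched-mean error < 0.05
normalized units); divergence recovery at 16+16 observers × 12 stimuli
over 10 seeds; type-I calibration at 200 replicates of 16+16 observers ×
2 stimuli (per-window rejection rate at α = .05 within [0.02, 0.09]);
decoder checks against exhaustive enumeration at T ≤ 8, K ≤ 3; and
signed-rank checks against sign-pattern enumeration at n ≤ 8. These
sizes were chosen so the whole suite runs in well under an hour on a
single CPU while leaving the statistical margins wide (observed: early
effect |r| ≈ 0.03 against a 0.1 bound; post-onset effects ≈ 0.5–1.0
against a 0.2 bound; recovery error ≈ 0.001 against 0.05).

## Known limitations

* The HMM assumes conditionally independent Gaussian emissions; smooth
  pursuit and saccade trajectories violate this within states.
* The area constraint's ellipse level (2 SD) and the axis-clamp N are
  conventions; results at other levels are a configuration sweep away.
* The divergence-onset estimator is threshold-based reporting, not an
  inferential change-point method.
* Exact signed-rank inference switches to the normal approximation above
  25 pairs; at that size the approximation error is far below reporting
  precision, but the exact/approximate boundary is visible in principle.
* The package ingests plain CSV/YAML/JSON; proprietary eye-tracker
  formats must be converted upstream.
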