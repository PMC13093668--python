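# Methods

## The problem

Projecting a high-dimensional molecular trajectory onto a collective
variable x produces a free energy landscape ΔG(x) = −k_B T ln P(x),
with P(x) the marginal of the full distribution. Marginalizing over
orthogonal degrees of freedom can lower barriers or remove them
entirely: frames near a barrier in x may already belong to the
neighbouring state in an orthogonal direction, so the projected
trajectory appears to recross the barrier rapidly (shortened
lifetimes), and states whose separation lives mostly in the discarded
directions disappear from ΔG(x) altogether.

Two corrections are implemented:

* **Dynamical coring** acts on the *state trajectory*: a transition
  into a new state counts only if the system stays there at least
  t_cor frames. It removes spurious recrossings but cannot resurrect a
  state that the projection never resolved.
* **Gaussian low-pass filtering** acts on the *feature trajectory*
  before states are defined: each feature column is convolved with a
  Gaussian kernel of standard deviation σ frames (window t_GF = 2σ).
  Suppressing intra-state fluctuations narrows the per-state
  distributions, which can re-open barriers in the projected landscape
  and recover hidden states — something coring cannot do.

## Toy model

The bundled landscape is a sum of three inverted isotropic Gaussian
wells plus a weak quartic confinement:

V(p) = −Σ_k A_k exp(−|p − c_k|² / 2σ_w²) + k_c |p − c_0|⁴.

The confinement (k_c = 0.02, centred between the wells) is required
for a well-defined equilibrium: without it V → 0 at infinity, the
Boltzmann density is non-normalizable, and trajectories eventually
escape into free 2D diffusion. Near the wells its contribution is
≤ 0.1 k_B T and it is included in all calibration measurements.

Default parameters (k_B T = 1): wells at (−1, 1.844), (0, 0),
(1, 1.844), depths A = 8, widths σ_w = 0.622. These were calibrated —
with the well *geometry* as part of the search space — so that two
independent, deterministic measurements hit the intended physics:

* the potential barrier along the piecewise-linear path *s* through
  the three minima is **4.00 k_B T** (dense 1D grid, saddle minus
  adjacent minimum);
* the barrier of ΔG(x) = −ln ∫dy e^(−V) is **1.00 k_B T** (dense 2D
  quadrature), with three minima at x ≈ −1, 0, 1.

Deep wells (A = 8) keep the flat background ≈ 4 k_B T above the path
saddles, so background escape is negligible compared to path hopping.
A note on the *sampled* ΔG(s): its barrier is ≈ 5.5 k_B T, not 4,
because the transverse width of the Boltzmann density is smaller at
the saddles than in the wells (an entropic contribution of
≈ 1.5 k_B T). The "4 k_B T" calibration refers to the potential along
the path, which is also what the acceptance measurement evaluates.

**Integrator.** Overdamped Euler–Maruyama,
p ← p − ∇V dt/γ + sqrt(2 k_B T dt/γ) ξ, with γ = 1, dt = 0.005, one
saved frame per 10 steps (frame = 0.05 time units), default 10⁶
frames. The frame time was chosen so the separation of time scales
matches the filtering window used throughout (t_GF = 10 frames): the
intrawell relaxation time is ≈ 1 frame and the mean interwell dwell
≈ 150 frames, so t_cor = t_GF = 10 frames sits comfortably between
them. A coarser frame (0.1 time units) makes dwells too short for the
10-frame window; this is a property of the model calibration, not a
tunable of the method.

**Projections.** The optimal coordinate *s* is the arc length of the
orthogonal projection onto the piecewise-linear path through the well
centres (nearest segment wins; clamped at segment ends). Suboptimal
coordinates are projections onto unit vectors: the x axis, and a
tilted axis *r* at 40° by default. At 40° two projected well centres
are separated by 0.42 ≈ 1.9× the intrawell spread (0.22), so the raw
ΔG(r) shows two minima while the t_GF = 10 filtered ΔG(r) (spread
reduced to ≈ 0.12) shows three. The degenerate angle for this
geometry — where two wells project exactly on top of each other — is
arctan(1/1.844) ≈ 28.5°.

## Gaussian filter

Implemented as a truncated discrete Gaussian kernel (half-width
4σ frames by default) applied per feature column. At the trajectory
ends the truncated kernel is renormalized to unit weight instead of
padding or reflecting: no data is invented and constant signals stay
exactly constant (to 1e−12). σ = t_GF/2 exactly; non-integer σ is
allowed; σ = 0 is the identity. The implementation delegates the
convolution to `scipy.ndimage.gaussian_filter1d` and divides by the
filtered indicator function to realize the edge renormalization.

`scan_filter_window` runs filter → state counting (→ optionally ITS)
for an ascending list of windows and recommends the smallest window at
which the state count and leading ITS have plateaued (default 10%
relative tolerance).

## Free-energy curves and state definition

`free_energy_1d` is the histogram estimator dG = −ln(P/P_max)
(Scott's rule bin count by default); bins with fewer than `min_count`
frames are *undefined* (NaN), not zero. `find_minima_and_barriers`
extracts alternating minima/barriers and merges shallow features:
while any barrier height (saddle minus the higher adjacent minimum) is
below `min_depth`, that barrier and its shallower minimum are removed.

For state counting on *sampled* curves the convenience wrapper
`count_states_1d` uses robustness guards: min_count = max(10, 2·10⁻⁵ T),
minima search restricted to dG ≤ 6 k_B T, prominence floor 0.5 k_B T.
Without them, Poisson noise in tail bins populated by a handful of
frames (dG ≈ 7–9) occasionally fabricates minima. The guards encode
that a state must be populated well above shot noise; they do not
affect the genuine minima of the toy model (all at dG ≤ 1.5 with
barriers ≥ 1).

## Density-based clustering

Every frame gets a neighbour count n_i within a hypersphere of radius
R and a local free energy F_i = −ln(n_i/max n). Frames are processed
in ascending F (ties by frame index) in `n_levels` batches; connected
components of the R-neighbourhood graph restricted to processed frames
are tracked incrementally with a union-find structure. A component
with no labelled member seeds a candidate cluster, accepted as a
microstate when its population reaches P_min·T (default
P_min = 0.01%); components touching one cluster join it; frames that
first bridge two clusters are boundary frames, assigned to the cluster
of their nearest higher-density neighbour. Frames never absorbed are
finally attached to their nearest assigned neighbour. When R is not
given it is chosen so a typical frame has ≈ 0.5% of all frames as
neighbours (median k-th-neighbour distance over a 512-frame
subsample). The screening schedule (equal-count levels, default 50) is
this package's concretization; the state count is controlled by P_min
rather than fixed beforehand.

## Coring

`dynamical_core` accepts a transition into state j at frame t only if
frames t..t+t_cor−1 all carry j; rejected excursions are reassigned to
the last accepted state. Boundary conventions: the first frame's state
is accepted unconditionally (no look-back exists), and a visit that
persists to the final frame is accepted even if shorter than t_cor —
the trajectory end cannot disprove the dwell, and keeping the data
unchanged is the lesser mutation. Unassigned (−1) frames are
transparent: they neither break nor extend a dwell and inherit the
accepted state at their position. `iterative_core` applies an
ascending schedule (default every integer 2..10), which empirically
reassigns fewer frames than a single pass at the final t_cor while
smoothing at the same resolution; the property test checks this over
seeded replicates.

The staying probability W_i(t) — the fraction of visits to state i
lasting ≥ t frames after coring at t_cor — supports the t_cor
heuristic: `recommend_coring_time` picks the smallest t_cor whose
W_i(t) lacks a rapid initial decay (initial rate, measured over three
frames past t_cor, no more than twice the bulk rate measured over the
second half of the usable curve, W ≥ 0.05).

## Markov state models

Sliding-window counts C_ij at lag τ (−1 frames excluded from both
roles); states visited fewer than τ frames are dropped and reported.
By default counts are symmetrized, (C+Cᵀ)/2 — the equilibrium
estimator — giving detailed balance and a real spectrum; a flag
disables it. Implied time scales t_i = −τ/ln|λ_i| from the eigenvalues
sorted by modulus; λ ≥ 1 reports +inf, λ ≤ 0 reports NaN.
`its_vs_lag` builds one model per lag over the same state definition
and flags convergence (default 10% relative change between successive
lags).

On the toy model, the model lag must exceed the correction time scale
(t_cor = t_GF = 10 frames) before cored/filtered ITS are meaningful;
agreement with the s reference is therefore assessed at lags
20–100 frames. Cored states match the reference within ~5%. Filtered
states retain a ~10% shortening of the slowest ITS: with an intrawell
relaxation of ≈ 1 frame, the 10-frame filter only halves the jitter
near the barrier, so a small fraction of recrossings survives. This is
a property of the filter at this window, visible only above log-axis
plot resolution.

## MPP lumping

At a fixed lag, metastability = T_ii from *unsymmetrized*
row-normalized counts (the merge criterion is directional). Loop:
if any state's population is below pop_min (improved variant), merge
the smallest such state into its most probable target j ≠ i;
otherwise, if any T_ii < q_min, merge the least metastable state
likewise; rebuild the matrix after every merge. Tie-breaks are
deterministic (lowest index on equal metastability; first maximum on
equal T_ij). A state that never appears as a transition source at the
lag is absorbed into the most populated other state. Every merge is
recorded (source, target, T_ii, population, reason) — the dendrogram.
Termination is guaranteed since each merge removes one state.

Macrostate profiles summarize per-state feature distributions as
boxplot statistics with Tukey-hinge quartiles (median of each half,
median included on odd halves), IQR = Q3 − Q1, and whiskers at the
most extreme data points within Q1/3 ∓ 1.5·IQR.

## Contacts and folding events

Inputs are per-frame residue-pair minimum heavy-atom distances in
Ångström (a >99% fraction of distances below 1 triggers a nm-vs-Å
warning). A native contact is a pair with |i−j| > 3 formed
(d < 4.5 Å) in strictly more than 30% of frames. Q(t) is the fraction
of native contacts formed per frame. Folding events are counted with
hysteresis: a passage entering the unfolded region (Q ≤ 0.3) and
subsequently reaching the native basin (Q ≥ 0.7); intermediate values
are transparent and re-entering unfolded before folding does not reset
progress. When a filter window is given, Q is computed from filtered
distances (filtering distances, not Cartesian coordinates, avoids
spurious distance fluctuations).

## Synthetic fixtures

`generate_fixture` emits data with shipped ground truth: `toy2d`
(short default-potential run), `telegraph` (two-state jump process,
exponential dwells, optional observation noise), `block_chain`
(Markov chain with planted blocks and known eigenvalues), and
`planted_folding` (alternating folded/unfolded distance segments at
3 Å / 8 Å with white *common-mode* noise shared across pairs — a
collective breathing that fakes extra folding events in raw Q(t) and
is removed by filtering — plus small independent per-pair noise).
These emulate the temporal structure the methods target (separated
noise/dwell time scales, block metastability, planted event counts);
they do not emulate real MD features such as anharmonic intrastate
dynamics, slowly-decorrelating noise, or state-dependent noise
amplitudes, so passing tests demonstrate correctness of the
operations, not performance on any particular protein system.

## Problem sizes and numerical choices

The test suite simulates one default 10⁶-frame toy trajectory (seed 1)
shared across tests; density clustering runs on subsampled (≈ 2·10⁴
frame) filtered data; Markov-chain recovery tests use 10⁶-step chains.
The Boltzmann-consistency check thins the trajectory by 500 frames
(several multiples of the slowest ITS) so a chi-square test against
the numerically integrated Boltzmann weights is valid, and pools bins
with expected counts below 5. Tolerances: kernel normalization 1e−12;
row-stochasticity 1e−12; barrier calibration ±0.5 k_B T; ITS plateau
agreement 15%; chain parameter recovery 10% at 10⁶ steps.

## Known limitations

* The density clustering is this package's concretization of the
  energy-ordered region-growing idea; it is not a re-implementation of
  any specific published code, and boundary assignment details differ
  from unpublished originals.
* Filtering shortens the effective time resolution to t_GF; ITS at
  lags below t_GF are biased and the residual ~10% ITS shortening at
  t_GF = 10 frames (see above) is inherent to the window, not a bug.
* The toy potential's sampled ΔG(s) barrier exceeds the potential-path
  barrier by the entropic narrowing at saddles (≈ 1.5 k_B T here);
  barrier-height calibration statements refer to the potential.
* Only overdamped dynamics in 2D are provided for the toy model;
  underdamped integrators, higher-dimensional potentials and replica
  methods are out of scope.
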