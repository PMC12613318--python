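# Methods

This note documents the models, the packaged study system, the numerical
choices, and the known limitations. It is the package's own account of its
science; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## 1. The lattice self-assembly model

Particles are distinguishable (number-labeled), carry a discrete internal
state (two by default), and occupy sites of a 2D lattice with closed
(hard-wall) boundaries; periodic boundaries are available but not the
default. Elementary moves are single-particle hops to a vacant
4-neighbour site and single internal-state flips. All energies are in
units of k_BT (k_BT = 1).

**Interactions.** The pair-energy table is generated from the stored
target structures. A *target* assigns each of its particles a relative
lattice offset, a required internal state, and a set of designed strong
bonds between adjacent offsets; adjacent designed offsets that are not
strong bonds are weak contacts. A particle pair in the required states
receives `J_s = -3.6` if it is a designed strong pair and `J_w = -1` if a
designed weak contact; every other combination — wrong states,
non-designed pairs — is non-interacting. The table is keyed only by
particle identity and internal states, *not* by orientation: designed
partners bind whenever adjacent, which is the microscopic origin of
misassembled (chimeric) kinetic traps.

**Rates.** A move with energy change dE occurs with rate
`nu * exp(-dE/2)` (`nu_trans` for hops, `nu_state` for flips; both 1/s by
default, i.e. state switching and translation on comparable time scales).
This symmetric Boltzmann form obeys detailed balance exactly:
`k(a->b)/k(b->a) = exp(-(E_b - E_a))`. Dynamics are rejection-free
(Gillespie): waiting times are exponential with mean 1/(total rate), and
the chosen move is proportional to its rate. Energy is tracked
incrementally and checked against full recomputation (unit test, 1e-9).

**Assembly detection.** After every applied move the simulator checks
whether any stored target is realized somewhere on the lattice: the
designed particles on the designed footprint (translations always;
rotations/reflections only if a target enables them — off by default
because the particles are distinguishable) in their required states. The
first hit defines `T_FAS` and stops the realization; otherwise the
realization ends at the step budget `N_steps` (flag 0, `T_FAS` = final
time).

## 2. The packaged desk system

The reference study system (lattice size, particle number, prefactors) is
not published, so the package ships its own small system chosen so that
complete ensembles run in minutes while exhibiting the phenomenology the
method addresses. All values live in `RunConfig` and are overridable.

* Lattice 4x4, closed; 6 particles, 2 internal states; `nu = 1/s`;
  `N_steps = 4e5`.
* Two stored 2x3 targets over the *same* six particles. Target B places
  the particles in the permuted order `(3, 0, 5, 2, 4, 1)` and inverts
  the required states, so the designed interactions of the two patterns
  interfere (Hopfield-style crosstalk).
* `J_s = -3.6`, `J_w = -1`, `rho = 1.5` (the published interaction
  constants).

**Why this design.** In a dilute box, stronger bonds *accelerate*
assembly (search-limited regime, no traps). At this density
(6 particles / 16 sites) assembly is rearrangement-limited and the
crosstalk creates compact misbound clusters: exhaustive enumeration of
all 46,080 compact arrangements shows chimeric clusters down to
-22.6 k_BT versus -20.0 for the targets. The strongly bound
configuration therefore gets stuck (yield ~33% at the desk horizon)
while the rho-scaled configuration reorganizes freely (~80%) — the
qualitative ordering the method presumes. The same enumeration shows the
model class cannot make the targets strictly deepest with two stored
2x3 patterns (the best achievable design ties them), which bounds what
the drive protocol can achieve here; see section 6.

**Windows and horizon.** `tau_BEAST,1 = 150 s` (about 300-500 KMC events
per window at this system's event rate), `tau_BEAST,2 = 60 s` (the
rho-scaled configuration relaxes faster, mirroring the much shorter
window the reference constants use for it), downsampling `d_s = 4`,
horizon 80 windows (12,000 s) for configuration 1 and 200 windows for
configuration 2 (same wall-clock horizon). Ensemble sizes follow the
reference study: 300 / 60 equilibrium and 420 driven realizations.
The published window constants (`tau_BEAST,1 = 3.7e-3 s`, `d_s = 100`,
`tau_L = 0.035 tau_BEAST,1`) are retained in `REFERENCE_CONSTANTS`; they
presuppose diffusive rate prefactors (~1e6/s) and are not meaningful at
the desk system's unit prefactors.

## 3. SLM segmentation

Each window slice is linearly interpolated onto a uniform grid whose
length equals the raw sample count, then downsampled to
`ceil(n/d_s)` points with both endpoints kept. Change-points are found by
an exact O(n^2) dynamic program minimizing per-segment linear-fit squared
error plus a penalty per segment:

* penalty = `penalty_scale * sigma^2 * log n`, with `sigma^2` estimated
  robustly from second differences (`Var = 6 sigma^2` for white noise on
  a piecewise-linear signal) and floored at 1e-12 of the signal variance
  so a noise-free series still yields a single segment;
* `penalty_scale = 10` (default), minimum segment length 3 points.

The backend sits behind a one-function contract
(`register_detector`), so a Bayesian trend detector can be plugged in
without touching the pipeline. The segment trend `<t*>` is
operationalized as the ordinary-least-squares slope of energy against
time within the segment — the fitted linear trend of the detector's
model class.

**Trap region.** Sort the trend values; the *jump size* j is the smallest
strictly positive gap between consecutive values; grow `[-m j, +m j]`
from m = 1 until the inclusive count exceeds `|Omega|/n_bins`
(`n_bins = 10` by default). The stopping multiple is solved in closed
form — the literal iteration is unbounded when j is at the float-ulp
scale — and verified locally; ties and duplicate trends fall back to the
smallest positive gap, and an unreachable threshold falls back to the
full trend range. A brute-force stepwise oracle is checked against the
implementation on thousands of randomized sets in the tests.

**Driven controller.** Decisions are made once per window, at the window
end, using the final segment's trend; a scheduled shock occupies the
first `tau_neq` seconds of the *next* window, implemented by swapping
the interaction table for that interval (events during the interval use
the active table; stopping and restarting the exponential clock at the
swap is exact by memorylessness). Windows containing a shock are split
at the shock-off instant and the covered segments flagged drive-on. With
an empty trap region or `tau_neq = 0`, the controller's event sequence is
bit-for-bit identical to the windowed equilibrium run under the same
seed (tested).

## 4. MSM construction

* **Binning:** nested quantiles, trend-major — trend edges at empirical
  quantiles, conditional energy quantiles inside each trend bin; occupied
  cells become states labeled by within-cell mean coordinates. Defaults
  5 trend x 2 energy bins, giving `N_s = 10` occupied states on the desk
  data (13 x 2 reproduces the reference study's 26-state variant). The
  trend-major order matters: it isolates near-zero-trend states, which is
  what gives the driven MSM genuine trap (activation) states.
* **Sequences:** segments map through the binning (out-of-range
  coordinates clamp to edge bins, required when reusing a binning on
  driven data); consecutive repeats merge; assembled trajectories end in
  the absorbing FA state at `T_FAS`.
* **Grid and lag:** grid step = 50x the smallest onset gap across the
  ensemble; lag = largest grid multiple such that the shortest `T_FAS`
  still contains five transitions, clamped to one grid step with a
  warning (the desk data clamps — fast assemblers are shorter than five
  steps, a property shared with the reference analysis, which also does
  not claim Markovianity at its lag).
* **Estimation:** label sequences are downsampled at the lag (beginning
  trimmed so the final tick is kept), re-merged; `P` counts transitions
  between distinct consecutive states; `T_bar` is the empirical mean
  dwell per state; censored endings contribute dwell but no exit; states
  never visited are dropped (warning), visited states without exits
  become flagged self-loop sinks. FA is absorbing by construction and
  `pi0` is the frequency of first-segment states.
* **Simulation:** Gillespie over the state graph with exponential dwells.
* **Diagnostics:** implied timescales `-tau/ln|lambda_k|` (eigenvalue
  moduli, descending; unit eigenvalues reported as infinite), a
  Chapman–Kolmogorov test with trajectory-bootstrap bands, and per-state
  Pearson R between dwell histograms and matched-mean exponentials on
  shared Scott-rule edges.

**Driven MSM.** Drive-on segments map through configuration 2's binning,
drive-off through configuration 1's. `T_F` counts (state just before
activation -> state just after), `T_B` the reverse at deactivation; rows
are normalized where observed, and unobserved rows fall back
deterministically to the destination layer's nearest-mean-energy state
(logged). Trap states are layer-1 states whose representative trend lies
in the closed trap interval. Simulation evolves layer 1, checks the trap
condition at every `tau_beast_1` boundary, dwells in layer 2 for
`tau_neq` seconds (residual dwells are discarded and redrawn — exact for
exponential dwells), and accumulates drive-on seconds; `T_Drive` is the
ensemble mean. In MSM time there are no KMC steps, so drive cost is
reported in seconds rather than step counts.

## 5. Metrics

`S_EMD` integrates `|F_a - F_b|` exactly over `[0, max(p99_a, p99_b)]`
using the piecewise-constant empirical CDFs and normalizes by the
interval length; differences entirely beyond the 99th percentile are by
definition invisible to it. KDE uses Gaussian kernels with Scott
bandwidth on a 512-point grid padded by three bandwidths; histograms use
Scott's rule. The protocol cost is `C = S~A - 0.5 T~Drive` with both
terms normalized by the maximum across both sources and all swept
durations; the optimum is reported at maximal C (the orientation is
configurable).

## 6. What the desk system does and does not show

Passing tests demonstrate: correct Gibbs sampling of the KMC kernel;
exact segmentation and trap-region algorithms; faithful recovery of a
known continuous-time chain from synthetic segment data; and that on a
genuinely trapped self-assembly system the SLM-MSM surrogate reproduces
yields (within ~2 points in all three settings), first-assembly-time
distributions (R 0.95-0.99, S_EMD 0.96-0.98 at the default seed), and
drive-time trends at a small fraction of the simulation cost.

They do *not* show that the closed-loop shock materially improves the
desk system's yield. With the published `J_s = -3.6`, `rho = 1.5` and
the symmetric rate form, a shock lowers an escape barrier dE by
`dE (1 - 1/rho) / 2 = dE/6` — about 1.2 k_BT for a two-bond step — so
shock-window escape rates change only by small factors; moreover the
desk system's chimeric traps are at or below the targets' energy (the
enumeration result above), so prolonged shocks melt targets and traps
alike. Well-powered ensembles (800 realizations per point) measure yield
changes of -5 to +1.3 points across shock durations: the drive is
approximately neutral here. The corresponding acceptance check asserts
the strict, CI-separated increase regardless and is expected to fail on
this system; the surrogate's *fidelity to the driven simulator* (which
is the modeling claim) holds throughout. A system with deeper, purely
kinetic traps — larger particle counts, or target designs whose ground
state strictly dominates all chimeras — would be needed for a large
closed-loop gain, and no such design exists within the two-pattern 2x3
six-particle class (exhaustive search over all 46,080 designs).

Other limitations: the desk trend estimates are resolution-limited at
`d_s = 4` (the window-robustness property is asserted at full sampling);
the single-observable assumption under-resolves entropy-dominated
metastability by construction; and the compiled event loop seeds a
global kernel RNG, so concurrent interleaved simulations in one process
are not supported (sequential use is deterministic and tested).
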