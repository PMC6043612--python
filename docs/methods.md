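# Methods

## The problem

In time-lapse experiments on differentiating stem cells, the event of
interest — the commitment of a cell to one lineage — is invisible.
What is observed instead is the onset of a lineage marker (a surface
antigen or a fluorescent reporter), which appears only after a long and
variable expression delay, often several cell generations after the
decision itself.  In a *non-dividing* cell the decision time would be
unidentifiable.  In a genealogy it is not: cells that divide during the
delay pass their partial marker expression to both daughters, so
related cells show *correlated* onset times, and the correlation
pattern encodes how many generations ago the decision fell.

`treedelay` implements a generative model of this process, an exact
likelihood for annotated genealogies, maximum-likelihood parameter
estimation, and prediction of the most likely decision cells — plus the
validation machinery: a forward simulator, a branching-process model of
colony assays, a stochastic toggle-switch simulator, and marker-slope
statistics.

## Generative model

A genealogy is a rooted binary tree of cells with birth/end times in
hours from movie start; onsets are annotated per branch and are
terminal (tracking of a branch stops at detection).

**Decision process.** While a lineage is undecided, every cell commits
with hazard

    λ(t) = max(0, a0 + a1·t),      θ = (a0, a1)

on *absolute* experiment time: the decision probability depends on
factors that are not inherited, so decision times are independent
across cells.  The event density is ϕ(t) = λ(t)·exp(−Λ(t)) with
cumulative hazard Λ, and the decision CDF is Φ(t) = 1 − exp(−Λ(t)).
The clipping at zero is our extension for a1 < 0 (the hazard fitted to
real data decreases): beyond the zero-crossing Φ saturates at
1 − exp(−a0²/2|a1|), interpreted as cells that never differentiate.
Whether the original analysis clipped or constrained the hazard is not
documented; clipping is the simplest choice that keeps ϕ a valid
(sub-)density.

**Delay process.** After the decision, marker expression is a
birth-death process on copy number x: production at rate α (zeroth
order), degradation at rate γ·x, started at x0 = 0.  The marker is
detected when x first crosses the integer threshold x*; η = (α, γ, x*).
The master equation is solved on the transient states {0, …, x*−1}
with an absorbing boundary, by matrix exponentials of the transient
sub-generator (likelihoods multiply thousands of propagator entries, so
ODE-solver tolerances would be the accuracy bottleneck; `expm` keeps
errors at machine level).  The first-passage density is the boundary
flux ψ_x0(t) = α·P_{x0→x*−1}(t).

**Inheritance.** At division both daughters *copy* the mother's
expression state x (default).  The abstract state x stands for the
activation level of the expression cascade, not a literal molecule
count, so halving it at division would be a modelling claim we cannot
support; binomial partitioning is available behind
`inheritance_mode="binomial"` for sensitivity checks.  (In the toggle
simulator, where molecule counts *are* literal, binomial partitioning
is the default.)

## Likelihood: hidden trees

The onsets of a genealogy T can be produced by many "hidden trees":
assignments of the decision to an antichain of cells covering all
onsets; cells unrelated to any onset may also have decided invisibly
(their expression censored).  The likelihood sums over all of them.
One hidden tree factorises into the undecided part U — a product of
no-decision factors exp(−ΔΛ) per cell — and one term per
decision-rooted subtree D_i.  Within D_i the latent decision time t′ is
integrated against λ(t′)exp(−(Λ(t′)−Λ(birth))) (conditioning on
lineage survival to the cell's birth keeps the factorisation exact:
survival *before* that birth is contributed by the ancestors in U).
The delay process is then propagated down the subtree by message
passing over the expression state: a vector over {0..x*−1} per cell,
multiplied by the propagator over the cell's lifetime; at divisions the
daughters' messages are multiplied elementwise *before* the mother's
propagation (they are independent only given the mother's division
state — marginalising each daughter separately would be wrong, and is
tested against a nested-quadrature oracle); onset leaves contribute the
first-passage flux at the observed time, censored leaves the remaining
sub-threshold mass.

The sum over scenarios is evaluated by a post-order dynamic program:

    A(c) = L_D(c) + S_c · Π_children A(child)     (no onset in c)
    A(c) = L_D(c)                                 (onset in c)

where S_c is the cell's no-decision factor; A(root) is the tree
likelihood.  Replacing + by max with backtracking yields the most
likely hidden tree; carrying sorted k-lists yields the k best.  Ties
within 1e−12 prefer fewer decision cells, then lexicographic ids.  On
trees small enough for explicit enumeration the DP agrees with the
brute-force sum to ~1e−15 relative; this is an acceptance-level test.

**Numerics.** All event times are snapped to a uniform grid (default
0.25 h) shared by the trapezoidal decision-time quadrature and the
propagators, which are exact matrix exponentials on grid steps; the
decision-time integrand may be subsampled (`quad_stride`) for fitting.
Likelihoods are kept in log space with per-cell message rescaling, so
deep trees with a hundred onsets cannot underflow.  Halving the grid
step on a grid-aligned tree changes the log-likelihood of a typical
simulated tree by well under 0.05, and the fit-level grid (0.5 h,
stride 4 ≙ 2 h quadrature) changes the 200-tree total log-likelihood by
~2 units in ~90 000 — far below the curvature relevant for the
estimates.

## Fitting

Parameters are estimated by maximising Σ_i log L(T_i | θ, η) over the
tree set (GM- and MegE-fated sets independently, when fate labels are
present).  x* is discrete, so the likelihood is profiled over an
integer grid of thresholds (default {5, 10, 15, 20, 25, 30, 40, 50,
65, 80, 100}).  For each x* the continuous parameters are optimised
with a multiple-restart scheme: a Latin-hypercube sample over (α, γ)
(both log-uniform — delays require α/γ ≳ x*, so most of a linear γ
range would be dead), screened by likelihood, with bounded
Nelder-Mead polish of the best points.  The decision parameters (a0,
a1) are *profiled out* at every delay-parameter point, by Nelder-Mead
searches started both from a neutral constant-hazard anchor and from
the incumbent: the likelihood surface genuinely holds competing modes
(early decision + dispersed delay vs late decision + short delay; a0-
vs a1-driven hazards), and the anchored profile plus a
log(α)-diversity rule for choosing polish candidates is what makes the
global mode findable.  This structure also matches the engine's cost
profile: re-scoring θ reuses all cached delay messages and costs
milliseconds, while each new η costs a full message pass.

Default bounds: a0 ∈ [0, 1]/h, a1 ∈ [−0.05, 0.05]/h², α ∈ [0.01, 5]/h,
γ ∈ [0, 1]/h.  No confidence intervals are reported; per-restart traces
are exposed for diagnostics.

## Forward simulator

The simulator draws gamma-distributed cell-cycle lengths (default
12 ± 5 h, optionally prolonged in the first generations), applies the
decision hazard per undecided cell, runs the exact birth-death SSA for
the marker after the decision, copies (or binomially partitions) the
state at divisions, and right-censors at movie end (default 120 h, i.e.
up to ~10–12 generations).  By default tracking of a branch stops at
marker detection (`prune_after_onset`), recorded as a censored end at
the onset time — the tracking strategy of the real assays, and the
reason observed trees do not grow to 2^10 cells.  An optional uniform
tracking-loss hazard can censor cells early; the likelihood treats lost
and movie-end cells identically (both censor the delay process).

What the simulator does *not* emulate: measurement noise in onset
annotation, cell-cycle correlations between relatives, death/apoptosis,
and any spatial structure.  Passing recovery tests therefore shows the
estimator works when the model class is correct at realistic sizes and
censoring — not that real data satisfy the model.

## Colony branching process

The per-generation decision probabilities λ(i) = E[1 − exp(−∫_{s_i}
^{s_i+c_i} λ)] are Monte-Carlo averages over lineages (cycle lengths
drawn per generation; birth times accumulated along the same draws, so
the (s_i, c_i) expectation respects within-lineage correlation).  The
pure-colony probability follows the recursion f(N, i) = λ(i)p +
(1−λ(i))f(N−1, i+1)², evaluated iteratively; the mixed-colony
frequency is the complement, which deliberately classes never-deciding
colonies as mixed.  N defaults to 10 generations (a ten-day assay at
~12 h cycles, by when frequencies have stabilised).  The recursion is
cross-checked against a vectorised direct simulation of the branching
process (10⁶ colonies within 3 standard errors).

## Toggle switch

The tristable toggle is two species with symmetric production
(basal + amp·X^n/(K_self^n + X^n)) · K_rep^m/(K_rep^m + Y^m) and linear
degradation; defaults basal = 5/h, amp = 10/h, K_self = 30, n = 4,
K_rep = 25, m = 2, deg = 0.25/h were chosen (once, at build time) so
that the system is tristable with a progenitor residence time of one
to two cell cycles and copy numbers of a few tens.  Commitment is a
noise-driven escape and is effectively irreversible on culture
timescales, so the quasi-potential −log P is estimated from the pooled
occupancy of an ensemble of finite-horizon chains started in the
progenitor state; a single long run would only ever sample one
committed well.  Wells are local minima of the Gaussian-smoothed
potential (nearby pits merged within 8 copy-number units), basins are
their watershed regions, and a cell turns marker-positive on first
entry into a committed basin.  Exactly three wells are required, or the
parameterisation is rejected.

On genealogies simulated from this switch, the inference stack
(knowing nothing of the toggle) recovers a per-cell decision hazard of
~0.04/h — the reciprocal of the measured ~22 h escape time — with a
short expression delay, and the predicted decision cells are exactly
where the (A, B) trajectories diverge.  Slopes of the A-signal at the
predicted decision differ overwhelmingly from one generation earlier
(up for A-fated, down for B-fated decision cells).  Because trees with
a pure single-sided fate are mostly one-cell trees (early root
commitment), this comparison conditions per decision cell on the
lineage side of its descendant onsets rather than per whole-tree fate
label.

## Marker-slope statistics

Concentration (intensity/area) is fitted by ordinary least squares
within each cell; slopes are grouped by generation offset from the
predicted decision cells (−1/0/+1; onset cells are also pooled
separately), and compared with the two-sided Wilcoxon rank-sum test
(exact for small tie-free samples, tie-corrected normal approximation
otherwise).  Raw p-values are reported without multiple-testing
correction, matching how such comparisons are usually presented.
Sister-onset correlations are computed on birth-relative onset times:
pooling absolute times across pairs born at different moments shows
correlation even for independent sisters.

## Problem sizes and defaults used in the shipped experiments

Recovery experiments use 200 genealogies per replicate at the
documented generative defaults (a0 = 0.15/h, a1 = −0.002/h², α =
0.5/h, γ = 0.01/h, x* = 25, 12 ± 5 h cycles, 120 h movie; ~300 cells
and ~120 onsets per tree), fitted with a reduced restart budget
(thresholds {15, 25, 40}, 10 starts, one polish) and the 0.5 h/stride-4
grid; toggle experiments use 260 trees at a 96 h movie.  These sizes
give sup-norm Φ errors of a few percent and mean-delay errors well
inside 15%, and are the package's chosen trade-off between statistical
resolution and a test suite that runs on a laptop.

## Known limitations

* The decision hazard is linear (clipped) in absolute time only; no
  covariates, no cell-age dependence.
* x* is fitted on a grid; α and x* trade off strongly (the delay mean
  ≈ x*/α at small γ), so individual delay parameters are weakly
  identified even when Φ and the delay distribution are recovered well.
* Scenario-level MAP and k-best only; no per-cell posterior marginals
  of decision times (a mode of the decision-time integrand is exposed
  as a point estimate for alignment analyses).
* The colony model takes p_GM as a free parameter; fitting it to
  observed colony counts with uncertainty is out of scope.
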