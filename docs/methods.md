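# Methods

## Model

`hiermem` simulates a fully connected recurrent network of `N` rate-coding
neurons with activities `x_i ∈ [−1, 1]`:

    dx_i/dt = tanh( β ( Σ_{j≠i} J_ij x_j + γ η_i^μ ) ) − x_i

`J_ij` is the synaptic weight from neuron `j` to neuron `i` (no
self-connections), `β` the gain, and `γ η^μ` an applied binary input pattern
of strength `γ`.  Time is measured in units of the single-neuron relaxation
time.  Spontaneous activity is the `γ = 0` case.

The memory task is a set of `K·M` input/target associations `(η^μ, ξ^μ)`
organised in `K` categories of `M` members.  For each category one typical
input and one typical target are drawn uniformly from `{−1, +1}^N`; members
are noisy copies in which each element is flipped with probability `p_flip`,
so two members of a category have expected correlation
`C = (1 − 2 p_flip)²` while all other pairs — across categories, and every
input with every target — are uncorrelated.  Correlations hold in ensemble
expectation only; no per-realisation constraint or deduplication is applied,
because the generative process, not an exact correlation matrix, defines the
ensemble.

While an input is applied at the training strength `Γ`, synapses follow a
perceptron-like supervised rule driven by the mismatch with the associated
target:

    dJ_ij/dt = α (ξ_i − x_i) x_j ,   diagonal pinned at 0.

Neural and synaptic dynamics run concurrently: both are advanced by the same
forward-Euler step, and within one step both updates read the pre-step
`(x, J)`.  Each association is presented for a fixed duration; one epoch
presents all `K·M` associations in a fresh uniform permutation, and the
neural state carries over between presentations.  The initial `J` has
entries drawn from `{−1, +1}` with equal probability (zero diagonal) and the
initial state is uniform on `[−1, 1]^N`.

## Default parameters

| parameter | default | units | role |
|---|---|---|---|
| `N` | 100 | neurons | network and pattern size |
| `K`, `M` | 6, 6 | — | categories × members = 36 associations |
| `p_flip` | 0.15 | probability | within-category correlation C = 0.49 |
| `β` | 4 | — | gain |
| `α` | 0.01 | 1/unit time | learning rate (synaptic vs neural timescale) |
| `Γ` | 16 | — | input strength during learning |
| epochs | 100 | — | `K·M` × 100 presentations in total |
| presentation time | 10 | unit time | duration of one presentation |
| `dt` | 0.01 | unit time | Euler step for both x and J |
| recording stride | 0.1 | unit time | trajectory sampling interval |
| analysis window | 400 after 100 | unit time | temporal averages (overlaps, mean activities) |
| recall threshold | 0.9 | overlap | "successful recall" criterion |
| cluster cut | 0.3 | distance | dendrogram threshold on D = 1 − S |
| approach threshold | 0.5 | overlap | visit detection in spontaneous runs |
| spontaneous window | 10 000 | unit time | transition statistics |

Choices that the model statement leaves open, and how they were fixed:

- **Integrator.** Forward Euler with `dt = 0.01`.  The equation has unit
  relaxation time, so `dt = 0.01` resolves the fastest timescale by two
  orders of magnitude; since the update is the convex combination
  `(1−dt)·x + dt·tanh(·)`, states remain in `[−1, 1]^N` for any `dt ≤ 1`.
  Halving `dt` changes trajectories at first order in `dt` (verified against
  the closed-form decay solution).
- **Presentation schedule.**  The presentation duration is not part of the
  model statement.  The default is 10 unit time per presentation — ten
  relaxation times, long enough for the activity to settle toward the evoked
  attractor at `Γ = 16`.  An error-based early stop (`stop_tol`) and an
  i.i.d.-with-replacement order are available as options; in our
  calibrations the early stop degraded recall and was not adopted.
- **Initial synapse scale.**  `J_ij ∈ {−1, +1}` is implemented literally.
  An optional `j_scale` factor exists; scaling by `1/√N` degraded both
  recall and cluster structure in calibration runs and is not the default.
- **State reset.**  The neural state is *not* reset between presentations
  (the dynamics "run concurrently"); `reset_state=True` is available as an
  ablation.

## Analyses

**Overlap.** `m^μ = Σ_i x_i ξ_i^μ / N` measures proximity of the state to
target `μ` (1 = exact match).  The *overlap profile* is the vector of
temporal-mean overlaps with all `K·M` targets over a 400-unit window after a
100-unit transient; its shape (flat vs single-peaked) reads out which level
of the hierarchy the activity represents.

**Localization factor.** The concentration of a profile is summarised by the
participation ratio of the rectified, normalised profile: with
`p_μ = max(m̄^μ, 0) / Σ_ν max(m̄^ν, 0)`, `σ = Σ_μ p_μ²` ∈ `[1/(KM), 1]`.
`σ` rises as overlap concentrates on fewer targets; negative means are
rectified because localization concerns proximity, not anti-alignment.
This is a standard concentration index defined here for the profile; only
its *ordering* across conditions (spontaneous < intermediate < strong
input) is treated as meaningful, never its absolute value.

**Similarity and clustering.** For each input `μ` the temporal-mean activity
`x̄_μ` is computed over the same 400/100 window; responses are compared by
the un-centred cosine `S_μν = x̄_μ·x̄_ν / (|x̄_μ||x̄_ν|)`.  Group-average
(UPGMA) agglomeration on `D = 1 − S`, cut at distance 0.3, counts the
distinguishable response groups.  UPGMA and the cut use
`scipy.cluster.hierarchy` (`linkage(method="average")`, `fcluster`); the
test suite checks the merge heights against an independent brute-force
O(n³) agglomeration on small random matrices.  Scipy's deterministic
tie-handling makes dendrograms reproducible across platforms.

**Transition statistics.** In a spontaneous run (default 10 000 unit time,
no transient removed), an *approach* is a maximal contiguous episode in
which some target overlap exceeds 0.5; the approached target is the one with
the highest overlap within the episode and the visit is stamped at that
maximum (an episode-entry timestamp is available as an option).  Consecutive
episodes on the same target merge into one visit, because a continuous stay
cannot be distinguished from leaving and immediately returning; self-
transitions are therefore excluded by construction.  From the visit sequence,
`P_μν` = fraction of departures from `ν` that arrive at `μ` (columns over
visited sources sum to 1) and `T_μν` = mean elapsed time of those moves.
Category-level `P′_ab`, `T′_ab` aggregate the same counts over categories;
their diagonals collect within-category moves between distinct targets.
Cells with no observed transition are NaN and serialise as empty CSV fields,
never 0.  Overlaps are evaluated at the recording stride (default 0.1 unit
time); a finer stride can be configured.

**Lyapunov exponent.** Benettin-style tangent-space propagation: the tangent
vector is advanced with the exact Jacobian of the Euler map, renormalised
every step, and the post-transient mean log growth per unit time is
reported, together with the SD of the running estimate over the last quarter
of the run as a convergence gauge.  Defaults: 5000 unit time with a 500-unit
transient.  A two-trajectory finite-perturbation mode (separation 1e−8,
renormalised each step) is available for cross-validation.  On linear
systems the estimator matches `ln ρ(A)/dt` of the Euler map `A` to 1e−6.

**PCA projections.** Principal axes are fitted (mean-centred) on the pooled
recorded states of whatever trajectories are passed in — the model
statement does not single out a fitting set, so the default experiment pools
the spontaneous run with the evoked runs being plotted.  Components are
ordered by descending variance with the sign fixed so the largest-magnitude
loading is positive; stored patterns can be projected onto the same axes.

## What the synthetic task does and does not emulate

All inputs are generated internally; the pattern generator *is* the study's
stimulus model (hierarchically correlated binary patterns), not a stand-in
for recorded data.  It produces exactly two hierarchy levels (category →
member); the deeper "clusters of categories" seen in the similarity analyses
are emergent properties of the trained dynamics, not generated structure.
Real neural data would add observation noise, non-binary and sparse
activity, and non-stationary inputs, none of which are modelled; passing
tests therefore validate the dynamical mechanism, not any claim about
biological recordings.

## Problem sizes used in the shipped analyses

The packaged acceptance script and the heavier tests train two independent
networks (72 associations) rather than a ten-network ensemble, and estimate
pattern statistics from 200 generated sets; similarity/cluster analyses run
all 36 evoked simulations per strength at γ = 4, 6 and 16.  These sizes keep
a full rerun on one CPU core in the minutes range while leaving the ensemble
statistics within a few percent of their large-ensemble values (the
recall fraction, estimated from 72 Bernoulli draws, carries a standard error
of about 5 percentage points; cluster counts at weak strength vary by a few
units between networks).

## Known limitations

- Quantities tied to a single realisation in the original setting (e.g. a
  particular `S_67`) are reproduced only qualitatively; only ensemble
  statistics are asserted.
- The cluster count at weak input strength is steeply sensitive to the
  within-category similarity level relative to the 0.3 cut, and therefore
  carries the largest network-to-network spread of all reported statistics.
  In our trained ensembles the weak-input (γ = 4) responses are more
  category-merged than the nominal regime, so the cluster count there comes
  out well below ten while the γ = 16 count (> 30) and the within-category
  similarity orderings are reproduced.
- The spontaneous activity of our trained networks is locally strongly
  chaotic (λ ≈ 3.5) yet globally *sticky*: it lingers near individual
  target ghosts for hundreds of unit times and crosses the 0.5 approach
  threshold only a handful of times per 10 000 unit-time run.  Transition
  matrices are therefore sparsely populated at this run length, their
  category-level bias cannot be estimated reliably, and the
  localization-factor ordering (spontaneous < intermediate < strong input)
  fails on the spontaneous side because a 400-unit window often samples one
  long trapping episode instead of broad itinerancy.  We verified this is
  robust to the presentation duration (2–20 unit time) and to rescaling the
  initial synapses, so it reflects the trained-dynamics regime reached
  under these study conditions, not a tuning accident; longer runs and
  larger network ensembles would be required to characterise the itinerant
  statistics properly.
- Stochastic (noise-driven) dynamics, synaptic bounds/decay, sparse
  connectivity and capacity scaling versus `N` are out of scope.
- With `dt` as large as allowed (`dt → 1`) the integrator remains bounded
  but no longer resolves the relaxation dynamics; all shipped analyses use
  `dt = 0.01`.
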