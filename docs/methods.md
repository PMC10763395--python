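# Methods

This note documents the models, algorithms, parameter choices and numerical
safeguards behind `looplessflux`, and what the test suite does and does not
establish.

## Flux spaces and the loop law

A constraint-based model is the polytope
`Ω = {v | S·v = 0, lb ≤ v ≤ ub}` over reaction rates `v` (units follow the
model, conventionally mmol/gDW/h; the code only assumes consistency).
Reactions are partitioned structurally: a column with nonzero entries of
one sign only is an **exchange** (pure source/sink across the system
boundary); all others are **internal**. No identifier conventions (such as
`EX_` prefixes) are consulted — the rule is scale-invariant and works on
arbitrary toy fixtures. The partition matters because the loop law binds
only internal reactions: a flux vector is **loop-active** when a nonzero
`g ∈ null(S_int)` is sign-compatible with it (`g_i·v_i ≥ 0` on internal
reactions, `g_i = 0` where `v_i = 0`). `Ω_loopless` excludes such vectors
and the zero vector; it is in general non-convex, which is the entire
difficulty the sampler addresses.

## Loop detection

The detector maps the internal part of `v` to a sign pattern in
`{−1, 0, +1}` using the threshold `tol_zero` (default `1e-9`; fluxes below
it count as exactly zero — this threshold decides borderline verdicts and
is therefore recorded in archive metadata). The existence question is an LP
feasibility problem solved in null-space coordinates `g = N_int·α` (c
variables instead of n_int; identical mathematics, cheaper when the cycle
space is small), with "g nonzero" made LP-expressible through the
normalization `Σ pattern_i·g_i ≥ 1` — any positive right-hand side is
equivalent by scaling. Because the verdict depends on `v` only through its
sign pattern, verdicts are cached per pattern; on fixture-scale networks
the per-proposal cost collapses to a dictionary lookup after warm-up.

A brute-force oracle (`brute_force_loop_oracle`) validates the detector on
small instances by enumerating every subset of the active pattern and
asking, per subset, for a circulation strictly active on all of it — a
structurally different LP (per-coordinate sign bounds over raw internal
fluxes, no basis, rank prefilter on the candidate columns). The suite
checks detector/oracle agreement on 1,000 randomized cases; minimal
feasible supports yield the sign-compatible type-III rays.

## Preprocessing

1. **Flux variability analysis** (per-reaction LP min/max over `Ω`) finds
   blocked reactions; reactions with `|v_min|, |v_max| ≤ tol_zero` are
   removed together with orphaned metabolite rows (idempotent; an
   `index_map` recovers original indices). This is a deliberate
   simplification of sparse-null-space preprocessing pipelines: downstream
   code needs only an unblocked model and a spanning sparse cycle basis.
2. **Null bases.** `N_perp` is an orthonormal basis of `null(S)` (SVD),
   used for isotropic Hit-and-Run directions and drift control. `N_int` is
   a basis of `null(S_int)` computed exactly over the rationals (sympy row
   reduction; stoichiometric coefficients are small rationals) followed by
   a greedy pairwise-elimination pass that shrinks column supports.
   Supports are inclusion-minimal within the basis, not globally minimal —
   global minimization is NP-hard and unnecessary here.
3. **Seed points.** A random `±1` objective is maximized over `Ω` (an
   over-dispersed vertex), internal cycles are stripped with a cycle-free
   LP (exchanges held fixed, internal fluxes confined between 0 and their
   current value, total internal magnitude minimized — circulation cancels,
   net conversion survives), and the result is verified loopless. Up to 50
   objectives are tried; if every attempt collapses to the zero vector the
   loopless space is reported degenerate. This procedure is this package's
   own choice of a defensible over-dispersion scheme; alternatives (e.g.
   warmup chains) are exposed via the CLI `--warmup` flag, which defaults
   off to match the benchmark protocol of starting directly from
   over-dispersed optimization seeds.

Tolerances: `tol_eq = tol_zero = 1e-9`, overridable. The LP backend is
HiGHS via scipy with the primal feasibility tolerance tightened to
`1e-10`, because archived samples are audited against the `1e-9` contract.

## Samplers

**ADSB.** `K` non-interacting chains, each a set of `k` loopless points.
Defaults: `k = min(2d+1, 50)` (d = null-space dimension), which guarantees
the spanning condition `rank(differences) = min(k−1, d)` whenever
attainable; when `k < d+1` the set spans only conditionally and a warning
is recorded in chain state and metadata. `K = 4` by default — a fixed value
rather than the machine's core count, because archives must be
bit-reproducible from config + seed on any machine; raise it freely.
Initialization draws `K·k` seed points and, when LP vertices coincide
(e.g. a 1-D flux line has only two vertices, one of them zero), applies
random loopless chord moves until the spanning rank is reached.

Steps follow the adaptive-direction scheme: `u* = (v_1 − v_2)/‖·‖`, chord
limits from a ratio test against the box (components with `|u_i| ≤ 1e-12`
impose no constraint; the interval always contains 0), uniform `λ*`,
shrink-on-reject. A failed shrink (interval narrower than
`eps_shrink = 1e-8 ×` initial width, relative) retains the current point,
which preserves the invariant distribution for slice-type shrinkage;
degenerate directions (`v_1 = v_2`) skip the step and count toward
thinning, so wall-clock behavior stays predictable. Run defaults follow
the established benchmark protocol: `n_samples = 2·10^5`,
`thinning = 100` attempted steps per stored point, `burn_in = 2·10^4`
stored points discarded. The stored point of each thinning block is the
slot targeted by the block's last step.

**Numerical drift.** Normalizing `u* = (v_1 − v_2)/‖v_1 − v_2‖` divides
the points' mass-balance round-off by `‖v_1 − v_2‖`; when members of the
set are close this amplifies the residual *multiplicatively* per step (it
grew from 1e-13 to order 1 within ~10³ steps on the 3-cycle fixture during
development). Three safeguards: the direction is re-projected onto
`null(S)` every step (cost `O(n·d)`), all points are re-projected every
`reproject_every = 1000` iterations, and each stored point is re-projected
at storage time. The projection is the plain orthogonal projector
`N_perp·N_perpᵀ` (the constraint is homogeneous), followed by clipping into
bounds and a loop re-audit; a point whose loop verdict would flip under
projection — possible only at the tolerance boundary — is left unprojected.
Every archive is audited post hoc: max `|S·v|` and bound violations must
be `≤ tol_eq` and (for ADSB/ll-ACHRB) zero loop-active rows; failure
raises an internal-consistency error rather than returning bad samples.

**Hit-and-Run** samples `Ω` with isotropic directions in null-space
coordinates (`u = N_perp·z`, `z` standard normal). With
`loopless_filter=True` the loop detector *marks* stored draws
(`loop_active_fraction` in metadata) without removing them — the
sample-then-verify protocol used when checking a convex sampler against
the loopless space.

**ll-ACHRB** replaces the adaptive direction with an artificial-centering
one (`u ∝ v_rand − mean(set)`) and keeps the same chord/shrink/swap
machinery. The running center depends on chain history, so the iterates do
not form a Markov chain; archives carry `non_markovian: true`.

Chains own independent `SeedSequence`-spawned RNG streams; results are
identical whether chains run sequentially or across `n_workers` processes
(parallelism is across chains only; within-chain computation is
sequential).

## Diagnostics

* **psrf**: `sqrt(var⁺/W)` with `W` the mean within-chain variance,
  `var⁺ = (N−1)/N·W + B/N`. Identical chains give the floor
  `sqrt((N−1)/N)`. A split-chain variant (each chain halved, catching
  within-chain drift plain psrf misses) is available and labeled; the
  plain variant is the default.
* **ESS**: `M·N/(1 + 2Σρ̂_t)` with autocorrelations combined across chains
  Stan-style (`ρ̂_t = 1 − (W − mean_c acov_{c,t})/var⁺`, FFT
  autocovariances) and truncated at the first non-positive pair sum
  (Geyer's initial-positive-sequence rule); capped at `M·N`, floored at 1.
  The suite checks it within a factor 1.5 of the AR(1) closed form
  `M·N·(1−φ)/(1+φ)` and against arviz's independent implementation.
* **Time per effective sample**: wall time divided by mean ESS over
  non-constant fluxes — the standard cost-per-quality metric for sampler
  comparison. Fluxes with within-chain variance `≤ 1e-14` are flagged
  constant and excluded from averages rather than dividing by zero.
* **Cross-sampler comparison**: per-flux Wilcoxon signed-rank on paired
  draws, Benjamini–Hochberg adjusted across fluxes. The test's nominal
  level assumes independent pairs, so draws are first strided down to
  their effective information content (total/median ESS) — without this,
  autocorrelation inflates false positives by orders of magnitude. The
  stride, test name and adjustment are recorded in the table attributes.

## Synthetic fixtures: what they emulate and what they do not

`make_toy_network` builds a linear uptake→conversions→secretion backbone
and closes `n_cycles` internal cycles with reversible chord reactions over
edge-disjoint backbone segments, so `dim null(S_int)` equals the requested
cycle count exactly and the loopless space is small enough to reason about
by hand (the 3-cycle fixture's loopless geometry is a 2-D polytope minus a
known wedge). Bounds are heterogeneous (uniform on `bound_scale × [5, 15]`,
deterministic per seed) to avoid accidental symmetry. `extra_exchanges`
adds secretion reactions on intermediate metabolites, raising the polytope
dimension without creating cycles — used to build loop-free but
multi-dimensional test targets. `make_box_model` gives the
stoichiometry-free box whose uniform moments are known in closed form
(mean `(lb+ub)/2`, variance `(ub−lb)²/12`).

These fixtures exercise the algorithmic contracts (looplessness,
uniformity, convergence, determinism) but are *not* genome-scale models:
they have no coupled nested cycles sharing many reactions, no
six-orders-of-magnitude bound heterogeneity, and no reactions that can
never carry flux simultaneously. Passing tests therefore certify
correctness of the machinery, not wall-clock competitiveness or mixing
behavior at genome scale. Problem sizes in the suite and in
`scripts/acceptance.py` (10^4–2·10^4 stored draws, thinning 2–10) were
chosen so the statistical assertions have comfortable power at
three-standard-error tolerances on these fixtures; the sampler defaults
remain the benchmark settings above.

## Known limitations

* The sign-pattern tolerance makes borderline loop verdicts
  tolerance-dependent; a flux hovering at `~1e-9` around zero can flip the
  verdict (metadata records the threshold for audit).
* The support-minimization pass on `N_int` is a heuristic; pathological
  cycle bases could remain denser than optimal (harmless for correctness,
  mildly wasteful for LP size).
* ll-ACHRB is provided for comparison only; it has no convergence
  guarantee and should not be used when unbiased statistics matter.
* On models whose reactions cannot all carry flux simultaneously without
  violating the loop law, only a conditional subspace can be explored;
  the spanning warning in chain metadata is the signal to inspect.
* Exact rational null-space computation (sympy) is comfortable up to a few
  hundred internal reactions; very large models would want a sparse
  numerical fallback, which is out of scope here.
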