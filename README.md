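# looplessflux

Uniform random sampling of the **loopless** mass-balanced flux solution
space of constraint-based metabolic models.

## The problem

For a metabolic network with stoichiometric matrix `S ∈ R^{m×n}` and flux
bounds `lb ≤ v ≤ ub`, the mass-balanced solution space

```
Ω = { v | S·v = 0, lb ≤ v ≤ ub }
```

is a convex polytope that classic Monte Carlo samplers (Hit-and-Run and its
descendants) can explore. Real flux states, however, must also obey the
*loop law* — the flux analogue of Kirchhoff's second law: no net flux around
a closed cycle of internal reactions. Writing `S_int` for the stoichiometry
restricted to internal (non-exchange) reactions, a flux vector `v` carries
an *active loop* iff a nonzero circulation `g` exists with

```
S_int·g = 0,   g_i·v_i ≥ 0 for all internal i,   g_i = 0 where v_i = 0,
```

i.e. a nonnegative combination of type-III extreme pathways (internal
cycles with no net conversion) hides inside `v`'s sign pattern. The
loopless space

```
Ω_loopless = { v ∈ Ω | no active loop, v ≠ 0 }
```

is almost surely **non-convex**, and convex samplers cannot avoid it:
on a simple 3-cycle network roughly a third of Hit-and-Run draws violate
the loop law (see the worked example). This package is for modelers who
need unbiased statistics (flux means, ranges, correlations) over the
*thermodynamically sensible* part of the flux space.

## The algorithm

**ADSB — Adaptive Direction Sampling on a Box.** Each of `K` independent
chains carries a current set `V = {v_1, …, v_k} ⊂ Ω_loopless`. One step:

1. pick a current point `v_c` and two other distinct members `v_1, v_2`;
2. move along the chord of the bound box through `v_c` parallel to
   `u* = (v_1 − v_2)/‖v_1 − v_2‖` (differences of mass-balanced points stay
   mass-balanced, so `S·v = 0` holds along the whole line);
3. draw `λ* ~ Uniform(λ_min, λ_max)` on the chord and propose
   `v* = v_c + λ*·u*`;
4. test `v*` for active loops — a *topological* test that needs only the
   sign pattern of the internal fluxes, decided by one small LP in
   null-space coordinates (verdicts are cached per sign pattern);
5. if `v*` is loop-active, shrink the chord toward `v_c` on the rejected
   side and redraw (the shrinking-interval rule from slice sampling);
   otherwise swap `v*` for `v_c` and continue.

Because directions come from the current population, they adapt to the
geometry of the target region; on convex regions the chain targets the
uniform distribution exactly, and on the non-convex loopless space it
retains that target as long as the current set spans the space. Hit-and-Run
(`run_hr`, over `Ω`, optionally marking loop-active draws) and ll-ACHRB
(`run_ll_achrb`, artificial-centering directions, not a Markov chain) are
included as comparators, and a diagnostics suite computes the Gelman–Rubin
potential scale reduction factor (psrf), effective sample size, time per
effective sample, and rank-based cross-sampler comparisons with
Benjamini–Hochberg adjustment.

## Worked example

```python
import looplessflux as lf

# engineered 3-cycle network: ->A, A->B, B->C, C-> and a reversible chord C->A
model = lf.make_toy_network(
    lf.ToyNetworkSpec(n_cycles=1, cycle_lengths=[3], backbone=2, seed=1)
)
fs = lf.build_flux_space(model, seed=0)
print(f"dim(flux space) = {fs.dim}, independent internal cycles = {fs.n_loops}")

opts = lf.SamplerOptions(n_samples=10_000, K=4, thinning=10, burn_in=250, seed=42)
adsb = lf.run_adsb(fs, opts)
print(f"ADSB: loop-active rows = {adsb.meta['audit']['loop_active_rows']}")

hr_opts = lf.SamplerOptions(n_samples=10_000, K=4, thinning=10, burn_in=250,
                            seed=42, loopless_filter=True)
hr = lf.run_hr(fs, hr_opts)
print(f"HR:   loop-active rows = {100 * hr.meta['loop_active_fraction']:.1f}%")

rep = lf.diagnose(adsb)
print(rep.to_frame().round(3).to_string(index=False))
```

prints

```
dim(flux space) = 2, independent internal cycles = 1
ADSB: loop-active rows = 0
HR:   loop-active rows = 31.9%
reaction  psrf    n_eff   mean    sd  constant
     SRC   1.0 8783.275  6.302 2.335     False
      B1   1.0 8318.142  2.846 1.775     False
      B2   1.0 8318.142  2.846 1.775     False
     SNK   1.0 8783.275  6.302 2.335     False
      L1   1.0 8683.912 -3.456 2.165     False
```

Reading this: the preprocessed space is 2-dimensional with one engineered
internal cycle. All 10,000 ADSB samples are loopless by construction, while
31.9% of plain Hit-and-Run draws over the convex relaxation carry an active
loop — exactly the bias loopless sampling removes. All per-flux psrf values
sit at 1.0 (4 chains agree) and each flux is worth ~8,000–8,800 independent
draws. `SRC = SNK` row-wise (total uptake equals secretion), and `L1`'s
mean is negative: running forward together with the `B1`/`B2` backbone
would close the triangle and violate the loop law, so the reversible chord
almost surely carries reverse flux, acting as a parallel route instead of a
cycle.

The same pipeline is available from the shell:

```sh
looplessflux make-fixture --cycles 1 --seed 1 --out cycle3.json
looplessflux sample --model cycle3.json --sampler adsb \
    --n-samples 10000 --thinning 10 --burn-in 250 --seed 42 --out run1/
looplessflux diagnose run1/ --out diag1/
```

Archives are CSV + a JSON metadata sidecar; a run is bit-reproducible from
the sidecar's config and seed alone.

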