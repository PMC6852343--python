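# Methods

## The leaky-cable model

A parallel-veined blade is idealised as a conduit of axial conductance
K_x (m⁴ s⁻¹ MPa⁻¹) running the blade length *l* (m), leaking radially
through the outside-xylem tissue with conductance k_ox per unit leaf
area (m³ m⁻² s⁻¹ MPa⁻¹) over a blade of width *w* (m). The steady-state
solution gives the whole-leaf conductance

    K_leaf = k_ox · tanh(αl) / (αl),    α = √(w · k_ox / K_x)  [m⁻¹].

This formulation is preferred to a series/parallel electrical analogue
because the axial and radial pathways are neither strictly in series nor
in parallel: water leaves the cable continuously along its length. Two
limits anchor intuition: αl → 0 (non-limiting xylem) gives
K_leaf = k_ox, and large αl means the distal blade is hydraulically
starved, K_leaf ≈ k_ox/(αl). Because tanh(x)/x ≤ 1, the solved k_ox is
never below the measured K_leaf.

Note on the α expression: the defining relation is dimensionally forced —
`w·k_ox/K_x` has units m⁻², so α must be its square root for αl to be
dimensionless. The package uses α = √(w·k_ox/K_x) throughout.

### Inverse solution

Measurements give K_leaf (evaporative flux method) and K_x (anatomy);
k_ox is the unknown. The forward map
g(k_ox) = k_ox·tanh(c√k_ox)/(c√k_ox), c = l√(w/K_x), is strictly
increasing, so the root is unique. `solve_kox` starts a fixed-point
iteration k_ox ← K_leaf·αl/tanh(αl) at k_ox = K_leaf, halving its step
whenever the update oscillates (relative step tolerance 1e-12, cap
10 000 iterations); if the iteration stalls it falls back to Brent root
bracketing on [K_leaf, 2ᵏ·K_leaf]. Either way the returned state must
satisfy the forward relation to a relative residual ≤ 1e-10 or a
`ConvergenceError` is raised — a partial result is never returned. A
deliberately independent plain-bisection solver (`solve_kox_bisection`)
exists solely to cross-check the primary path; the test suite compares
the two on random instances. tanh(x)/x is evaluated as 1 for x < 1e-8 to
avoid 0/0.

All cable arithmetic runs in volumetric units
(m³ m⁻² s⁻¹ MPa⁻¹); conversion to the molar reporting unit
(mmol m⁻² s⁻¹ MPa⁻¹) happens only at the reporting boundary, at 20 °C,
so forward/inverse round trips are conversion-free.

### Sensitivity analysis

Holding the wet-baseline k_ox fixed and scaling K_x by f ∈ (0, 1]
rescales αl by 1/√f, so the back-calculated K_leaf relative to baseline
reduces algebraically to

    ratio(f) = √f · tanh(αl₀/√f) / tanh(αl₀),

which is strictly increasing with ratio(1) = 1. `find_halving_fraction`
bisects this curve for ratio = 0.5 (|ratio − 0.5| ≤ 1e-9); at αl₀ = 0.80
the halving sits at f ≈ 0.114, i.e. K_x must lose ~89% of its ideal
value before K_leaf halves. The exact model value at f = 0.05 is 0.336;
a smoothed regression through such a curve reads closer to 0.30, and the
package reports the model value, not a smoothed one. The default grid is
100 log-spaced fractions on [0.01, 1].

## Xylem conductance and embolism

K_x = Σ π d⁴/(128η) over all tracheids, with pressure in MPa. The
measured sample (≥ 1 vein, each a list of lumen diameters in μm) is
scaled to the whole leaf by multiplying the *mean per-vein* Poiseuille
sum by the vein census round(density × width), floored at 1 — the census
must be a whole number. Diameters are inscribed-circle values with no
ellipse correction; pit-membrane resistance, taper and connectivity are
not modelled, so K_x is an ideal upper bound and the xylem's reported
resistance share a lower bound. Dye surveys give percent embolism as
100·(unstained/total); multiplying K_x by the stained fraction gives
K_x-stained. Because the inverse solve must still reproduce the same
measured K_leaf with a smaller axial conductance, k_ox-stained ≥ k_ox
always — a monotonicity the tests verify dataset-wide.

## Flux measurements

Transpiration E is the OLS slope of balance mass vs time (g s⁻¹),
converted through the molar mass of water and the projected leaf area to
mmol m⁻² s⁻¹. The default analysis window drops the first 600 s of the
record (equilibration) and uses everything after; a non-negative slope
is an error, never a zero. K_leaf = E/(−Ψ_leaf) with Ψ_leaf < 0 required.

g_min = (mass-loss rate)/(2·A·ΔC): both faces of the blade lose water,
hence 2× the projected area A; ΔC = C_sat(T_leaf) − RH·C_sat(T_air) with
the leaf interior taken saturated at leaf temperature (the standard
psychrometric convention; the alternative — air temperature — is not
used). C_sat comes from the Tetens saturation vapour pressure over
liquid water and the ideal gas law. ΔC ≤ 0 is a domain error.

## Water properties

Viscosity uses the Vogel correlation
η = 1e-3·exp(−3.7188 + 578.919/(T_K − 137.546)) Pa·s (≈1.0017e-3 at
20 °C, within 0.3% of tabulated values on 0–50 °C); molar density
interpolates a 0–50 °C liquid-water density table at 5 °C steps and
divides by 18.015 g mol⁻¹ (55 410 mol m⁻³ at 20 °C). Exact third-digit
agreement with any particular lab spreadsheet is not expected and not
required — conductance ratios and partitions are insensitive to these
constants at the 0.1% level. Temperatures outside 0–50 °C raise a
domain error everywhere.

## Synthetic experiments

The generator emulates a three-treatment (wet / dry / rewetted) drought
study, default 7 plants per treatment, each plant drawn from a
deterministic substream of a single global seed (`(seed, plant index)`),
so any subset regenerates identically.

Per plant: blade width ~ N(3, 0.3²) cm and length ~ N(25, 2²) cm
truncated positive, projected area 0.85·w·l; vein density
~ N(3.47, 0.12²) mm⁻¹ (equivalent to a ~288 μm interveinal distance);
20 sampled veins of 5 tracheids with lognormal lumen diameters (median
10 μm, log-SD 0.25). K_x follows from the anatomy; the truth k_ox is
centred so the wet-condition αl ≈ 0.8 for each plant's own geometry and
xylem, with 10% lognormal biological spread. The dry treatment multiplies
truth k_ox by 0.5 (and rewetted by 1.0): the degradation is placed in the
outside-xylem pathway, with K_x anatomy untouched and embolism expressed
only through binomial stained-vein counts (probabilities 0.815 / 0.648 /
0.765 per treatment). Water potentials are N(−0.46 / −0.78 / −0.42,
0.08²) MPa. Because αl co-varies with k_ox, halving k_ox lowers K_leaf by
≈45%, not exactly 50% — the treatment effect on K_leaf is emergent, not
imposed.

Measured records are then synthesised: a piecewise-linear balance series
whose steady slope encodes E = K_leaf·(−Ψ) times a mean-one lognormal
measurement factor (CV `noise_cv`, default 0.15), preceded by a steeper
600 s equilibration segment that the analysis must discard; an analogous
dark series for g_min; anatomical trait vectors drawn from
per-treatment means/SEs typical of such studies. With `noise_cv = 0`
and biological spread off, the full pipeline is an identity: every truth
parameter is recovered to better than 1e-6 relative, which is what the
end-to-end tests assert.

What the generator does **not** emulate: balance quantisation and drift,
non-stationary transpiration, within-leaf gradients of vein geometry,
correlated trait noise, or any real anatomical covariance beyond the
shared treatment effect. Passing recovery tests therefore demonstrates
the correctness of the computational chain under the stated statistical
structure, not robustness to every artefact of real balance data.

## Statistics

Treatment summaries report means ± SE (SE = SD/√n) with classical
one-way ANOVA (F = MS_between/MS_within) across conditions; identical
groups report F = 0. Pearson r with two-sided p is computed pairwise
with pairwise-complete observations; pairs with fewer than 3 complete
rows or a zero-variance member are reported as missing, never as 0.
Bonferroni adjustment is available as a CLI flag and off by default.
Per-plant solver or flux failures skip the row with a logged warning
rather than aborting a run, and all outputs are sorted by
(condition, plant_id) for byte-stable reproducibility.

## Problem sizes

Default analyses use 7 plants × 3 treatments; the solver consistency
sweeps use 1000 random leaves spanning αl from ~10⁻³ to ~10²; the
Hagen–Poiseuille oracle check uses 100 random anatomies. The whole test
suite and the acceptance script each complete in a few seconds on one
core.

## Known limitations

- K_x is a theoretical maximum; real axial resistance is higher, so the
  xylem's resistance share is a lower bound.
- The cable model assumes a single vein rank with uniform leakage along
  the length; vein-order-resolved network effects are out of scope.
- g_min has no boundary-layer correction (measurements assume a fan).
- The inverse solve propagates, not absorbs, measurement error in
  K_leaf and K_x; no uncertainty quantification is attached to k_ox.
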