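# Methods

## Model

The channel is described as an equilibrium (grand-canonical) binding
polynomial over joint ligand-occupancy states (i Na⁺, j Gβγ), with no
kinetics: the published activation curves are steady-state, so only the
relative statistical weights of occupancy states matter. Relative to
the reference state (minimal Na⁺ occupancy, no Gβγ),

    w(i,j) = C(n_var, i−i₀) (Na/K_dn)^(i−i₀)
           · C(4,j) (x/K_db)^j · b^(−j(j−1)/2) · η^(−i·j)

**Conventions adopted.** The binding literature is loose about where a
cooperativity factor sits; the conventions here are fixed by two
anchors. (1) The per-step convention for b — the j-th Gβγ binds with
microscopic dissociation constant `K_db·b^(j−1)`, giving the pairwise
factor `b^(−j(j−1)/2)` — reproduces the measured normalized activity
0.018 at (x = 0.001, Na = 0) to within 7% with the published GIRK4
parameters; the opposite sign convention is off by orders of magnitude.
(2) The cross term `η^(−i·j)` (each bound Na⁺ multiplies every Gβγ
dissociation constant by η) is fixed by the exact collapse of the
GIRK1/4 model at zero Na⁺ to a Gβγ ladder with effective constant
`K_db·η²`; thermodynamic reciprocity (bound Gβγ scaling the Na⁺
constant by η) follows automatically from the single weight expression.
Na⁺ binding itself is non-cooperative (binomial with one K_dn).

Only states with full Gβγ occupancy conduct (j_open = 4); the
`j_open` argument exists solely for the stoichiometry comparison, where
the conducting set becomes the states with exactly k Gβγ. θ(i), the
open-state activity, interpolates linearly between θ(0) and θ(4) for
the homo-tetramer and the N217D variant and is free per accessible i
for GIRK1/4. θ > 1 is legal: currents are normalized to the
experimental fully-activated reference, which the fitted θ absorbs.

**Variants.** GIRK4: i = 0…4 (25 states). GIRK1/4: the two GIRK1
subunits are treated as permanently Na⁺-occupied, i = 2…4 (15 states),
with the i = 2 row as reference. GIRK1(N217D)/4 is modelled on the full
25-state grid because the mutation restores Na⁺ sensitivity (its θ(0)
is a reported quantity, so i = 0 states must exist).

**Units.** Gβγ concentration is Ni-NTA-lipid mole fraction throughout;
K_db is calibrated in those units. The 1:3 sGβγ:Ni-NTA stoichiometry
(`gbg_surface_density`) is a reporting convenience and never enters the
weights.

## Parameters

| name | meaning | units | reference value (GIRK4) |
|---|---|---|---|
| K_db | Gβγ dissociation constant, ligand-free channel | Ni-NTA mole fraction | 0.004 |
| K_dn | Na⁺ dissociation constant | mM | 50 |
| b | per-step Gβγ cooperativity | – | 0.6 |
| η | Gβγ–Na⁺ cross-cooperativity | – | 0.7 |
| θ(i) | open-state activity at Na⁺ occupancy i | normalized current | 0.6 → 1.2 |

Reference sets for all three variants live in
`girkfit.REFERENCE_PARAMETERS` (GIRK1/4: K_db 0.004, η 0.8,
θ(2…4) = 1.1, 1.2, 1.1; N217D: K_db 0.0024, η 0.71, θ(0) 0.45,
θ(4) 1.1 with b = 0.6).

## Numerics

Weights are computed as direct float64 products. Within the fitting
bounds (K_db ≥ 1e−5, x ≤ 0.015, b, η ≥ 0.05) the largest possible
weight is far below float64 overflow, and exact direct summation is
what the brute-force enumeration oracle in the test suite compares
against at 1e−12 relative. `occupancy_distribution` falls back to a
log-sum-exp renormalization only if a partition sum ever turns
non-finite (unbounded user parameters). `0⁰ = 1` handles the x = 0 and
Na = 0 boundaries exactly, so A(x=0) is exactly 0 and the GIRK1/4
zero-Na⁺ degeneracy (only the baseline row contributes) needs no
special casing.

## Fitting

Bounded nonlinear least squares on the per-point residuals
(observed − predicted mean activity). Default objective is unweighted;
an SEM-weighted mode divides by `max(SEM, 0.005)`, the floor preventing
near-zero SEMs from dominating. Bounds: K_db ∈ [1e−5, 1],
K_dn ∈ [1, 5000] mM, b, η ∈ [0.05, 5], θ ∈ [0, 3] — generous log-scale
boxes around the reference values. K_db, K_dn, b, η are optimized on a
log10 scale (they are scale parameters spanning decades), θ linearly.

The b–η trade-off creates local minima, so fits are multi-start: the
default is 32 log-uniform initializations inside the bounds (θ draws
floored at 1e−3), each refined by a trust-region reflective solver at
tight tolerances, best SSR kept; deterministic given the seed. Standard
errors come from the Gauss–Newton curvature at the optimum
(`cov = s² (JᵀJ)⁻¹`, J by finite differences clamped to the feasible
box); a residual-resampling bootstrap is provided as an independent
cross-check — how the published "±" values were obtained is not stated,
so both routes are exposed. Adjusted R² is always computed on the
unweighted scale: `1 − (1−R²)(n−1)/(n−p−1)` with SST about the dataset
mean. Parameters that land on a bound are recorded on the results
object and raised as a warning, not an error (with 27 points the
GIRK1/4 θ(3), θ(4) are genuinely weakly identified and occasionally
pin; their published uncertainties, ±0.8, say the same thing).

The N217D protocol holds b = 0.6 and θ(4) = 1.1 fixed at the GIRK1/4
values; held parameters are excluded from the free vector entirely, so
they cannot drift, and are recorded in the `fixed_map` of every result
for exact replication.

**Open-stoichiometry selection** refits the dataset under each
candidate conducting set (exactly k Gβγ, k = 1…4, occupancy grid
unchanged) and ranks candidates by SSR; ties within 1e−9 go to the
smaller k (conservative: never claim more required Gβγ than the data
force).

## Synthetic data

The generator emulates the bilayer titration design: Na⁺ ∈ {0, 8, 32}
mM; Gβγ grid = 0 plus eight log-spaced Ni-NTA fractions across
2×10⁻⁴–0.015 (the stated experimental range; log spacing covers the
sigmoid rise around K_db ≈ 0.004, and the exact sampled fractions of
the real experiment are not public); n = 3 replicate bilayers per
point; replicate activity = model + Gaussian(0, σ = 0.03), truncated at
zero (normalized inward current cannot be negative; truncation rather
than folding keeps the mean bias negligible at this σ). σ = 0.03 is
chosen to match the error-bar scale of the published curves and is a
config knob, not a claim. Mean and SEM = sd/√n are recorded per point.

What it deliberately does not emulate: fusion stochastics and channel
orientation, channel-count variability (normalization cancels it —
`simulate_bilayer_raw` demonstrates this), activity-dependent noise,
time-series traces, PIP₂ dependence (saturating throughout), or
rundown. Passing recovery tests therefore show the *pipeline* is
correct and the design is informative under idealized noise — not that
real bilayer noise is Gaussian and constant.

## Validation protocols and problem sizes

`girkfit.protocols` packages the two simulation studies.
*Recovery*: 50 seeds × (simulate at the reference truth → refit);
medians of the free estimates summarize accuracy. Refits use 16 starts
— multi-start count only affects how reliably the global optimum is
found, and 16 was enough for every seed tested; the library default
stays 32. *Stoichiometry*: 100 seeds of 4-Gβγ-generated data, each
refit under k = 1…4 with 6 starts; the fraction of seeds where SSR(4)
is strictly smallest quantifies how firmly this design identifies the
4-Gβγ requirement (≥95% expected). Noiseless variants of the same loop
check exact identifiability (recovery to ≤1e−6 relative for all three
variants).

`scripts/acceptance.py --seed S --out f.json` reruns the deterministic
forward-model point and the 50-seed GIRK4 recovery (all child seeds
derived from S) and writes the four headline numbers.

## Limitations

- Equilibrium only: no gating kinetics, no single-channel analysis,
  no voltage dependence or rectification.
- Subunit-arrangement isomers of the hetero-tetramer are not resolved;
  GIRK1/4 is assumed 2:2 with the two GIRK1 sites equivalent.
- K_dn is weakly identified at this design (three Na⁺ levels); its
  recovery tolerance is correspondingly wide, matching the published
  uncertainty pattern (±300 mM for GIRK1/4).
- The cell-mixture predictor (`simulate_cell_na_experiment`) is a
  population-weighted sum of the two variants' activities at one
  effective Gβγ density — a qualitative account of whole-cell Na⁺
  insensitivity, not a quantitative cell model.
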