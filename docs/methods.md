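# Methods

## Scope and model

`dynmet` turns a metabolic reaction network into a parameterised system of
ordinary differential equations

    dx/dt = S · v(x, k),

where `S` is the stoichiometric matrix and each reaction's flux follows
the common modular rate law (a generalised reversible Michaelis–Menten
form):

    v = u · f_reg · [kcat⁺ Π_i (a_i/kM_i)^α_i − kcat⁻ Π_j (b_j/kM_j)^β_j]
        / [Π_i (1 + a_i/kM_i)^α_i + Π_j (1 + b_j/kM_j)^β_j − 1 + D_reg]

with enzyme concentration `u` (mM), allosteric regulation
`f_reg = Π_act (x/kM)/(1+x/kM) · Π_inh 1/(1+x/kM)` and specific regulation
`D_reg = Σ_act kM/x + Σ_inh x/kM`. Irreversible reactions fix kcat⁻ = 0.
One-sided exchange reactions use the same law with the absent side
contributing 1 to the denominator and 0 to the numerator; written `A → ∅`
such a reaction therefore only carries outward flux — model influx with a
reversible two-sided exchange if needed.

## Parameter balancing

All kinetic quantities are linear functions of a basic vector
`q = (μ° | ln kM | ln kV | ln u | ln c)`:

    ln keq   = −(1/RT) Σ n_ij μ°_i
    ln kcat± = ln kV ∓ (h/2) Σ n_ij (μ°_i/RT + ln kM_ij)
    ln vmax± = ln u + ln kcat±
    μ_i      = μ°_i + RT ln c_i,   Rᴬ_j = −Σ n_ij μ_i

(`R` = 8.314 J·mol⁻¹·K⁻¹, `T` default 300 K, RT expressed in kJ·mol⁻¹
where it meets μ°). The cooperativity `h` is a fixed per-reaction constant
(default 1), not an estimated quantity — estimating it would make the
system nonlinear. Because the Haldane relationship
`h·ln keq = ln kcat⁺ − ln kcat⁻ + h Σ n ln kM` and the Wegscheider cycle
conditions (`Σ_j γ_j ln keq_j = 0` for null-space vectors γ of S) are
algebraic identities of these rows, every posterior mean and every sampled
draw satisfies them exactly; the test suite asserts residuals below 1e-9.

Measurements enter as Gaussian likelihood rows on the log scale (identity
rows for basic quantities, dependency rows for keq, kcat±, vmax±), and the
posterior is the linear-Gaussian precision-form update, solved by Cholesky
factorisation with a 1e-10 jitter retry; with no measurements the prior is
returned unchanged. Records that carry no uncertainty get a default
log-std of ln 2; records carrying their own temperature are not corrected
to the system temperature (no correction model is implemented; a warning
is the caller's job if conditions are mixed).

### Pseudo-priors

Unmeasured quantities fall back to broad pseudo-priors meant to
approximate experimentally plausible ranges (all configurable):

| quantity | median | spread (log-std) | unit |
|---|---|---|---|
| kM | 0.1 | ln 10 | mM |
| kV | 10 | ln 10 | s⁻¹ |
| u | 0.01 | ln 10 | mM |
| c | 0.1 | ln 10 | mM |
| μ° | 0 | 20 (linear std) | kJ·mol⁻¹ |

The μ° spread of 20 kJ·mol⁻¹ keeps pseudo-prior equilibrium constants
within exp(±~11), matching the spirit of a prior that describes values one
could actually observe; a much wider μ° prior would put nearly all prior
mass on models whose rate constants overflow double precision when
sampled.

## Parameter search

Adapters declare identifier-translation capabilities (edges of a
namespace multigraph) and quantity lookups. For each task the search
enumerates *all* simple translation paths (no namespace revisited, length
≤ 6 by default, shortest first with lexicographic adapter-name
tie-breaks) from the subject's annotated namespaces to any adapter
offering the wanted quantity, then executes every path, following every
translation branch. Identical values for the same rate from the same
source collapse to one record; genuinely distinct values all survive, and
the balancer weighs each of them. Full provenance (every resolved
identifier) and literature references travel with each record.

kM is keyed by (reaction, compound); the fixture table layout therefore
carries a `compound_id` column on quantity rows so a reaction-level lookup
can be matched back to the participant it describes.

## Synthetic study system

The generator builds random mass-balanced networks: a spanning pass
guarantees every metabolite participates in some reaction, random
reactions consume the remaining budget, one-sided exchange reactions open
the boundary (at least 2; the last one doubles as FBA objective), and a
repair pass adds reactions until every metabolite has a producer and a
consumer — by design this may exceed the requested reaction count, since
a simulable network matters more than an exact count. Defaults: ≤2
substrates and ≤2 products per reaction, unit stoichiometric coefficients
(configurable to 2), 80% reversible reactions, regulation-edge probability
0.05, one compartment.

Ground-truth parameters are one draw per basic quantity: multiplicative
quantities from the pseudo-prior spreads above, μ° from N(0, 10 kJ·mol⁻¹)
— the scale of typical reaction standard free energies. Emitting μ°, kM,
u, c and the *derived* kcat⁺ (instead of the unobservable kV) gives a
record pool that is exactly as large as the basic dimension and
thermodynamically consistent by construction. Fixture databases chain
model identifiers through two synthetic namespaces before the
quantity-bearing tables, so the path search is genuinely exercised
offline; a bookkeeping table records what was planted.

What the generator does **not** emulate: scale-free genome-scale topology,
curated thermodynamic data, condition (pH/temperature) structure, or
correlated measurement errors. Tests passing on these networks show the
machinery is correct, not that any particular organism's model is
accurate.

## Simulation

Stiff-capable integration uses LSODA (via `scipy.integrate.odeint`) with
a numba-compiled right-hand side; pulses are discontinuities at which the
integration restarts, the grid point at a pulse time carrying the
post-pulse value (the pre/post pair is logged). Defaults: 400 s window,
401-point output grid, ×10 multiplicative pulse, rtol 1e-6, atol 1e-9 mM,
10000-step budget. Concentrations are floored at zero inside the rate law;
boundary species hold their concentration fixed. Compartment volumes
divide each species' net rate so cross-compartment reactions conserve
amounts.

## Robustness protocol

A gold-standard model is balanced from the complete truth pool ("known"
records enter with log-std ln 1.1 — narrow enough to pin the posterior
while keeping the update linear-Gaussian), its median-parameter trajectory
is the reference, and each repetition (a) keeps a random fraction of the
pool, (b) re-balances, (c) repeatedly draws full parameter sets from the
new posterior (scaled by the sampling width; every draw thermodynamically
consistent), simulates, and scores the mean square error over species and
time points against the reference, until after 25 samples
(σ_s/√n)/μ_s < 0.05, capping at 10000 samples (capped runs are flagged
unconverged and excluded from medians). Width 0 is deterministic, so a
single sample suffices. The subset is drawn once per repetition, not per
inner sample; subsetting is per record.

Numerical choices specific to this harness: sampled and reference
trajectories always share their solver tolerances, so the comparison is
unbiased (the sweep defaults are looser than the simulation module's —
trajectories of 0.01–100 mM are compared against score differences of
orders of magnitude); the sampler's integrations get a 500-step budget
per output interval; and a draw whose parameters leave the physically
plausible range (kcat ≤ 1e7 s⁻¹, u ≤ 1e3 mM, kM ≤ 1e5 mM, c ≤ 1e4 mM,
everything ≥ 1e-12) is rejected without integration — such a draw is not
biochemistry. Failed or rejected samples are not dropped (that would bias
low-information cells optimistic); each scores a sentinel equal to the
worst successful score observed so far (1e6 before any success). The
sentinel is deliberately on the scale of the real scores: a sentinel
orders of magnitude above them makes the relative-SEM convergence rule
unattainable whenever failures are rare but nonzero — a single such
outlier pins (σ_s/√n)/μ_s near 1/√f until hundreds of failures have
accumulated, sending every mildly-failing cell to the sample cap.
Problem sizes used by the shipped analysis: 20 metabolites / 20
reactions, 51-point scoring grid, rtol 1e-3 / atol 1e-5 mM, fractions
0–100% in 10% steps, width 1, 20 repetitions per fraction.

## Flux-based reduction

Operating purely on the constraint-based view (bounds default ±1000
mmol·s⁻¹; boundary species excluded from mass balance): pruning removes,
one at a time, the unprotected reaction with the smallest FVA range
(computed at ≥99% of the FBA optimum, mirroring the 1% growth tolerance;
ties break lexicographically), committing only when the reduced optimum
stays within tolerance and previously active protected reactions remain
unblocked. Compression eliminates every internal unprotected metabolite
that occurs in exactly two reactions (one producing +p, one consuming −q)
by the flux-coupled combination q·R₁ + p·R₂, iterating until maximal
chains are lumped; lumped reactions get conservative bounds
(w ∈ [max(l₁/q, l₂/p), min(u₁/q, u₂/p)]), which preserves the optimum
exactly, and are flagged synthetic so the parameter search skips them.
Protection sets are model knowledge the user must supply.

## Design choices made where the design was open

- SBML modifiers without an SBO term default to activators (with a
  warning); SBO 20/206/207/536/537 map to inhibitor, 21/459/461/462 to
  activator.
- The pulse shape (multiplicative, ×10) is a configuration default; the
  magnitude and additivity of the perturbation are not canonical.
- Non-integer stoichiometries are accepted as real exponents in the rate
  law (genome-scale biomass reactions need this).
- Reduction runs before the parameter search, on the unparameterised
  network.
- vmax measurements map through the ln vmax± dependency rows; enzyme
  concentrations default to their pseudo-prior when unmeasured.

## Known limitations

- No pH/ionic-strength adjustment of equilibrium constants; no
  condition-correction of measurements.
- Only the common modular rate law is generated; transport and signalling
  reactions get the same form.
- The balancing posterior is a full dense covariance: memory grows
  quadratically in the basic dimension, which is fine for networks of
  hundreds of reactions but would need sparse/low-rank treatment at true
  genome scale.
- Influx through one-sided exchange reactions is zero under the rate-law
  convention above.
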