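# Methods

## Model family

Four deterministic ODE systems over the state `(B, B*, A, A*)` — factory,
mutant-factory, stem and mutant-stem cells — share a common structure:
every growth term is throttled by the logistic crowding factor
`C(t) = 1 − N(t)/K` with `N = B + B* + A + A*` (the sum always runs over
all four populations, so one state shape serves every scenario), and
every population is diluted at the continuous harvest rate `m`.

**Base (conventional culture).** Factory cells grow at `r_b`, mutants at
`r_b* > r_b`, and mutation feeds the mutant pool at `c_b B C`:

    dB/dt  = r_b B C − m B
    dB*/dt = (r_b* B* + c_b B) C − m B*

**Red light (production).** Stem cells divide asymmetrically: one stem +
one factory daughter. The stem pool is therefore conserved up to
mutation losses (`r_a = ln(1−p)/τ_b* ≤ 0`), the factory pool gains
`c_ab A C`, and a mutant stem cell replaces itself while minting one
mutant factory cell per division — so the mutant-stem line is driven by
`A`, not by `A*` (mutant stems are *not* self-amplifying under red
light; this is why red is the terminal phase):

    dB/dt  = (r_b B + c_ab A) C − m B
    dB*/dt = (r_b* B* + c_b B + c_ab* A + c_ab** A*) C − m B*
    dA/dt  = r_a A C − m A
    dA*/dt = r_a* A C − m A*

**Green light (regeneration).** Stem cells double (`r_ag ≈ ln2/τ_b*`);
factory cells keep their own slow division clock, each division handing
one stem daughter to the A pool (`c_bag`, matched over τ_b), so the
factory count is conserved up to mutation (`r_bg = ln(1−p)/τ_b ≤ 0`).
Mutant factory cells do not self-amplify under green light either — they
mint mutant stem cells instead (`c_bag** B*`).

**Green star.** As green light for the stem side, but factory and
mutant-factory cells stay committed and follow the base-model lines
verbatim; stems double with mutation on the fast clock (`r_ags`,
`r_ags*`, `c_ags` — the base-model triple with τ_b → τ_b*).

### Rate derivations

Every rate constant is fixed by an endpoint condition on the linear
(dilute, closed-vessel) system: integrating one doubling time from a
unit seed must reproduce the division-diagram daughter counts. E.g.
`B(τ_b) = 2(1−p)` gives `r_b = ln(2(1−p))/τ_b`, and requiring
`B*(τ_b) = 2p` in the two-exponential solution gives
`c_b = 2p(r_b*−r_b)/(e^{r_b* τ_b} − e^{r_b τ_b})`. The same template
yields all conversion rates; the identities `r_a* = −r_a`,
`c_ab* = −r_a` and `c_ab** = r_b*` hold exactly and are asserted to
machine precision in the tests. Degenerate 0/0 forms (coincident
exponents, e.g. `p = 0` with τ_b = τ_b*) return the analytic limit, so
`p = 0` remains usable as a mutation-free control.

The `oracle` module carries the closed-form linear solutions (the
defining relations above) as independent test oracles; components fed by
three exponential sources are evaluated by high-accuracy quadrature of
the exact integrand rather than a four-term symbolic expansion, and the
whole set is cross-checked against `expm` of the system matrix.

## Units

Internally time is measured in mutant doubling times (`τ_b* = 1`), so
the division ratio `τ_b/τ_b*` is the only shape parameter; K only
rescales outputs (the model is scale-free in K and populations are kept
as fractions of K by default).

The user-facing dilution rate `m` is in **vessel volumes per factory
doubling time** (per generation — the unit every time course is reported
in), i.e. the internal rate is `m/ratio`. This convention is what makes
the standing assumption `r_b > m` ("factory cells can build up in the
vessel") hold across the standard conditions and the sensitivity grid:
per generation, `r_b = ln(2(1−p)) ≈ 0.693` exceeds every
`m ∈ [0.1, 0.9]` except the extreme corner. Under the alternative
reading (m per mutant doubling time) the factory population simply
washes out at the standard point and the stem-cell scenarios lose to the
base model over most of the grid, which contradicts the behavior this
model family is built to exhibit. The cumulative yield `B_Har` is
invariant under the time relabeling, so the choice affects regime, not
bookkeeping.

## Light-cycling controller

The switched scenarios regulate the *productive* factory fraction `B/N`
(mutant factory cells make no product) about the threshold `q` with a
bang-bang rule:

* `B/N < q` → **red** (asymmetric stem division rebuilds the factory
  fraction toward q);
* `B/N ≥ q` → **green** (the fraction is at target, so the vessel can
  afford symmetric stem division, which replenishes the stem pool at the
  cost of a transient dip in `B/N`).

This orientation is forced by the dynamics: whenever crowding is
positive, `B/N` is non-decreasing under red light and non-increasing
under green light, so the opposite assignment ("red while above q")
admits no oscillation at all — the vessel locks into a single red phase,
the stem pool washes out unused, and the scenario degenerates to the
base model plus a dead 10% stem inoculum. With the orientation above the
fraction oscillates about q exactly as intended, dipping during each
green pulse and recovering during red.

Operational details:

* each phase is held for at least one factory doubling time (cells need
  time to adapt to a light change); during the dwell only
  takeover/washout can end the phase, and at the dwell boundary the
  threshold condition is re-evaluated on the instantaneous state;
* after the dwell, switching uses integrator event location on the
  crossing `B − qN = 0` (upward in red, downward in green);
* the run starts in red;
* **terminal red** needs no separate rule: as mutants accumulate, some
  red phase never re-attains `q`; the event never fires and the vessel
  stays red until takeover — exactly the intended "finish producing"
  phase. One consequence: a mutation-free control (`p = 0`) cycles
  red/green indefinitely (the controller regulates the stem/factory
  balance whether or not mutants exist) rather than sitting in a single
  red phase.
* a run ends at mutant **takeover** (productive fraction
  `(B+A)/N < ε = 10⁻³`; results are insensitive to ε because the
  post-takeover harvest contribution is negligible), at complete washout
  (`N` below the extinction floor), or at the horizon cap.

A stem-sensing variant (switch on `(A+A*)/N` against `1−q`, which is
what a fluorescence-based sensor would actually measure) was evaluated
and behaves nearly identically while mutants are scarce; it is not the
implemented rule because the factory-fraction threshold is the stated
contract.

## Yield metric and comparisons

`B_Har = ∫ m B/N dt` — the harvested outflow volume weighted by its
productive fraction, invariant under time rescaling. It is computed two
ways: an extra ODE quadrature state integrated alongside the populations
(authoritative), and trapezoidal integration of the sampled fractions
(cross-check; the two agree to ~1e−8 relative on standard runs).
`harvest_index` also exposes a `capacity` normalization (`∫ m B/K dt`,
absolute harvested cells per vessel volume); the two coincide when the
vessel runs near capacity and diverge in washout regimes. The standard
index is the default and is what all comparisons and sweeps report.

Comparisons run the base model from an all-factory vessel (`B₀ = K`) and
the MiST scenarios from the target composition (`B₀ = 0.9K`,
`A₀ = 0.1K`); yields are insensitive to this choice at the few-percent
level (verified over initial stem fractions 5–50%). The sensitivity
sweep varies the division ratio over 1..10 (by setting `τ_b = ratio`
with `τ_b* = 1`) and `m` over 0.1..0.9, holding `p = 10⁻⁶`, `q = 0.9`;
each grid point runs base + both MiST variants to takeover with a hard
cap of 200 generations (every observed takeover on the grid occurs well
before the cap; only no-takeover regimes such as ratio ≈ 1 are capped,
identically for all scenarios).

## Numerical choices

* **Integrator**: LSODA with `rtol = 10⁻⁸`, `atol = 10⁻¹² K` (the
  mutation channels are ~6 orders of magnitude smaller than the growth
  terms), dense output sampled at Δt = 0.02 mutant doublings (0.05 in
  sweeps, where yields come from the quadrature state and the samples
  are only diagnostics).
* **Extinction floor**: populations and fractions treat `N < 10⁻¹² K`
  as empty (avoids 0/0 in `B/N`); the same floor terminates fully
  washed-out runs.
* **Negative undershoots**: values within the solver tolerance band
  below zero are clamped to 0; larger negatives raise an error carrying
  the last valid state.
* **Determinism**: no randomness anywhere; trajectories and summaries
  serialize at full float precision (`%.17g`, round-trip-exact parsing),
  so identical configurations give byte-identical files.

## What a green test establishes — and limits

The test suite verifies the closed-form rates against independent
numerical integration of their defining endpoint conditions, the
nonlinear integrator against the linear closed forms in the dilute
limit, fixed points against their algebraic values, and the headline
comparative statements (standard-condition improvement ≥ 29.7%, sign
structure of the sweep, takeover delay and inevitability) on the model's
own terms. It does **not** establish anything about real bioreactors:
the model assumes a perfectly mixed vessel, instantaneous and exact
fraction sensing, deterministic continuum populations (no demographic
noise in the earliest mutant copies, where stochasticity is strongest),
burden-free stem cells, and mutation rates independent of product
chemistry.

Known limitations: the reported sweep maximum of the yield improvement
(~69% at ratio 10 under the standard index; ~168% under the capacity
normalization) brackets, but does not reproduce, the ~127% figure
sometimes quoted for this configuration — the discrepancy traces to
exactly which normalization of the harvested yield is compared, and both
are exposed. Fed-batch operation, light-intensity dynamics, sensor
noise, and optimal (rather than threshold) switching policies are out of
scope.
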