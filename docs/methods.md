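# Methods

## The model

`hfqnet` solves the deterministic mass-action kinetics of duplex formation
between `n` sRNA species and `m` target-mRNA species competing for the Hfq
hexamer. The state holds free Hfq `H`, free RNAs `S_i` and `T_j`,
singly-bound complexes `HS_i` and `HT_j`, ternary complexes `HS_iT_j` and
released duplexes `D_ij` — `1 + 2n + 2m + 2nm` concentrations, flattened
in exactly that order (matrices row-major) for serialization and for the
solver.

Assumptions baked into the rate equations:

* One Hfq hexamer binds at most one sRNA and one mRNA (separate binding
  sites; the shared-site case is covered only by the complex-type
  combinatorics, `count_complex_types(..., shared_sites=True)`).
* Annealing and duplex release are one lumped first-order step `k5`
  acting on the ternary complex; the step regenerates free Hfq, which is
  how Hfq recycling enters the model. Duplexes never rebind Hfq.
* All species share a single degradation/dilution rate constant β
  (default 1 time⁻¹, i.e. time is measured in RNA lifetimes).
  `beta_overrides` maps a species role (`"S"`, `"HS"`, ...) to a
  different rate; its only preset use is the sensitivity check with
  10-fold faster free-sRNA turnover.
* Concentrations and time are unitless model units; the explored rate
  constants span roughly 10⁻⁵–10⁸, which is why a stiff integrator is a
  hard requirement.
* Hfq multimers beyond the hexamer, RNA exchange between hexamers,
  Hfq–DNA/protein binding and explicit RNase/ribosome species are out of
  scope, as is any fitting to experimental data.

The derivative function is exact mass action. Three structural
invariants are tested rather than assumed: summing the derivative over
all Hfq-containing species leaves only `α_H − β·(those species)` (all
binding/annealing terms cancel); the analogous identity holds per sRNA
and per mRNA lineage; and transposing the sRNA/mRNA roles (with
transposed rate tensors) transposes the derivative.

## Steady states

The reported quantities are steady-state values. The primary route
integrates from the all-zero state — a cell before induction; no
multistability has been observed in this reaction class, and the
root-finder cross-check starts from independent cold starts precisely to
catch any — using `scipy.integrate.solve_ivp(method="LSODA")` with an
analytic dense Jacobian (assembled in `jacobian_flat`; for an 881-state
n = 20 network the analytic Jacobian is the difference between seconds
and minutes per solve).

Convergence follows a two-checkpoint rule: the solution at 90% and 100%
of the horizon (default 100 RNA lifetimes) must agree per species to an
absolute 1×10⁻¹⁰, with a relative guard (default 10⁻⁹) for species whose
concentrations are large enough that the absolute criterion sits below
double precision. On failure the horizon doubles, up to 6 times, after
which an explicit failure object is returned — never an exception and
never a silently unconverged state. Solver tolerances default to
rtol 10⁻¹⁰ / atol 10⁻¹²; sweep-heavy tests and scripts relax to
10⁻⁸/10⁻¹⁰ (conservation identities still hold to ~10⁻¹² there). Tiny
negative concentrations from solver round-off are clipped to zero.

`algebraic_oracle` re-derives the steady state as a root of the
derivative function (scipy `hybr`, damped Newton) started from the
integrator's answer and from cold starts, accepting only non-negative
roots with residual below 10⁻⁹ times the concentration scale. It is a
test oracle for small systems, not a replacement for integration.

## Composite parameters

The y-parameters condense the eight per-pair rate constants:

| name | definition | meaning |
|------|------------|---------|
| y1 | ((k₂k₃)/(k₁k₄))^½ | mRNA-vs-sRNA affinity for Hfq |
| y2 | (k₁k₂k₃k₄)^¼ | association magnitude (conc⁻¹ time⁻¹) |
| y3 | ((k₂k₄)/(k₁k₃))^½ | branch bias (sRNA-first vs mRNA-first) |
| y4 | ((k₃k₄)/(k₁k₂))^½ | cooperative association (>1 positive) |
| y5 | (k₋₁k₋₂k₋₃k₋₄)^¼ | dissociation magnitude (time⁻¹) |
| y6 | ((k₋₁k₋₂)/(k₋₃k₋₄))^½ | cooperative dissociation (>1 positive) |
| y7 | ((k₁k₂k₋₃k₋₄)/(k₋₁k₋₂k₃k₄))^¼ | cognate selection (<1 selects) |
| y8 | same form over starred constants | non-cognate exclusion (>1 excludes) |
| y9 | (k₋₁k₋₂k₋₃k*₋₃k₋₄k*₋₄)^⅙ | total dissociation incl. non-cognate |

Starred constants are read off the designated non-cognate ternary complex
`HS_iT_jnc` (identical to the `HS_incT_j` constants in uniform square
networks, and the only well-defined choice for the 1-sRNA/2-mRNA pool
topology). Ratios with a vanishing denominator are reported as NaN, not
raised.

Inverting the first four definitions is a log-linear 4×4 solve with the
closed form `k1 = y2/√(y1y3y4)`, `k2 = y2√(y1y3/y4)`, `k3 = y2√(y1y4/y3)`,
`k4 = y2√(y3y4/y1)`; a brute-force numerical solve of the log-linear
system is kept as an independent oracle in the tests. The 2-constraint →
4-constant dissociation split is under-determined; the symmetric
convention `k₋₁ = k₋₂ = y5√y6`, `k₋₃ = k₋₄ = y5/√y6` is used, which
collapses to all-equal whenever a regime pins y6 = 1.

Two inversions deserve a note:

* **Cognate selection (y7) defaults to the association route** — scaling
  the diagonal k₃, k₄ up by y7⁻². The alternative dissociation route
  (scaling diagonal k₋₃, k₋₄ down) produces the same y7 but has no
  kinetic leverage when `k5 ≫ k₋₃`: a cognate ternary complex already
  converts to duplex with probability ≈ 1, so stabilizing it further
  changes nothing. Both routes are selectable (`y7_route`), and
  non-cognate exclusion (y8) defaults to the dissociation route (faster
  unbinding from non-cognate complexes), for which there is direct
  in-vitro support (active-cycling observations).
* **y9 is treated as the composite target.** When exclusion multiplies
  the two starred dissociation constants by y8², the uniform base is set
  to `y9·y8^(−2/3)` so the six-constant geometric mean lands exactly on
  the requested y9 (and likewise for a dissociation-route y7). This
  makes regimes quoted as, e.g., (y9 = 10¹, y8 = 10¹) internally exact.

## Output metrics and robustness

* `percent_duplex(i,j)` = 100·D_ij over the total pool of mRNA j (free +
  singly bound + all ternary + all duplexes). At steady state with
  uniform β the denominator equals `α_Tj/β`, which is used as a
  cross-check, not as the implementation.
* `relative_hfq` = total Hfq in all forms over the focal pair's total
  mRNA; with uniform β it equals `α_H/α_T(focal)`.
* `hfq_allocation` splits total Hfq into free / sRNA-bound / mRNA-bound /
  cognate-ternary / non-cognate-ternary fractions (cognate ⇔ `k5 > 0`).
* `percent_hfq_sequestered` is defined here as bound Hfq **not** in a
  productive complex: singly-bound plus non-cognate ternary. This axis
  has no published formula; the chosen convention is the complement of
  the free and cognate-ternary fractions and reproduces the described
  qualitative behavior.

`hfq_sweep` titrates α_H over a log grid (default 10 points/decade over
10⁻⁵–10⁷, resolving bounds to <0.1 decade) with one independent solve per
point; per-point failures are recorded, never fatal.
`bounds_and_robustness` finds the first upward and last downward crossing
of the threshold (default 10% duplex) by interpolation that is linear in
(log₁₀ relative Hfq, percent) — the read-off rule is a package
convention. Curves that never reach threshold yield NaN bounds with
`robustness = 0` and an explicit `defined = False`; threshold crossings
at a grid edge set `edge_warning`.

## Scenario presets and chosen constants

The scenario library (`fig2`…`fig13`, `s1`) encodes the published
simulation designs; the printed parameter values (the y-grids, k5 levels,
y7 = 10⁻¹, y8 = 10¹, y9 ∈ {10⁰, 10⁴}, the 5:1–1:5 production ratios, the
100× pool, the 10× degradation factor) are used verbatim. A few
constants are not printed anywhere and are design choices of this
package, exposed as overridable scenario parameters:

* **Single-pair production scale** (`PART1_ALPHA_RNA = 100`
  concentration units per RNA, fig2–fig4, fig11, s1). The published
  behavior of the isolated-pair schemes — duplex formation in *every*
  panel of the affinity/magnitude grid — requires even the slowest
  association step (y2 = 10^0.5 under a 10⁴-fold affinity bias, i.e. a
  rate constant of 10⁻¹·⁵) to outpace RNA turnover; that pins the RNA
  concentration scale well above one unit. 100 units satisfies this
  across the whole explored range. Bounds are unaffected as they are
  measured in relative-Hfq units.
* **Network baseline** (fig7/8/10/12: y2 = 10^2.5, y9 = 10⁰, k5 = 10³):
  k5 and y9 are pinned by the published comparison baseline; y2 is the
  center of the explored association range. Networks use 1 production
  unit per RNA so relative Hfq equals α_H directly.
* **Isolation-vs-network contrast** (fig6: y2 = 10^0.5, y9 = 10⁰,
  k5 = 10⁰): the low ends of the explored ranges. This is the regime in
  which a single pair clears the 10% threshold while the same kinetics
  in a five-pair network never do, as the published contrast requires;
  at faster association or annealing the five-pair network still forms
  duplexes and the contrast disappears.
* **Rapid-dissociation base for the degradation check** (s1: y5 = 10⁴
  paired with y2 = 10^4.5): cycling among Hfq complexes only outpaces
  degradation if rebinding is fast; with slow association the free-sRNA
  pool is large and 10× faster free-sRNA turnover would trivially
  dominate, contradicting the published claim of a minimal effect.
* **Stability mixes** (fig9): stable pairs y9 = 10⁰, unstable y9 = 10⁴;
  dissociation of a ternary complex follows the species that leaves
  (k₋₁/k₋₄ from the sRNA's class, k₋₂/k₋₃ from the mRNA's).
* **Pool representation** (fig13): the 100 unpartnered mRNAs are one
  aggregate species with 100× production — identical mass-action
  dynamics at identical constants, at a fraction of the cost. The
  affinity tilt ((k₂k₃k*₃)/(k₁k₄k*₄))^⅓ is applied symmetrically so the
  association magnitude is unchanged.

## What the presets emulate — and what they do not

The preset networks are idealized study conditions: pairs within a
regime are kinetically identical, pairing is strictly single-partner (or
strictly indiscriminate), and production is constant in time. Real sRNA
networks have heterogeneous rate constants, overlapping target sets,
regulated production and degradation machinery (RNase E recruitment,
ribosome protection) that this model lumps into β and k5. Passing the
suite therefore demonstrates the kinetic mechanisms — sequestration,
recycling, cooperativity, cycling — under controlled conditions, not a
quantitative prediction for any particular organism's network.

## Problem sizes and tolerances in the tests

The test suite and `scripts/acceptance.py` use coarser titration grids
than the library default (2–4 points per decade instead of 10) and relax
the integrator to rtol 10⁻⁸–10⁻⁷ for the largest networks; the asserted
orderings are separated by one or more decades, far above grid
resolution. Network-scaling checks run n ∈ {5, 10, 20} (up to 881 ODEs);
conservation and solver cross-checks use seeded random networks with
n, m ≤ 3 at 10⁻⁶ relative tolerance; y-parameter round trips are checked
to 10⁻¹² relative.

## Known limitations

* Shared-site binding enters only through the complex-type counting; the
  dynamical model always assumes separate sites.
* The algebraic root-finder is practical for small systems only
  (roughly n·m ≤ 9); larger networks rely on integration alone.
* Robustness is tied to the 10% threshold convention; curves peaking
  near the threshold make it a noisy summary (the bounds carry
  `edge_warning`/`defined` flags for exactly this reason).
* A unique steady state is assumed (and cross-checked), not proven.
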