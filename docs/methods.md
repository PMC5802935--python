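# Methods

## The model

A landscape's element budget is represented as a weighted directed
multigraph.  Compartments are aspatial nodes with a role — *internal
ecosystem*, *exterior* (inexhaustible pool: no stock tracked, no balance
required), or *storage* — and optional scalar area (m²) and stock (Gg C).
Flows are directed records `(source, target, process, orientation, best,
low, high)` in Gg C yr⁻¹; multiple processes may connect the same ordered
pair and are aggregated only when the flow matrix is built.  Orientation
(vertical / lateral / internal) is an input attribute, not inferred from
geometry.  Self-flows are restricted to the storage processes
(accumulation, sedimentation); a negative magnitude is allowed only for
accumulation, meaning the pool is drawing down its store.

Two per-compartment primitives drive everything else: **throughput** (sum
of |flow| over incident non-self flows — the compartment's activity) and
**net balance** (inflow − outflow, the empirical analogue of a local growth
rate).  Self-flows are excluded from throughput because they describe what
a compartment retains rather than what crosses its boundary; this
convention exactly reproduces the case study's per-ecosystem throughputs
(5503.5 / 1669.9 / 113.7 Gg C yr⁻¹), which is why it is the default.

## Significance rule

A non-self flow is significant iff `|best| ≥ ratio × throughput(e)` for at
least one internal-ecosystem endpoint `e`, with `ratio = 0.01` (the
two-orders-of-magnitude rule).  The at-least-one-endpoint form is used
because a flux negligible to a large donor can still dominate a small
recipient (forest DIC runoff, 10 Gg C yr⁻¹, is <1% of the forest's
5503.5 but ~9% of the surface waters' 113.7); it is the unique simple rule
consistent with all nine published significance verdicts in the case
study.  Ties count as significant (conservative retention).  Thresholds
are computed once, on the unfiltered network, making flagging idempotent
and order-independent.  Self-flows are always significant.

Classification then follows from the flags: internal ecosystems
significantly interconnected + significant boundary-crossing flows →
**fragmental**; interconnected with no boundary leakage → **systemic**; no
significant inter-ecosystem flows → **discrete**, split into *laterally
discrete* when significant vertical connections exist (e.g. through the
shared atmosphere) and *omnidirectionally discrete* otherwise.

A consequence of excluding self-flows from throughput: an ecosystem whose
only non-self flux is a single tiny leak still finds that leak
"significant" (it is 100% of its own throughput).  Omnidirectional
discreteness therefore describes ecosystems that only cycle internally —
which is what the concept means.

## Adjustment to a meta-ecosystem

Closure re-points each flow with an exterior-role endpoint at the exterior
compartment mapped from its orientation (process-level overrides take
precedence), drops insignificant flows (configurable), and normalises
storage terms.  Positive accumulation and sedimentation stay as self-loops.
Three policies for a negative accumulation −m are provided because the
bookkeeping is genuinely underdetermined:

- `release_inflow` (API default): a flow of +m into the compartment from a
  dedicated storage node — physically, the store subsidises the network;
- `signed_self_loop`: kept as signed; index computations take magnitudes;
- `exclude`: the term is omitted from the flow network.

Re-adjusting an adjusted network is a no-op; storage nodes are members of
the closed system, not boundary.

## ENA indices and the capacity question

Indices are computed on the pair-aggregated matrix with base-2 logarithms
and k = 1 (AMI in bits; the published values satisfy A = TST × AMI exactly
in base 2), with 0·log 0 := 0 and zero cells skipped.  `T_i` is the
out-throughflow (row sum) and `T_j` the in-throughflow (column sum).
Self-loops are included in TST and in the marginals by default
(configurable), which the case-study reproduction supports.

Development capacity is provided in two forms.  The **flow-diversity**
form, `C = −Σ T_ij log2(T_ij/T)`, is the standard in the ENA literature
and is the library default.  The **throughflow-diversity** form,
`C = −Σ_i T_i log2(T_i/T)`, is the Shannon diversity of compartment
out-throughflows scaled by TST; it is also a genuine upper bound on
ascendency (mutual information never exceeds a marginal entropy, so
A = T·I ≤ T·H(row marginal)), and it is the *tighter* of the two bounds.

The two forms disagree materially on the case study, and the disagreement
is diagnostic.  On every defensible composition of the adjusted NHLD
network the flow-diversity capacity is ≥ ~17 800 Gg C bits yr⁻¹ — the five
dominant fluxes alone force a flow entropy above 2 bits — whereas the
published capacity is 11 767.45, i.e. C/TST ≈ 1.42 bits.  No arrangement
of the printed fluxes (accumulation placement, insignificant-flow
inclusion, node merging, log base) brings the flow-diversity form anywhere
near that value, while the throughflow-diversity form lands within ~1.2%
of it.  The case-study pipeline therefore reports capacity in the
throughflow form; the flow form remains available everywhere via
`capacity_form="flow"`.

## Case-study composition

The published closed-network flow matrix exists only as a diagram, so its
exact composition is ambiguous.  Summing the significant fluxes plus the
positive storage self-loops (forest accumulation 968, wetland accumulation
89, sediment 17) while omitting the negative surface-water accumulation
gives TST = 8289.0 Gg C yr⁻¹, within 0.04% of the published 8292.00 — the
closest of the candidate compositions (retaining the −15 as a release
inflow gives 8304.0, 0.14%).  The case-study configuration
(`metaecoflux.nhld`) adopts that composition: `exclude` for the negative
accumulation, self-loops included, throughflow capacity.  Residual
differences against the published indices (AMI 0.6537 vs 0.668294 bits;
capacity 11 908 vs 11 767) are at the level this composition ambiguity
explains, and the reproduction tests assert the published values at
exactly that documented level — TST to 0.1%, AMI to 0.02 bits, capacity to
2%, the resilience ratio to 2 percentage points — alongside the internal
identities A = TST·AMI and A + R = C, which hold to machine precision by
construction.

## Spatial budgets

Compartment areas are not part of the published budget; they are
back-derived from (total flux)/(local intensity) pairs — forest from GPP
(3233×10⁹ g / 936 g m⁻² = 3.454×10⁹ m²), wetland from GPP, surface waters
from CO₂ evasion — and shipped in the intensity table with the derivation
noted.  Vertical budgets are net fluxes into each compartment
(precipitation + production − respiration/emission terms; the wetland has
a CH₄ term, the surface waters only evasion terms — the budget's asymmetry
is the data's, not smoothed over), and the atmosphere closes the vertical
system exactly by construction.  Lateral budgets are negative for donors
(areal runoff terms plus lineal litter × shoreline length) and positive
for the receiving waters minus the downstream export, so donors +
recipient + export ≡ 0.  All conversions use 1 Gg = 10⁹ g.

## Synthetic generator

`generate_network` draws an Erdős–Rényi-style directed support (each
ordered pair with probability `connectance`, no self-loops) with
log-normal magnitudes, seeded through `numpy.random.default_rng` for exact
reproducibility.  With `balanced=True` a ring is superimposed to guarantee
an irreducible support and the matrix is diagonally balanced
(`mat ← D⁻¹ mat D`, `D = diag(√(out/in))`, ≤200 sweeps to 1e-12) so every
compartment's inflow equals its outflow — a mass-conserving network whose
source–sink residual vanishes.  The generator emulates the *structure* of
flux networks (sparse, heavy-tailed magnitudes), not their ecology: no
orientation semantics, no storage terms, no exterior pools.  Passing
property tests on generator output therefore validates the index algebra
and the I/O round-trip, not the ecological conventions, which are
exercised by the case-study tests instead.

## Scenarios

Scenario inputs are explicit substitution maps keyed by
`(source, target, process)`, not automatic range sampling: summing the
budget's upper-bound column does not reproduce the published
"relatively active" totals, so range endpoints are demonstrably not how
those alternative flux sets were constructed, and guessing a rule would
fabricate data.  The comparison table reports each scenario's indices and
deltas against the base network; extensive indices (TST, A, C, R) scale
linearly under uniform scaling while AMI is scale-free, which the tests
assert.

## Known limitations

- Compartments are aspatial; there is no geometry, routing or gridded
  modelling — "interactive" means compartment-level budgets with interface
  terms.
- Only the exterior-compartment closure is implemented, not boundary
  re-delineation that absorbs neighbouring ecosystems.
- The instantaneous balance is computed; stocks are not integrated through
  time.
- Only the five holistic indices are computed — no cycling analysis,
  input/output environs or trophic aggregation.
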