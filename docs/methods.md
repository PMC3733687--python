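# Methods

## Model

`cfpath` treats a metabolic network in two coupled views.

The *stoichiometric* view is the matrix S (metabolites × reactions) with
signed rational coefficients, exchange fluxes included as single-signed
columns. Every reversible reaction is split into irreversible forward and
backward halves (`id_f`/`id_b`), so all fluxes are nonnegative; the split
pairs are recorded and at most one half of a pair may be active in any
solution. Splitting preserves the steady-state cone: a signed flux of the
original network maps to `(v⁺, v⁻)` on the split network and back (this is
property-tested on the toy fixture).

The *carbon-exchange* view is a directed graph whose arcs are the
(substrate, product) pairs of each reaction that exchange carbon atoms,
taken from a curated arc table rather than inferred — automatic atom mapping
is out of scope. Arcs on reversible reactions appear in both orientations,
one per split half. Hub metabolites (defaults for genome-scale work: CoA,
CO2, AMP, ATP, ADP) are removed from the graph but **not** from S: they
carry no path arcs yet must still be mass balanced. The built-in
glycolysis/pentose-phosphate fixture uses an empty hub list, since CO2 is a
legitimate, countable product there.

A carbon flux path (CFP) from α to β is the shortest simple path of the
carbon graph embeddable in a steady-state flux distribution. The MILP uses
binary arc indicators u, binary reaction activities z, continuous fluxes v;
degree/conservation/visit constraints define the path, `S v = 0` with
`z_r ≤ v_r ≤ M z_r` defines the flux state, and
`Σ_{r supports (i,j)} z_r ≥ u_ij` couples them. The degree constraints are
implemented as "one arc leaves α, one enters β, none enters α or leaves β",
the only reading consistent with the conservation and visit-limit
constraints. Because every extra arc costs one objective unit, optimal
solutions contain no spurious cycles. The path itself is reported, but only
its *length* is used downstream; when several optima exist the solver's
certified optimum is returned and nothing may depend on its identity.

## Parameters

- `big_M` (default 1000, dimensionless flux units): upper flux bound for an
  active reaction; an active reaction must carry at least one unit. Raise it
  for networks needing a wider dynamic range.
- `time_limit` (default 60 s per solve): a solve hitting the limit raises a
  distinct *undetermined* error and is reported separately — never counted
  as a disconnection, which is a scientific claim requiring a proof of
  infeasibility from the solver.
- feasibility tolerance: mass-balance residuals of returned solutions are
  within 1e-6 (HiGHS defaults; asserted in tests).
- hub list: configuration, see above.
- `N`, `seed`: background sample size and RNG seed for p-values (below).

The MILP backend is HiGHS via `scipy.optimize.milp`, wrapped behind a small
backend contract (binary/continuous variables, two-sided linear constraints,
proven-infeasible status) so another solver can be substituted. HiGHS
single-threaded solves are deterministic, which makes every pipeline output
reproducible byte for byte.

## Connectivity curves, ΔL and the viability filter

A connectivity curve performs one CFP solve per non-hub carbon-graph
metabolite other than the source (source as path origin in accumulation
mode, as target in depletion mode; metabolites absent from the carbon graph,
e.g. exchange-only species, are not targets). Targets that are topologically
unreachable are recorded as disconnected without invoking the MILP — a sound
shortcut, since the MILP is a restriction of graph reachability.

ΔL_j = L_j^K − L_j^W compares mean CFP distances between knockout and wild
type over the metabolites still connected under the knockout; the wild-type
mean is restricted to that same set. L^K is computed from the cumulative
curve counts (newly-reached-at-i × i, normalised by the connected count) in
exact rational arithmetic, and equals per-metabolite mean differencing
(property-tested). A knockout disconnecting *everything* has no defined ΔL
and is reported as fully disconnecting instead. Knockouts block both split
halves of the original reaction. The knockout universe is every non-exchange
original reaction, transports included; exchanges are environment, not
enzymes.

The viability filter accepts a knockout only if every (medium input,
excreted output) pair that is CFP-connected in the wild type remains
connected; these are feasibility-only solves. Non-viable knockouts are still
scored but excluded from ranking positions (`rank_nonviable=True` restores
them). Positions use competition (minimum) ranking, so tied ΔL means tied
position and identical p-value; display order breaks ties lexicographically.

## Specificity p-values

For each of N background source metabolites (sampled uniformly without
replacement from the non-hub carbon-graph metabolites, excluding the study
metabolite; with-replacement available) a full knockout scan is run and each
enzyme's position recorded; an enzyme missing from a scan's ranking gets
that scan's worst position plus one — a conservative choice that can only
inflate its p-value. The empirical CDF of the positions gives
p = F*_N(k) at the observed position k. The sample cannot resolve
probabilities below 1/N, so reported p-values are clamped at that floor
(`clamp_floor=False` yields the literal empirical-CDF value, which can be 0
for a position never attained in the background). On the 19-metabolite
fixture the background is all 18 other metabolites, so the floor is 1/18 and
p-values are necessarily large; the statistic only becomes sharp at genome
scale (N of order 1000).

## What the fixtures emulate

`toy_network()` is the classical glycolysis / pentose-phosphate example: 19
internal reactions, a glucose input and CO2/R5P/pyruvate outputs, cofactors
treated as external. The reversible set — Pgi, Fba, TpiA, Rpe, Rpi, TktI,
Tal, TktII — makes the isomerase/aldolase/transferase steps bidirectional
and the kinase/dehydrogenase/lactonase steps one-way. Carbon arcs follow
standard biochemistry: the Gnd decarboxylation feeds both Ru5P and CO2;
transketolase/transaldolase donors feed both products while acceptors feed
only the elongated one; phosphate-transfer partners carry no arcs. With this
table the wild-type curve from G6P is 2, 8, 13, 14, 15, 16, 17 over steps
1–7 (only glucose itself is unreachable), the Pgi knockout gives 1, 2, 4, 6,
9, 12, 14, 15, 16, 17 over steps 1–10, and the TpiA knockout leaves 16
metabolites connected with DHAP infeasible despite surviving topological
routes. One narrative count sometimes quoted for the Pgi knockout — three
metabolites within three steps — is structurally impossible here: step 3 of
the only remaining route out of G6P is the decarboxylation, which delivers
Ru5P and CO2 together, so |C_3| = 4 whenever the full 17-metabolite reach
(CO2 included) holds; the corresponding assertion is kept at the narrative
value and fails, documenting the conflict.

`random_network()` produces small connected unit-stoichiometry networks
(chain plus random 1→1/2→1/1→2 conversions, one input, one output,
deterministic under seed) for property tests. Neither fixture emulates
compartments, non-unit stoichiometry at scale, gene–protein–reaction rules
or realistic medium composition, so passing tests demonstrate correctness of
the algorithms, not biological coverage of real genome-scale models.

Problem sizes used by the test suite and the reproduction script — all-pairs
solves on the 19-metabolite fixture, 25 random networks of 4–8 metabolites,
and an 18-scan background — keep a full run in the low minutes on one CPU
while exercising every code path at full fidelity; the same interfaces
accept genome-scale SBML plus an arc table unchanged.

## Verification strategy

The ILP is checked pair-by-pair against an independent brute-force oracle
(simple-path enumeration in increasing length, each path tested for
steady-state embeddability by a standalone activity/flux MILP without any
path variables). Further property tests: relaxing the flux constraints
reduces CFP lengths to BFS distances; blocking reactions never shortens a
distance nor repairs a disconnection (hence ΔL ≥ 0 for viable knockouts);
depletion mode equals accumulation mode on the arc-transposed network;
cumulative and per-metabolite ΔL forms agree exactly; p-values are monotone
in position with floor 1/N.

## Known limitations

- Carbon traceability is enforced per step, not end-to-end from α to β — a
  documented property of the path concept itself.
- Alternative optimal paths are solver-dependent; only lengths are stable.
- The viability filter checks input–output connectivity only; it does not
  guarantee biomass production or any richer functional criterion.
- No k-shortest paths, elementary flux modes, combined knockouts, or
  regulatory information.
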