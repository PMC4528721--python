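# Methods

## Steady-state model and conventions

All computations operate on the polytope `{v : S v = 0, lb ≤ v ≤ ub}`.
Rows of *S* are **intracellular** metabolites only; extracellular species
are unbalanced, so the exchange reaction that moves a species across the
boundary is its terminal source or sink.  Exchanges are written in the
export direction: uptake is a negative exchange flux, and a measured uptake
rate *u* enters as a lower bound of −*u*.  The substrate exchange is
**pinned** (both bounds at −*u*): minimisation objectives only produce
storage at all when the measured carbon input is imposed as an equality,
which mirrors how measured rates constrain such analyses in practice.
Ammonium and phosphate act as capacities (lower bound only); nitrogen
limitation is `nh4_uptake = 0`.  The N-limited phase also carries a
measured oxygen-uptake capacity; without it, ATP-production maximisation
degenerates to total respiration and stores nothing.  "Unbounded" enzymatic
capacities are ±10⁴ mmol/(g-DW·h) numerically.

Maintenance ATP (NGAM) is an equality bound on a dedicated hydrolysis
reaction (ATP + H2O → ADP + Pi + H⁺), the standard COBRA convention.
Growth-associated maintenance (GAM, default 30 mmol-ATP/g-DW) is embedded
in the biomass reaction.

## COD accounting

Storage fluxes, substrate and biomass are put on a common
chemical-oxygen-demand scale via the theoretical oxygen demand

    ThOD = 8 γ,   γ = 4C + H − 2O − 3N + 5P + 6S − charge   [g-O2/mol]

i.e. the degree of reduction relative to CO2/H2O/NH3/phosphate/sulfate
reference states (glucose 192, acetate 64, NH4⁺ 0 g-O2/mol).  The +5P/+6S
terms make phosphate and sulfate ThOD-neutral, so phosphorylated
intermediates score like their parents.  For reconciliation the *signed*
value is used, so O2 carries −32 g-COD/mol.  Predicted storage fluxes are
normalised by the biomass COD content, giving
mg-COD<sub>storage</sub>/(g-COD<sub>biomass</sub>·h).

## Biomass construction

A biomass composition is a set of macromolecule mass fractions (g/g-DW,
must sum to 1 ± 0.01) with precursor stoichiometries per macromolecule.
The assembled biomass reaction derives the elemental formula of its product
**exactly** from the net precursor demand (protons added to neutralise the
derived charge), then rescales the demand so that unit flux forms exactly
1 g-DW (the "biomass unit" is 1 mmol of molar mass 1000 g/mol).  Two
consequences: the biomass reaction is elementally consistent by
construction, so every steady-state solution closes the C/N/P/COD balances
over its exchange fluxes; and the biomass COD needed for yield
normalisation comes directly from the unit's formula.  Element counts of
this pseudo-species are fractional — ordinary metabolites use integer
formulas.

## Solvers and numerical choices

LPs (growth FBA, weighted flux objectives, L1 minimisation via the
`t ≥ |v|` auxiliary formulation, FVA) are solved with HiGHS through
`scipy.optimize.linprog`.  MOMA QPs are solved with OSQP
(eps 10⁻¹⁰, polish) and then **refined by a KKT solve on the detected
active set**, which brings solutions to ~10⁻⁹ accuracy on the problem sizes
handled here; a cheap LP feasibility screen runs first because
near-infeasible QPs make first-order solvers stall.  Optimal solutions are
required to satisfy ‖S v‖∞ ≤ 10⁻⁶ (asserted in tests).  Everything is
deterministic: simplex vertex solutions and strictly convex QPs, no
randomised initialisation anywhere.

Degenerate growth optima are resolved by a secondary L1 flux minimisation
at fixed optimal growth — MOMA needs a unique, reproducible reference, and
parsimonious selection is the standard tie-break.

ATP/NADH "production rate" objectives count **gross production** (the
summed positive stoichiometric coefficients of ATP resp. NADH across
reactions), not net production; NADH means NADH only, not NADPH.

## The combined objective

`max_storage_env_moma` is lexicographic: phase 1 maximises the COD-weighted
storage total; phase 2 constrains the total to at least (1 − tol) of that
optimum and minimises the MOMA distance to the growth reference.  The
default band is `tol = 0.0075`.  A genuinely infinitesimal band would be
appropriate for genome-scale networks, whose storage-maximal optimum is a
degenerate *face* (many pathway combinations tie); on a ~33-reaction lumped
network the optimum is an isolated vertex, and a small finite band plays
the role of that missing degeneracy — it is what allows the MOMA step to
select a storage *mixture* rather than echo the vertex.  The band is
configurable per run (`lexicographic_tol`), as is a PHB:PHV co-polymer
composition constraint (default 85:15 on a COD basis — a conventional
PHB-dominated split; override it with the measured proportion whenever one
is available).

## NGAM calibration

Total storage flux is monotone decreasing in NGAM for the flux-economy
objectives (every mmol of maintenance ATP costs respired substrate that
could have been stored).  `calibrate_ngam` verifies monotonicity on probe
points, locates the feasibility edge of the bracket by bisection (high NGAM
eventually exceeds the respiratory ATP supply), and then bisects to
|simulated − measured| ≤ 10⁻⁴·measured.  Objectives whose curve cannot
reach the measured total — environmental MOMA, whose maintenance demand is
absorbed by futile cycles, and ATP maximisation under an O2 cap — raise a
range error carrying the achievable interval; the pipeline then falls back
to a conventional 0.5 mmol/(g-DW·h) and logs it.

## Bayesian discrimination

Posterior shares over objectives use independent Gaussian measurement
errors per (substrate, compound) yield fraction with the measured standard
errors and a uniform prior:
`P_j ∝ Π N(y_sc ; ŷ_jsc, SE_sc²)`, computed in log space (no underflow out
to 100 SE).  Yields are compared as COD-basis *fractions* of the total
storage because calibration has already matched the totals.  This
independent-Gaussian construction is the standard one for
objective-function discrimination; it is an explicit modelling assumption,
not a derived result.

## Rate reconciliation

Classical linear data reconciliation: measured rates *r* (signed,
consumption negative) with covariance *F* are projected onto the balance
space of *E* (rows: C, N, P and signed COD by default; dependent rows are
dropped automatically):

    r̂ = r − F Eᵀ (E F Eᵀ)⁻¹ E r,
    h = (E r)ᵀ (E F Eᵀ)⁻¹ (E r) ~ χ²(rank E) under the null.

The projection is idempotent and exact (E r̂ = 0 to 10⁻⁸); *h* provides the
global gross-error test.  Cochran's (1977) weighted mean and standard error
(weights 1/error; the Gatz–Smith variance formula, reducing to the ordinary
SE of the mean for equal errors) summarise ensembles of flux solutions
weighted inversely by their fitting errors.

## The synthetic toy study

`make_toy_model()` builds a pinned ~40-metabolite / 33-reaction aerobic
heterotroph: lumped glycolysis and gluconeogenesis, pyruvate dehydrogenase,
lumped TCA, the glyoxylate shunt (the only route to net C4 from C2 — acetate
growth requires it), pyruvate-carboxylase anaplerosis, oxidative
phosphorylation at P/O 2 (1 for FADH2), an ATP maintenance reaction, a
PFK/FBPase futile pair, and four storage sinks: glycogen (from G6P), PHB and
PHV (from acetyl-/propanoyl-CoA), TAG (from palmitoyl chains +
glycerol-3-P).  Every conversion is elementally and charge balanced; a
checksum of the canonical serialisation is pinned in the tests.

Design choices that shape the study's behaviour (all deliberate, all
documented here because they are what the toy's "physiology" consists of):

* **Storage-route ATP overheads** (glycogen lump 0, PHA polymerisation 2.1,
  TAG assembly 8 mol-ATP/mol) set the N-limited COD-efficiency ordering
  TAG > PHA (≈0.5 % behind) > glycogen (≈2 % behind on glucose).  Vertex
  solutions of the storage-maximisation LP therefore report a single
  compound, while MOMA-based selection within the near-optimal band
  recovers mixtures — the toy-scale analogue of genome-scale pathway
  redundancy.
* **Polymer export blocks** of comparable molar COD (12 glucosyl / 16 PHB /
  12 PHV monomers vs 1 TAG, ≈2.3 g-COD/mmol each) keep the MOMA compound
  split from being an artifact of arbitrary polymer unit sizes.
* **Biomass routes through the storage branch points**: carbohydrate is
  drawn from the glycogen pool, lipid from acyl chains + glycerol-3-P, and
  growing cells carry 10 % PHA granules.  The growth reference therefore
  transmits flux through every storage branch, seeding the MOMA overflow.
* **Growth-phase storage rates are pinned** (10 % of substrate COD in a
  35/45/20 glycogen/PHA/TAG split): organisms of this class measurably
  store during balanced growth, and the reference must reflect it.
* **Catabolite repression**: gluconeogenesis is fixed at zero on glucose
  (both phases).  Without this regulatory constraint the N-limited MOMA
  solutions run a glycolysis/gluconeogenesis/anaplerosis carbon-recycling
  loop that mimics the growth flux profile instead of storing.
* **Study conditions**: glucose uptake 2.0 (growth) / 0.28 (N-limited)
  mmol/(g-DW·h), acetate 6.0 / 0.84 — both 384 mg-COD/(g-DW·h) in growth,
  with the N-limited uptake at 14 % of it; N-limited O2 capacities 0.5 /
  0.75 mmol/(g-DW·h); growth NGAM 0.5; study NGAM 1.5.

The noise model for synthetic measurements is independent Gaussian with
relative SD (floored at an absolute SE of 0.02 for yield fractions),
truncated at physical sign constraints, with the covariance recorded
truthfully in the table.

What the toy does **not** emulate: isotope-labelling dynamics, batch
time-courses (only phase-wise steady-state snapshots), NADPH/NADH
distinction, compartmentation beyond in/ex, and the pathway redundancy of a
real genome-scale network.  Consequently, passing the packaged study shows
the machinery is correct and well-calibrated under known ground truth — not
that any particular objective describes a given real organism.

## Known limitations

* On the acetate toy study all seven objectives predict single-compound
  storage; the mixture patterns of the MOMA-based objectives appear on the
  glucose study only.  A small lumped network simply lacks enough parallel
  routes on acetate (everything funnels through acetyl-CoA), and the
  glycolysis/gluconeogenesis recycling loop cannot be repressed there
  because acetate growth needs gluconeogenesis.
* ATP-production maximisation is NGAM-insensitive under an O2 capacity
  (respiration pins to the cap regardless of maintenance), so it is
  calibrated by fallback, and the strictly-decreasing NGAM-curve property
  is asserted for the other flux-economy objectives.
* Environmental-MOMA NGAM-insensitivity is asserted over the operating
  range (NGAM 1.0–2.0), where the O2 capacity and the futile cycle absorb
  maintenance changes; at very low NGAM the curve still drifts.
* The problem sizes used throughout (33-reaction network, 100-replicate
  Monte-Carlo, 10⁴ null draws) were chosen to make every stage exactly
  verifiable against brute-force oracles and analytical distributions.
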