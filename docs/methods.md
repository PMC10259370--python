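# Methods

## Scope and model

`qcfill` validates single retrosynthetic steps by constrained
elementary-step exploration and an energy-only feasibility analysis. The
core modelling commitments are:

* **Electronic energies only.** Barriers and reaction energies are
  differences of total electronic energies on a common reference. No
  zero-point, thermal, or entropic corrections are applied, and no
  pre-exponential factors enter the kinetic comparison. This matches the
  data an automated semiempirical exploration produces and keeps the
  dominance argument transparent; it also means near-degenerate barrier
  pairs (within a few kJ mol⁻¹) should not be over-interpreted.
* **Compound-level aggregation.** Structures (3D conformers) sharing
  molecular connectivity form one compound; elementary steps whose
  endpoints map to the same compound multisets form one reaction whose
  best barrier and reaction energy are minima over member steps. Compound
  identity is the canonical, stereochemistry-free SMILES of the
  hydrogen-suppressed charged graph. Multisets (not sets) keep `2A → B`
  distinct from `A → B`.
* **Thermodynamic control for the rule-out.** Reactions with
  ΔE > `endo_tol` (default 0 kJ mol⁻¹) are discarded before any kinetic
  reasoning. This is deliberately aggressive: an endothermic elementary
  step can still be part of a viable multi-step mechanism, which is why
  multi-step cases are validated through explicit decompositions instead.
* **Kinetic dominance via the Maxwell–Boltzmann kinetic-energy
  distribution.** The survival function is the 3-translational-DOF form
  Q(3/2, E/RT) = erfc(√x) + (2/√π)√x·e^(−x). Among the forms one could
  attach to "kinetic energy of the reactants", the 3-DOF choice is the one
  consistent with the four-orders-of-magnitude separation between the
  218/250 kJ mol⁻¹ channels of the ether-synthesis case at 100 °C, which
  fixes the convention. Only competitors *more exothermic* than the target
  are tested for dominance: a less exothermic survivor with a higher
  barrier is doubly disfavored and cannot overturn the verdict.

## Parameters that matter

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| temperature | 373.15 | K | 100 °C, the reference condition of the analysis |
| endo_tol | 0 | kJ mol⁻¹ | strict sign rule for the endothermic rule-out |
| dominance_threshold | 100 | – | conservative pass line; clear-cut cases exceed 10⁴ |
| d_min | 0.5 | Å | minimum interatomic distance after sanitization; below this, semiempirical SCF reliably fails |
| n_rotamers, n_attack_points | 2, 2 | – | minimal plurality of initial arrangements per reactive pair |
| max_bond_modifications | 1 | – | one forming intermolecular bond; no dissociations, no intramolecular trials |
| stereoisomer cap | 64 | – | 2⁶ unspecified elements; bounds downstream exploration cost |
| step tolerance | 1 | kJ mol⁻¹ | slack on E_TS ≥ E_react and E_TS ≥ E_prod before a step is rejected |
| sec_per_trial | 20 | CPU s | pooled average over successful and dead-end trials |
| cost/trial scaling exponents | 2, 2 | – | quadratic energy-evaluation cost × quadratic pair growth |
| combiner weight w | 0.5 | – | confidence update strength; the combiner is a plug-in point |
| error budget | 0 | trials | any backend error makes the verdict inconclusive |
| adapter wall limit | 300 | s | generous margin over observed semiempirical step-search times |

Gas constant: 8.3144626 × 10⁻³ kJ mol⁻¹ K⁻¹; Hartree → kJ mol⁻¹ at
2625.499639, applied only at the external-adapter boundary.

## The surrogate backend: what it emulates, what it does not

The surrogate is a graph-level stand-in for a semiempirical exploration
engine. Its energy is a sum of bond-increment terms over the connectivity
graph (implicit hydrogens included) — a pure function of the molecular
graph, so results are bit-identical across runs and platforms. Step
outcomes come from an explicit rule table keyed by (reactant connectivity,
forming atom pair, optionally rotamer/attack), with unmatched trials
returning `no_step` like the dead-end trials of a real search.

The bundled ether-synthesis fixture encodes the energetics of a real
semiempirical exploration of iodoethane + phenol: the SN2 target channel
(barrier 218, ΔE −34 kJ mol⁻¹), ortho and para ring-attack channels
(250/−48 and 253/−52), one mildly exothermic meta channel (300/−10,
synthetic values chosen so the thermodynamic filter leaves four survivors
while the meta channel — less exothermic than the target — never enters
the dominance comparison), and 34 distinct endothermic decoy channels
(synthetic iodo-alcohol adducts) standing in for the unproductive
chemistry a free exploration discovers. The aggregated fixture network
therefore reproduces the reference counts (43 compounds, 38 reactions, 34
endothermic) by construction.

What passing tests on the surrogate do **not** show: that any particular
real reaction has these energetics, that a geometric saddle-point search
would converge, or that the semiempirical method is accurate for a given
chemistry. The surrogate verifies the *pipeline logic* — enumeration,
pruning, aggregation, filtering, dominance arithmetic, confidence flow,
budgeting — not the electronic structure. Reproducing energies requires
the external adapter with an installed program.

The Friedel–Crafts fixture exercises the multi-step path: a two-step
decomposition (acylium formation, then aromatic attack on a deactivated,
nitro-substituted ring) where only the first step has a rule-table entry
and the configured trial budget (100) runs out mid-way through the second
search. The step is reported inconclusive — the exploration was
incomplete, so the failed second step is not treated as a disproof.

## Numerical and design choices

* **Clash repair.** Embedded geometries are repaired by symmetrically
  displacing the closest pair along its separation vector (fixed axis for
  coincident atoms) with a 5 % overshoot to avoid stalls, iterating until
  the minimum distance reaches `d_min`; embedding retries up to 5 derived
  seeds before failing.
* **Barriers are floored at zero** (E_TS below E_react within the step
  tolerance is treated as barrierless), so the reaction-level
  `best_barrier` is always well defined.
* **Mapping-based pruning uses formed bonds, not just changed atoms.**
  An atom-mapped reaction SMILES yields both the changed-atom set and the
  specific intermolecular bonds formed; trial enumeration restricts atom
  pairs to those formed bonds. For the ether-synthesis mapping this leaves
  exactly the O···C pair (4 trials instead of 84); pruning by changed
  atoms alone would also keep the iodine, which the mapping shows is a
  leaving group, not a forming-bond partner.
* **Trial ordering is lexicographic** on (atom A, atom B, rotamer,
  attack), so trial logs are diffable and reaction merging is
  order-independent by construction (running minima).
* **Target matching tolerates unnamed byproducts.** A network reaction
  matches the target when its reactant compound multiset equals the
  precursors' and its products contain the named product compound(s); the
  leaving-group byproduct (e.g. HI) need not be declared.
* **Verdict boundaries.** `validated` requires the target found, ΔE ≤
  `endo_tol`, and a dominance ratio ≥ threshold against every more
  exothermic survivor. An exploration that is incomplete (budget) or over
  its error budget yields `inconclusive`, never `invalidated`: a missing
  step in an unfinished search is not evidence of infeasibility — search
  failures can be technical. Raising the dominance threshold can only
  demote a verdict (monotonicity is tested).
* **Confidence combiner.** `c′ = 1 − (1−c)(1−w)` / `c·(1−w)` / identity
  is the default; any plug-in combiner is checked against the contract
  (range [0, 1], validation never lowers, invalidation never raises) with
  1e-9 round-off slack.
* **Spin multiplicities** default to the electron-parity guess (even → 1,
  odd → 2); a backend-provided guess can override per structure. The
  external adapter passes charge and `multiplicity − 1` unpaired electrons
  through verbatim.
* **Stereochemistry.** Stereoisomer enumeration covers unspecified
  tetrahedral centers and double-bond geometries, leaving assigned
  elements untouched. The orchestrator explores the first canonical
  isomer by default (a config flag exposes enumeration); inputs whose
  stereochemistry SMILES cannot encode (e.g. axial chirality) are simply
  stereo-incomplete — no guessing is attempted.
* **Roles and channels.** Precursor roles default to "reactant" (role
  information is usually unavailable from retrosynthesis output); only
  reactant-role species enter trial generation. Declared byproduct and
  work-up fields are accepted and logged but not simulated. Catalyst
  dimerization is supported only through an explicit config mapping
  (catalyst SMILES → dimer SMILES added as an input species).
* **Homo-coupling** (A reacting with a second copy of A) is enumerated
  only when the declared stoichiometry of that precursor is ≥ 2.

## Problem sizes

The default test and acceptance runs use the fixture explorations: 84
trials (free) and 4 trials (mapped) for the ether-synthesis case, 184
planned trials across the Friedel–Crafts decomposition, and
trial-combinatorics cross-checks on molecule pairs of up to 12 heavy atoms
(50 random size pairs against a brute-force oracle). These sizes exercise
every code path of the pipeline; the budget model is what extrapolates to
production-scale explorations (10⁴–10⁶ trials).

## Known limitations

* The external adapter's step search is a rigid-body approach scan
  (frozen internal geometries, distance grid on the forming pair, highest
  point as the transition-state estimate, distance-based bond perception
  at the end point). It is a crude NT-style probe, not a saddle-point
  optimizer; barriers from it are upper-bound flavored and product
  perception assigns single bonds only.
* No solvation model: explorations are gas-phase, so strongly
  solvent-mediated chemistry (and base-assisted variants, e.g. phenolate
  instead of phenol as the nucleophile) must be posed explicitly as
  different inputs.
* Reaction-count reproducibility: compound/reaction counts of a real
  exploration depend on the engine's internal deduplication and on the
  electronic-structure method; the fixture encodes them, the pipeline does
  not derive them from physics.
* The multi-step path requires a user-supplied decomposition; automated
  discovery of intermediates is out of scope.
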