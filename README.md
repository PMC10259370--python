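# qcfill

First-principles fill-in validation for AI-driven retrosynthesis planning.

AI retrosynthesis models propose disconnections with a confidence score, but
for reactions that are rare in the training data (patent reaction corpora
are heavily imbalanced) that confidence is low and experimental data cannot
be produced on demand. `qcfill` implements the complementary loop: each
low-confidence single-step prediction is handed to an automated
reaction-network exploration that probes its chemistry from first
principles, and the resulting thermodynamic/kinetic verdict is folded back
into the step's confidence.

The pipeline, in the order it runs:

1. **Input preparation** (`molecule_io`) — precursor and product SMILES are
   parsed, sanitized 3D conformers are embedded (with clash repair, since
   overlapping nuclei make quantum-chemistry calculations fail), total
   charges are read from the SMILES, spin multiplicities are guessed by
   electron parity, and unspecified stereocenters can be enumerated. An
   atom-mapped reaction SMILES, when available, yields the set of *changed
   atoms* and the specific bond that forms.
2. **Trial enumeration** (`trial_generator`) — constrained bimolecular
   elementary-step trials: every pair of non-hydrogen atoms across the two
   reactants, times `n_rotamers × n_attack_points` initial arrangements.
   The count is `n_A · n_B · R · P` — quadratic in system size — unless the
   atom mapping prunes it to the forming bond.
3. **Step searches** (`energy_backends`) — a pluggable calculator contract.
   The deterministic surrogate backend (bond-increment energies plus an
   explicit step-outcome rule table) makes the whole pipeline testable
   without any quantum-chemistry install; the external adapter shells out
   to a semiempirical program (e.g. `xtb`), converting Hartree to kJ mol⁻¹
   at the boundary (1 Eₕ = 2625.499639 kJ mol⁻¹).
4. **Network aggregation** (`reaction_network`) — structures with the same
   connectivity form a *compound*; elementary steps with the same
   compound-level endpoints merge into a *reaction* whose best barrier is
   the minimum over member steps.
5. **Feasibility analysis** (`feasibility`) — endothermic reactions are
   ruled out under the assumption of thermodynamic control; among the
   surviving channels the target must dominate kinetically. The fraction of
   the reactant ensemble able to cross a barrier `E` follows the
   three-degree-of-freedom Maxwell–Boltzmann kinetic-energy distribution,

   ```
   P(KE > E) = erfc(√x) + (2/√π) √x e^(−x),   x = E / RT,
   ```

   and the dominance ratio for target barrier `E_t` vs a competitor's
   `E_c > E_t` is `[P(KE > E_t) − P(KE > E_c)] / P(KE > E_c)`.
6. **Confidence update and budgeting** (`orchestrator`,
   `resource_estimator`) — the verdict adjusts the model confidence
   (`c′ = 1 − (1 − c)(1 − w)` on validation, `c′ = c(1 − w)` on
   invalidation, unchanged when inconclusive), and a resource model bounds
   the exploration: at ~20 CPU s per trial a single core covers 30 240
   trials per week, and doubling the system size cuts weekly coverage by
   2²·2² = 16.

## Worked example

The bundled ether-synthesis fixture (iodoethane + phenol → ethoxybenzene,
an SN2 substitution) encodes a full surrogate exploration:

```python
from qcfill import ValidationConfig, SurrogateBackend, validate_step, thermo_filter
from qcfill.orchestrator import williamson_route, williamson_rule_table

step = williamson_route().steps[0]          # AI confidence 0.42
backend = SurrogateBackend(rule_table=williamson_rule_table())

report = validate_step(step, config=ValidationConfig(use_mapping=False),
                       backend=backend)
print(report.status)                         # validated
print(report.n_trials_planned)               # 84
print(report.summary.n_reactions)            # 38
print(report.summary.n_endothermic)          # 34
print(len(thermo_filter(report.network)))    # 4
print(report.verdict.target_barrier)         # 218.0
print(report.verdict.target_energy)          # -34.0
print(round(report.verdict.dominance_ratio)) # 28184
print(report.confidence_after)               # 0.71
```

Reading: the free (unmapped) exploration of the reacting pair spawns
3 × 7 × 2 × 2 = 84 trials, which aggregate into 38 compound-level
reactions. 34 are endothermic and are ruled out; of the four survivors the
target substitution (barrier 218 kJ mol⁻¹, ΔE −34 kJ mol⁻¹) faces two more
exothermic ring-attack competitors with barriers of 250 and 253 kJ mol⁻¹.
At 100 °C the population able to cross 218 but not 250 kJ mol⁻¹ outnumbers
the population above 250 kJ mol⁻¹ by a factor of ~2.8 × 10⁴ — four orders
of magnitude — so the step is validated and its confidence rises from 0.42
to 0.71. With the atom mapping supplied (`use_mapping=True`, the default),
the same verdict needs only 4 trials instead of 84.

The same machinery is scriptable from the shell:

```bash
qcfill mb-ratio --lo 218 --hi 250        # {"ratio": 28183.69..., "log10": 4.45}
qcfill estimate --cores 1 --days 7       # {"trials_in_budget": 30240, ...}
qcfill fixtures --name williamson --seed 7 --outdir fx
qcfill validate --route fx/route.json --rules fx/rules.json --no-mapping
```

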