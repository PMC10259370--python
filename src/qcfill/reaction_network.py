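"""Reaction-network bookkeeping with compound-level aggregation.

An exploration produces many individual objects: 3D conformers, elementary
steps (one transition state, no intermediates), and their energies.  For
feasibility reasoning these are aggregated: structures sharing molecular
connectivity form one *compound*, and elementary steps whose endpoints map to
the same compound multisets form one *reaction* whose best barrier is the
minimum over its member steps.  This module stores that aggregation, keeps
the energetic invariants honest, and serializes the whole network to JSON.

Energies are total electronic energies in kJ mol⁻¹ on a common per-network
reference; no thermal or entropic corrections are implied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .molecule_io import Structure, connectivity_key

__all__ = [
    "Compound",
    "ElementaryStep",
    "Reaction",
    "ReactionNetwork",
    "StepInvariantError",
    "NetworkSummary",
    "STEP_TOL_DEFAULT",
    "SCHEMA_VERSION",
]

#: Tolerance (kJ/mol) for the transition-state inequality checks.
STEP_TOL_DEFAULT = 1.0

SCHEMA_VERSION = "qcfill-net/1"


class StepInvariantError(ValueError):
    """An elementary step violates an energetic or connectivity invariant."""


@dataclass
class Compound:
    """All structures sharing one molecular connectivity."""

    id: str
    connectivity_key: str
    structure_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ElementaryStep:
    """One transformation through a single transition state.

    ``ts_structure_id`` may be ``None`` for barrierless steps and for
    surrogate searches that produce energies without geometries.
    """

    id: str
    reactant_structure_ids: tuple[str, ...]
    product_structure_ids: tuple[str, ...]
    e_react: float  # kJ/mol
    e_ts: float
    e_prod: float
    ts_structure_id: Optional[str] = None

    @property
    def barrier(self) -> float:
        """Activation energy E(TS) − E(reactants), floored at 0 kJ/mol."""
        return max(0.0, self.e_ts - self.e_react)

    @property
    def reaction_energy(self) -> float:
        return self.e_prod - self.e_react


@dataclass
class Reaction:
    """Compound-level aggregate of alternative elementary steps."""

    id: str
    reactant_compounds: tuple[str, ...]  # sorted multiset of compound ids
    product_compounds: tuple[str, ...]
    step_ids: list[str] = field(default_factory=list)
    best_barrier: float = float("inf")  # kJ/mol, min over member steps
    reaction_energy: float = float("inf")  # kJ/mol, min over member steps


@dataclass(frozen=True)
class NetworkSummary:
    n_compounds: int
    n_structures: int
    n_reactions: int
    n_steps: int
    n_endothermic: int


class ReactionNetwork:
    """Registry of structures, compounds, elementary steps and reactions.

    Registration is idempotent at the compound level (same connectivity key →
    same compound) and merge-commutative at the reaction level: registering
    steps in any order yields the same reactions and best barriers.
    """

    def __init__(self, step_tol: float = STEP_TOL_DEFAULT):
        self.step_tol = step_tol
        self.compounds: dict[str, Compound] = {}
        self.structures: dict[str, Structure] = {}
        self.steps: dict[str, ElementaryStep] = {}
        self.reactions: dict[str, Reaction] = {}
        self.provenance: dict[str, str] = {}  # step id -> trial descriptor
        self._key_to_compound: dict[str, str] = {}
        self._pair_to_reaction: dict[tuple, str] = {}
        self._structure_compound: dict[str, str] = {}

    # -- structures and compounds -----------------------------------------

    def add_structure(self, structure: Structure, key: Optional[str] = None) -> str:
        """Store a structure and aggregate it into its compound; returns the
        structure id (compound membership is available via
        :meth:`compound_of`)."""
        key = key if key is not None else connectivity_key(structure.graph)
        sid = f"s{len(self.structures)}"
        self.structures[sid] = structure
        cid = self._key_to_compound.get(key)
        if cid is None:
            cid = f"c{len(self.compounds)}"
            self.compounds[cid] = Compound(id=cid, connectivity_key=key)
            self._key_to_compound[key] = cid
        self.compounds[cid].structure_ids.append(sid)
        self._structure_compound[sid] = cid
        return sid

    def register_structure(self, structure: Structure, key: Optional[str] = None) -> str:
        """Register a structure; returns the id of its (possibly new) compound."""
        return self._structure_compound[self.add_structure(structure, key=key)]

    def compound_of(self, structure_id: str) -> str:
        return self._structure_compound[structure_id]

    def compound_by_key(self, key: str) -> Optional[str]:
        return self._key_to_compound.get(key)

    # -- steps and reactions ----------------------------------------------

    def _compound_multiset(self, structure_ids: Sequence[str]) -> tuple[str, ...]:
        return tuple(sorted(self._structure_compound[sid] for sid in structure_ids))

    def register_step(self, step: ElementaryStep, provenance: str = "") -> str:
        """Validate and store a step, merging it into its reaction.

        Steps with identical (reactant compound, product compound) multiset
        pairs merge into one reaction; ``best_barrier`` and
        ``reaction_energy`` are running minima over member steps.
        """
        tol = self.step_tol
        if step.e_ts < step.e_react - tol:
            raise StepInvariantError(
                f"E_TS ({step.e_ts}) < E_react ({step.e_react}) - tol ({tol})"
            )
        if step.e_ts < step.e_prod - tol:
            raise StepInvariantError(
                f"E_TS ({step.e_ts}) < E_prod ({step.e_prod}) - tol ({tol})"
            )
        for sid in step.reactant_structure_ids + step.product_structure_ids:
            if sid not in self.structures:
                raise StepInvariantError(f"unknown structure id {sid!r}")
        reactants = self._compound_multiset(step.reactant_structure_ids)
        products = self._compound_multiset(step.product_structure_ids)
        if reactants == products:
            raise StepInvariantError(
                "reactant and product compound multisets are identical "
                "(connectivity must change)"
            )
        self.steps[step.id] = step
        if provenance:
            self.provenance[step.id] = provenance
        pair = (reactants, products)
        rid = self._pair_to_reaction.get(pair)
        if rid is None:
            rid = f"r{len(self.reactions)}"
            self.reactions[rid] = Reaction(
                id=rid, reactant_compounds=reactants, product_compounds=products
            )
            self._pair_to_reaction[pair] = rid
        rxn = self.reactions[rid]
        rxn.step_ids.append(step.id)
        rxn.best_barrier = min(rxn.best_barrier, step.barrier)
        rxn.reaction_energy = min(rxn.reaction_energy, step.reaction_energy)
        return rid

    # -- summaries ----------------------------------------------------------

    def summarize(self, endo_tol: float = 0.0) -> NetworkSummary:
        """Counts record; ``n_endothermic`` counts reactions with
        reaction energy above ``endo_tol`` (kJ/mol)."""
        n_endo = sum(1 for r in self.reactions.values() if r.reaction_energy > endo_tol)
        return NetworkSummary(
            n_compounds=len(self.compounds),
            n_structures=len(self.structures),
            n_reactions=len(self.reactions),
            n_steps=len(self.steps),
            n_endothermic=n_endo,
        )

    # -- persistence ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "step_tol": self.step_tol,
            "compounds": [
                {"id": c.id, "connectivity_key": c.connectivity_key,
                 "structure_ids": list(c.structure_ids)}
                for c in self.compounds.values()
            ],
            "structures": [
                {
                    "id": sid,
                    "elements": list(s.elements),
                    "coordinates": [[float(v) for v in row] for row in s.coordinates],
                    "charge": s.charge,
                    "multiplicity": s.multiplicity,
                }
                for sid, s in self.structures.items()
            ],
            "steps": [
                {
                    "id": st.id,
                    "reactants": list(st.reactant_structure_ids),
                    "products": list(st.product_structure_ids),
                    "ts": st.ts_structure_id,
                    "e_react": st.e_react,
                    "e_ts": st.e_ts,
                    "e_prod": st.e_prod,
                }
                for st in self.steps.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "reactant_compounds": list(r.reactant_compounds),
                    "product_compounds": list(r.product_compounds),
                    "step_ids": list(r.step_ids),
                    "best_barrier": r.best_barrier,
                    "reaction_energy": r.reaction_energy,
                }
                for r in self.reactions.values()
            ],
            "provenance": dict(self.provenance),
        }

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_dict(cls, data: dict) -> "ReactionNetwork":
        if data.get("schema") != SCHEMA_VERSION:
            raise ValueError(f"unsupported network schema {data.get('schema')!r}")
        import numpy as np

        from .molecule_io import Atom, MolGraph

        net = cls(step_tol=data.get("step_tol", STEP_TOL_DEFAULT))
        for c in data["compounds"]:
            net.compounds[c["id"]] = Compound(
                id=c["id"],
                connectivity_key=c["connectivity_key"],
                structure_ids=list(c["structure_ids"]),
            )
            net._key_to_compound[c["connectivity_key"]] = c["id"]
            for sid in c["structure_ids"]:
                net._structure_compound[sid] = c["id"]
        for s in data["structures"]:
            # connectivity lives in the compound key; store a minimal graph
            graph = MolGraph(
                atoms=tuple(Atom(element=el) for el in s["elements"]),
                bonds=(),
                total_charge=s["charge"],
            )
            net.structures[s["id"]] = Structure(
                graph=graph,
                elements=tuple(s["elements"]),
                coordinates=np.asarray(s["coordinates"], dtype=float),
                charge=s["charge"],
                multiplicity=s["multiplicity"],
                d_min=0.0,
            )
        for st in data["steps"]:
            net.steps[st["id"]] = ElementaryStep(
                id=st["id"],
                reactant_structure_ids=tuple(st["reactants"]),
                product_structure_ids=tuple(st["products"]),
                ts_structure_id=st["ts"],
                e_react=st["e_react"],
                e_ts=st["e_ts"],
                e_prod=st["e_prod"],
            )
        for r in data["reactions"]:
            rxn = Reaction(
                id=r["id"],
                reactant_compounds=tuple(r["reactant_compounds"]),
                product_compounds=tuple(r["product_compounds"]),
                step_ids=list(r["step_ids"]),
                best_barrier=r["best_barrier"],
                reaction_energy=r["reaction_energy"],
            )
            net.reactions[r["id"]] = rxn
            net._pair_to_reaction[(rxn.reactant_compounds, rxn.product_compounds)] = r["id"]
        net.provenance = dict(data.get("provenance", {}))
        return net

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ReactionNetwork":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def export_edgelist(self, path: Union[str, Path]) -> None:
        """Write the compound–reaction bipartite graph as a TSV edge list."""
        lines = ["source\ttarget\trole"]
        for r in self.reactions.values():
            for cid in r.reactant_compounds:
                lines.append(f"{cid}\t{r.id}\treactant")
            for cid in r.product_compounds:
                lines.append(f"{r.id}\t{cid}\tproduct")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
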