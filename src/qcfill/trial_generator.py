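"""Constrained enumeration of bimolecular elementary-step trials.

Left unconstrained, a reactive exploration tries to bond every atom of one
molecule to every atom of the other — quadratic in system size before
rotamers and attack points multiply it further.  This module enumerates that
trial space under the standard constraints (bimolecular only, one
intermolecular bond formation, no dissociations, hydrogens unreactive) and,
when an atom-to-atom mapping is available, prunes it to the bond the mapping
says must form, which is what makes single-step validation cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .molecule_io import AtomMapping, Structure

__all__ = [
    "Trial",
    "TrialConstraints",
    "reactive_atoms",
    "generate_trials",
    "count_trials",
]


@dataclass(frozen=True)
class TrialConstraints:
    """Knobs narrowing the reactive-trial space.

    Defaults mirror a conservative bimolecular exploration: all heavy atoms
    reactive, two rotamers, two attack points, a single bond modification,
    no unimolecular trials or dissociations.  Broadening any of these grows
    the trial count multiplicatively.
    """

    reactive_atom_rule: str = "non_hydrogen"  # or "all"
    mapping: Optional[AtomMapping] = None
    n_rotamers: int = 2
    n_attack_points: int = 2
    max_bond_modifications: int = 1
    allow_unimolecular: bool = False
    allow_dissociations: bool = False
    allow_homo_coupling: bool = False

    def __post_init__(self) -> None:
        if self.n_rotamers < 1 or self.n_attack_points < 1:
            raise ValueError("n_rotamers and n_attack_points must be ≥ 1")


@dataclass(frozen=True)
class Trial:
    """One reactive attempt: bring two structures together so that one
    intermolecular bond forms between ``atom_a`` (in A) and ``atom_b`` (in B),
    from a given rotamer and attack-point initial arrangement."""

    structure_a: Structure = field(repr=False)
    structure_b: Structure = field(repr=False)
    atom_a: int  # heavy-atom graph index in A
    atom_b: int
    rotamer_index: int
    attack_index: int

    @property
    def forming_elements(self) -> tuple[str, str]:
        return (
            self.structure_a.graph.atoms[self.atom_a].element,
            self.structure_b.graph.atoms[self.atom_b].element,
        )

    def descriptor(self) -> str:
        ea, eb = self.forming_elements
        return (
            f"{ea}{self.atom_a}~{eb}{self.atom_b}"
            f"/rot{self.rotamer_index}/att{self.attack_index}"
        )


def reactive_atoms(structure: Structure, constraints: TrialConstraints) -> list[int]:
    """Heavy-atom graph indices allowed to form the new bond.

    Default rule: every non-hydrogen atom.  With an atom mapping, only atoms
    whose map index is in ``changed_atoms`` remain — spectator moieties such
    as an untouched aromatic ring are excluded entirely.
    """
    graph = structure.graph
    if constraints.mapping is not None:
        indexed = [a.map_index for a in graph.atoms if a.map_index is not None]
        if not indexed:
            raise ValueError(
                "mapping constraint given but the structure carries no atom-map "
                "indices; map the reaction SMILES or drop the mapping"
            )
        return [
            i
            for i, a in enumerate(graph.atoms)
            if a.map_index in constraints.mapping.changed_atoms
        ]
    if constraints.reactive_atom_rule == "all":
        return list(range(graph.n_atoms))
    return [i for i, a in enumerate(graph.atoms) if a.element != "H"]


def _mapped_pair_allowed(
    a_map: Optional[int], b_map: Optional[int], mapping: AtomMapping
) -> bool:
    """A mapped trial must realize a bond the mapping says is formed."""
    if a_map is None or b_map is None:
        return False
    if not mapping.formed_pairs:
        # mapping without formed-bond information: fall back to changed atoms
        return True
    return (min(a_map, b_map), max(a_map, b_map)) in mapping.formed_pairs


def generate_trials(
    a: Structure, b: Structure, constraints: TrialConstraints = TrialConstraints()
) -> list[Trial]:
    """Enumerate bimolecular trials for the pair (A, B).

    Without a mapping the list has exactly
    ``|reactive(A)| × |reactive(B)| × n_rotamers × n_attack_points`` entries;
    with a mapping, atom pairs are additionally restricted to the bonds the
    mapping forms between the two molecules.  Ordering is lexicographic on
    (atom_a, atom_b, rotamer, attack) so runs are diffable; an empty reactive
    set on either side yields an empty list.
    """
    ra = reactive_atoms(a, constraints)
    rb = reactive_atoms(b, constraints)
    mapping = constraints.mapping
    trials: list[Trial] = []
    for i in ra:
        a_map = a.graph.atoms[i].map_index
        for j in rb:
            if mapping is not None and not _mapped_pair_allowed(
                a_map, b.graph.atoms[j].map_index, mapping
            ):
                continue
            for rot in range(constraints.n_rotamers):
                for att in range(constraints.n_attack_points):
                    trials.append(
                        Trial(
                            structure_a=a,
                            structure_b=b,
                            atom_a=i,
                            atom_b=j,
                            rotamer_index=rot,
                            attack_index=att,
                        )
                    )
    return trials


def count_trials(
    n_a: int, n_b: int, constraints: TrialConstraints = TrialConstraints()
) -> int:
    """Closed-form trial count for reactive-set sizes ``n_a`` and ``n_b``.

    ``n_a · n_b · n_rotamers · n_attack_points`` — quadratic in system size
    for a fixed pair of molecules, hence the 4× growth when both reactive
    sets double.
    """
    if n_a < 0 or n_b < 0:
        raise ValueError("reactive-set sizes must be non-negative")
    return n_a * n_b * constraints.n_rotamers * constraints.n_attack_points
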