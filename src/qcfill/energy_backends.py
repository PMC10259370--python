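"""Energy backends: the calculator contract, a deterministic surrogate, and a
subprocess adapter for an external semiempirical program.

The exploration logic only needs two capabilities from a backend: a total
electronic energy for a structure, and an elementary-step search for a
reactive trial.  Real explorations obtain both from a semiempirical
tight-binding program (e.g. GFN2-xTB) driving saddle-point searches; that is
delegated to :class:`ExternalBackend`, which shells out to a configured
executable.  The :class:`SurrogateBackend` is a graph-level stand-in — a
bond-increment energy model plus an explicit rule table for step outcomes —
that makes every pipeline stage deterministic and testable without any
quantum-chemistry installation.  Energies are kJ mol⁻¹ throughout; external
outputs in Hartree are converted at the adapter boundary.
"""

from __future__ import annotations

import json
import re
import shutil
import subprocess
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence, Union

from rdkit import Chem

from .molecule_io import AROMATIC, Structure, connectivity_key, embed_3d, parse_smiles, write_xyz
from .trial_generator import Trial

__all__ = [
    "CalcResult",
    "ProposedStep",
    "StepSearchResult",
    "EnergyBackend",
    "StepRule",
    "RuleTable",
    "SurrogateBackend",
    "ExternalBackend",
    "BackendUnavailableError",
    "HARTREE_TO_KJ_PER_MOL",
    "DEFAULT_BOND_INCREMENTS",
]

#: CODATA conversion applied at the external-adapter boundary.
HARTREE_TO_KJ_PER_MOL = 2625.499639


class BackendUnavailableError(RuntimeError):
    """The configured external program cannot be executed."""


@dataclass(frozen=True)
class CalcResult:
    """Outcome of a single-point energy evaluation.

    ``energy`` (kJ/mol, backend reference) is present iff ``converged``;
    ``wall_seconds`` is informational only and never enters any verdict.
    """

    converged: bool
    energy: Optional[float] = None
    wall_seconds: float = 0.0
    message: str = ""

    def __post_init__(self) -> None:
        if not self.converged and self.energy is not None:
            raise ValueError("unconverged results must not carry an energy")


@dataclass(frozen=True)
class ProposedStep:
    """An elementary step as found by a backend, before network registration."""

    reactants: tuple[Structure, ...]
    products: tuple[Structure, ...]
    e_react: float  # kJ/mol
    e_ts: float
    e_prod: float
    ts_structure: Optional[Structure] = None


@dataclass(frozen=True)
class StepSearchResult:
    outcome: str  # "step_found" | "no_step" | "error"
    step: Optional[ProposedStep] = None
    message: str = ""

    def __post_init__(self) -> None:
        if (self.outcome == "step_found") != (self.step is not None):
            raise ValueError("step present iff outcome is step_found")


class EnergyBackend(Protocol):
    """Calculator contract used by the orchestrator."""

    name: str

    def energy(self, structure: Structure) -> CalcResult: ...

    def search_step(self, trial: Trial) -> StepSearchResult: ...


# --------------------------------------------------------------------------
# surrogate backend
# --------------------------------------------------------------------------

#: Bond-increment energies (kJ/mol) of the surrogate model.  Synthetic
#: calibration values — internally consistent, not fitted to experiment.
DEFAULT_BOND_INCREMENTS: dict[tuple[tuple[str, str], Union[int, str]], float] = {
    (("C", "H"), 1): -400.0,
    (("C", "C"), 1): -350.0,
    (("C", "O"), 1): -360.0,
    (("H", "O"), 1): -460.0,
    (("C", "I"), 1): -230.0,
    (("C", "C"), AROMATIC): -500.0,
    (("H", "I"), 1): -298.0,
    (("C", "O"), 2): -740.0,
    (("C", "C"), 2): -610.0,
    (("C", "Cl"), 1): -330.0,
    (("Al", "Cl"), 1): -420.0,
    (("C", "N"), 1): -300.0,
    (("N", "O"), 1): -200.0,
    (("N", "O"), 2): -480.0,
    (("C", "F"), 1): -480.0,
    (("C", "N"), AROMATIC): -450.0,
}

#: Fallback increment for bonds absent from the table (kJ/mol).
FALLBACK_INCREMENT = -300.0


def _bond_key(el_i: str, el_j: str, order: Union[int, str]) -> tuple:
    return (tuple(sorted((el_i, el_j))), order)


@dataclass(frozen=True)
class StepRule:
    """One entry of the surrogate's step-outcome table.

    Matches a trial by the connectivity keys of the two reactants and the
    forming atom pair, optionally narrowed to a specific rotamer/attack
    combination; symmetric in the (A, B) orientation.  On a match the
    surrogate reports a step with the configured barrier and reaction energy
    (kJ/mol, relative to the bond-increment reactant energy) whose products
    are embedded from the given SMILES.
    """

    a_key: str
    a_atom: int
    b_key: str
    b_atom: int
    barrier: float
    reaction_energy: float
    product_smiles: tuple[str, ...]
    rotamer_index: Optional[int] = None
    attack_index: Optional[int] = None

    def matches(self, trial: Trial, key_a: str, key_b: str) -> bool:
        if self.rotamer_index is not None and trial.rotamer_index != self.rotamer_index:
            return False
        if self.attack_index is not None and trial.attack_index != self.attack_index:
            return False
        direct = (
            key_a == self.a_key
            and trial.atom_a == self.a_atom
            and key_b == self.b_key
            and trial.atom_b == self.b_atom
        )
        swapped = (
            key_a == self.b_key
            and trial.atom_a == self.b_atom
            and key_b == self.a_key
            and trial.atom_b == self.a_atom
        )
        return direct or swapped

    def to_dict(self) -> dict:
        return {
            "a_key": self.a_key,
            "a_atom": self.a_atom,
            "b_key": self.b_key,
            "b_atom": self.b_atom,
            "barrier": self.barrier,
            "reaction_energy": self.reaction_energy,
            "product_smiles": list(self.product_smiles),
            "rotamer_index": self.rotamer_index,
            "attack_index": self.attack_index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StepRule":
        return cls(
            a_key=d["a_key"],
            a_atom=d["a_atom"],
            b_key=d["b_key"],
            b_atom=d["b_atom"],
            barrier=d["barrier"],
            reaction_energy=d["reaction_energy"],
            product_smiles=tuple(d["product_smiles"]),
            rotamer_index=d.get("rotamer_index"),
            attack_index=d.get("attack_index"),
        )


@dataclass
class RuleTable:
    rules: list[StepRule] = field(default_factory=list)

    def lookup(self, trial: Trial, key_a: str, key_b: str) -> Optional[StepRule]:
        for rule in self.rules:
            if rule.matches(trial, key_a, key_b):
                return rule
        return None

    def save(self, path: Union[str, Path]) -> None:
        doc = {"schema": "qcfill-rules/1", "rules": [r.to_dict() for r in self.rules]}
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RuleTable":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        if doc.get("schema") != "qcfill-rules/1":
            raise ValueError(f"unsupported rule-table schema {doc.get('schema')!r}")
        return cls(rules=[StepRule.from_dict(d) for d in doc["rules"]])


class SurrogateBackend:
    """Deterministic graph-level backend for testing the pipeline.

    The energy of a structure is the sum of bond increments over its
    connectivity graph (implicit hydrogens included), a pure function of the
    molecular graph — identical across runs and platforms.  Step searches
    consult an explicit :class:`RuleTable`; a trial without a matching rule
    is a ``no_step`` outcome, mirroring the dead-end trials of a real
    exploration.
    """

    name = "surrogate"

    def __init__(
        self,
        rule_table: Optional[RuleTable] = None,
        bond_increments: Optional[dict] = None,
        fallback_increment: float = FALLBACK_INCREMENT,
        embed_seed: int = 2023,
    ):
        self.rule_table = rule_table or RuleTable()
        self.increments = dict(bond_increments or DEFAULT_BOND_INCREMENTS)
        self.fallback = fallback_increment
        self.embed_seed = embed_seed
        self._structure_cache: dict[str, Structure] = {}

    # -- energies ----------------------------------------------------------

    def graph_energy(self, structure: Structure) -> float:
        graph = structure.graph
        if graph.n_atoms == 0:
            raise ValueError("cannot evaluate the energy of an empty molecule")
        total = 0.0
        for b in graph.bonds:
            key = _bond_key(graph.atoms[b.i].element, graph.atoms[b.j].element, b.order)
            total += self.increments.get(key, self.fallback)
        for a in graph.atoms:
            key = _bond_key(a.element, "H", 1)
            total += a.n_h * self.increments.get(key, self.fallback)
        return total

    def energy(self, structure: Structure) -> CalcResult:
        return CalcResult(converged=True, energy=self.graph_energy(structure))

    # -- step search --------------------------------------------------------

    def _embed_product(self, smiles: str) -> Structure:
        cached = self._structure_cache.get(smiles)
        if cached is None:
            cached = embed_3d(parse_smiles(smiles), seed=self.embed_seed)
            self._structure_cache[smiles] = cached
        return cached

    def search_step(self, trial: Trial) -> StepSearchResult:
        key_a = connectivity_key(trial.structure_a.graph)
        key_b = connectivity_key(trial.structure_b.graph)
        rule = self.rule_table.lookup(trial, key_a, key_b)
        if rule is None:
            return StepSearchResult(outcome="no_step", message="no matching rule")
        e_react = self.graph_energy(trial.structure_a) + self.graph_energy(trial.structure_b)
        products = tuple(self._embed_product(s) for s in rule.product_smiles)
        step = ProposedStep(
            reactants=(trial.structure_a, trial.structure_b),
            products=products,
            e_react=e_react,
            e_ts=e_react + rule.barrier,
            e_prod=e_react + rule.reaction_energy,
        )
        return StepSearchResult(outcome="step_found", step=step)


# --------------------------------------------------------------------------
# external adapter
# --------------------------------------------------------------------------

#: Regex for the total-energy line of common tight-binding program output,
#: e.g. ``:: total energy   -12.176438312381 Eh``.
_ENERGY_PATTERNS = (
    re.compile(r"total energy\s+(-?\d+\.\d+)", re.IGNORECASE),
    re.compile(r"TOTAL ENERGY\s+(-?\d+\.\d+)\s*Eh", re.IGNORECASE),
)


def parse_total_energy_hartree(stdout: str) -> float:
    """Extract the total electronic energy (Hartree) from program output."""
    for pattern in _ENERGY_PATTERNS:
        m = pattern.search(stdout)
        if m:
            return float(m.group(1))
    raise ValueError("no total-energy line found in program output")


class ExternalBackend:
    """Subprocess adapter for an external semiempirical program (e.g. xtb).

    Writes the structure as XYZ, invokes the configured executable with the
    molecular charge and number of unpaired electrons, and parses the total
    energy from standard output (Hartree → kJ/mol at this boundary).  Spin
    and charge are passed through verbatim; restricted-open-shell or
    point-group options go in ``extra_flags``.  All invocations are logged
    to ``log`` (a list of command/duration records).
    """

    name = "external"

    def __init__(
        self,
        executable: str = "xtb",
        method_flags: Sequence[str] = ("--gfn", "2"),
        extra_flags: Sequence[str] = (),
        timeout_s: float = 300.0,
        workdir: Optional[Union[str, Path]] = None,
    ):
        self.executable = executable
        self.method_flags = tuple(method_flags)
        self.extra_flags = tuple(extra_flags)
        self.timeout_s = timeout_s
        self.workdir = Path(workdir) if workdir else None
        self.log: list[dict] = []

    def _check_available(self) -> None:
        if shutil.which(self.executable) is None:
            raise BackendUnavailableError(
                f"external program {self.executable!r} not found on PATH; install "
                "it or point the backend at the executable (config key "
                "'executable'), or use the surrogate backend"
            )

    def energy(self, structure: Structure) -> CalcResult:
        try:
            self._check_available()
        except BackendUnavailableError as exc:
            return CalcResult(converged=False, message=str(exc))
        start = time.monotonic()
        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            xyz = Path(tmp) / "structure.xyz"
            write_xyz(xyz, structure.elements, structure.coordinates)
            cmd = [
                self.executable,
                str(xyz),
                "--chrg",
                str(structure.charge),
                "--uhf",
                str(structure.multiplicity - 1),
                *self.method_flags,
                *self.extra_flags,
            ]
            try:
                proc = subprocess.run(
                    cmd,
                    capture_output=True,
                    text=True,
                    timeout=self.timeout_s,
                    cwd=tmp,
                )
            except subprocess.TimeoutExpired:
                return CalcResult(
                    converged=False,
                    wall_seconds=time.monotonic() - start,
                    message=f"calculation exceeded {self.timeout_s} s wall limit",
                )
        wall = time.monotonic() - start
        self.log.append({"cmd": cmd, "wall_seconds": wall, "returncode": proc.returncode})
        if proc.returncode != 0:
            return CalcResult(
                converged=False,
                wall_seconds=wall,
                message=f"{self.executable} exited {proc.returncode}: {proc.stderr[-500:]}",
            )
        try:
            hartree = parse_total_energy_hartree(proc.stdout)
        except ValueError as exc:
            return CalcResult(converged=False, wall_seconds=wall, message=str(exc))
        return CalcResult(
            converged=True, energy=hartree * HARTREE_TO_KJ_PER_MOL, wall_seconds=wall
        )

    # -- NT-style approach scan -------------------------------------------

    #: approach-coordinate grid (Å) for the forming-pair distance
    scan_distances: tuple[float, ...] = (3.0, 2.7, 2.4, 2.1, 1.9, 1.7, 1.55, 1.45)

    def _supermolecule(self, trial: Trial, distance: float) -> tuple[tuple[str, ...], "np.ndarray"]:
        """Rigidly place B so the forming pair sits at ``distance`` Å.

        The attack direction leaves A's centroid through the forming atom
        (tilted per ``attack_index``); ``rotamer_index`` rotates B about the
        approach axis.  Rigid-body placement only — internal geometries are
        frozen, relaxation is left to the external program.
        """
        import numpy as np

        a_xyz = trial.structure_a.coordinates
        b_xyz = np.array(trial.structure_b.coordinates, copy=True)
        pa = a_xyz[trial.atom_a]
        axis = pa - a_xyz.mean(axis=0)
        if np.linalg.norm(axis) < 1e-6:
            axis = np.array([0.0, 0.0, 1.0])
        axis = axis / np.linalg.norm(axis)
        # tilt the approach direction per attack point (deterministic grid)
        tilt = np.array([0.3 * trial.attack_index, 0.17 * trial.attack_index, 0.0])
        axis = axis + tilt
        axis /= np.linalg.norm(axis)
        # rotate B about the approach axis per rotamer
        theta = 2.0 * np.pi * trial.rotamer_index / max(1, 2)
        k = axis
        kx = np.array(
            [[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]]
        )
        rot = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)
        pb = b_xyz[trial.atom_b]
        b_xyz = (b_xyz - pb) @ rot.T
        b_xyz += pa + distance * axis
        elements = trial.structure_a.elements + trial.structure_b.elements
        return elements, np.vstack([a_xyz, b_xyz])

    def _point_energy(self, elements, coords, charge: int, multiplicity: int) -> CalcResult:
        from .molecule_io import Atom, MolGraph

        graph = MolGraph(
            atoms=tuple(Atom(element=el) for el in elements), bonds=(), total_charge=0
        )
        structure = Structure.__new__(Structure)  # bypass clash check on scan points
        object.__setattr__(structure, "graph", graph)
        object.__setattr__(structure, "elements", tuple(elements))
        object.__setattr__(structure, "coordinates", coords)
        object.__setattr__(structure, "charge", charge)
        object.__setattr__(structure, "multiplicity", multiplicity)
        object.__setattr__(structure, "d_min", 0.0)
        return self.energy(structure)

    def search_step(self, trial: Trial) -> StepSearchResult:
        """NT-style elementary-step search along a rigid approach coordinate.

        The two molecules are brought together so the forming pair traverses
        a fixed distance grid; the external program supplies a single-point
        energy at every scan point.  The highest point estimates the
        transition state, the final point the product; if the end geometry's
        perceived connectivity still equals the reactants', the trial is a
        dead end (``no_step``).  A missing executable is an actionable error,
        never a silent ``no_step``.
        """
        try:
            self._check_available()
        except BackendUnavailableError as exc:
            return StepSearchResult(outcome="error", message=str(exc))
        r_a = self.energy(trial.structure_a)
        r_b = self.energy(trial.structure_b)
        if not (r_a.converged and r_b.converged):
            return StepSearchResult(
                outcome="error",
                message=f"reactant energies failed: {r_a.message or r_b.message}",
            )
        e_react = r_a.energy + r_b.energy
        charge = trial.structure_a.charge + trial.structure_b.charge
        nelec_parity = (
            sum(_atomic_number(el) for el in trial.structure_a.elements)
            + sum(_atomic_number(el) for el in trial.structure_b.elements)
            - charge
        ) % 2
        multiplicity = 2 if nelec_parity else 1
        energies: list[float] = []
        last_geometry = None
        for d in self.scan_distances:
            elements, coords = self._supermolecule(trial, d)
            res = self._point_energy(elements, coords, charge, multiplicity)
            if not res.converged:
                return StepSearchResult(
                    outcome="error",
                    message=f"scan point at {d} Å failed: {res.message}",
                )
            energies.append(res.energy)
            last_geometry = (elements, coords)
        e_ts = max(e_react, max(energies))
        e_prod = energies[-1]
        elements, coords = last_geometry
        if not self._connectivity_changed(trial, elements, coords):
            return StepSearchResult(
                outcome="no_step", message="end-point connectivity unchanged"
            )
        product = self._perceive_structure(elements, coords, charge, multiplicity)
        if product is None:
            return StepSearchResult(
                outcome="error", message="could not perceive product connectivity"
            )
        step = ProposedStep(
            reactants=(trial.structure_a, trial.structure_b),
            products=(product,),
            e_react=e_react,
            e_ts=e_ts,
            e_prod=e_prod,
        )
        return StepSearchResult(outcome="step_found", step=step)

    @staticmethod
    def _perceive_graph(elements, coords):
        """Distance-based bond perception of a scan geometry (single bonds)."""
        from rdkit.Chem import rdDetermineBonds

        xyz_lines = [str(len(elements)), "scan end point"]
        for el, (x, y, z) in zip(elements, coords):
            xyz_lines.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
        mol = Chem.MolFromXYZBlock("\n".join(xyz_lines) + "\n")
        if mol is None:
            return None
        try:
            rdDetermineBonds.DetermineConnectivity(mol)
        except (ValueError, RuntimeError):
            return None
        return mol

    def _connectivity_changed(self, trial: Trial, elements, coords) -> bool:
        mol = self._perceive_graph(elements, coords)
        if mol is None:
            return False
        n_a = len(trial.structure_a.elements)
        intermolecular = sum(
            1
            for b in mol.GetBonds()
            if (b.GetBeginAtomIdx() < n_a) != (b.GetEndAtomIdx() < n_a)
        )
        return intermolecular > 0

    def _perceive_structure(self, elements, coords, charge, multiplicity):
        mol = self._perceive_graph(elements, coords)
        if mol is None:
            return None
        from .molecule_io import Atom, Bond, MolGraph

        atoms = tuple(Atom(element=a.GetSymbol()) for a in mol.GetAtoms())
        bonds = tuple(
            Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), 1) for b in mol.GetBonds()
        )
        graph = MolGraph(atoms=atoms, bonds=bonds, total_charge=0)
        structure = Structure.__new__(Structure)
        object.__setattr__(structure, "graph", graph)
        object.__setattr__(structure, "elements", tuple(elements))
        object.__setattr__(structure, "coordinates", coords)
        object.__setattr__(structure, "charge", charge)
        object.__setattr__(structure, "multiplicity", multiplicity)
        object.__setattr__(structure, "d_min", 0.0)
        return structure


_PT = Chem.GetPeriodicTable()


def _atomic_number(element: str) -> int:
    return _PT.GetAtomicNumber(element)
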