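"""Molecular input preparation: SMILES graphs, 3D structures, atom mappings.

A retrosynthesis model communicates in SMILES, which fixes connectivity and
formal charges but nothing a quantum-chemistry program needs: no Cartesian
coordinates, no spin multiplicity, and often no stereochemistry.  This module
bridges that gap.  It parses plain and atom-mapped SMILES into light-weight
connectivity graphs (:class:`MolGraph`), embeds sanitized 3D conformers
(:class:`Structure`) with clash repair so downstream electronic-structure
calculations do not start from overlapping nuclei, guesses spin multiplicities
by electron parity, enumerates unspecified stereocenters, and derives the set
of *changed atoms* from an atom-mapped reaction SMILES — the information that
later prunes reactive-trial enumeration.

RDKit does the chemistry-aware heavy lifting (parsing, aromaticity perception,
ETKDG conformer generation, stereoisomer enumeration, canonicalization); the
types here are deliberately minimal and serializable.
"""

from __future__ import annotations

import io
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from rdkit import Chem, rdBase
from rdkit.Chem import AllChem
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)

rdBase.DisableLog("rdApp.error")  # diagnostics are re-raised as exceptions
rdBase.DisableLog("rdApp.warning")

__all__ = [
    "Atom",
    "Bond",
    "MolGraph",
    "Structure",
    "AtomMapping",
    "SmilesParseError",
    "SanitizationError",
    "MappingError",
    "AROMATIC",
    "D_MIN_DEFAULT",
    "parse_smiles",
    "graph_from_rdkit",
    "graph_to_rdkit",
    "connectivity_key",
    "embed_3d",
    "enforce_min_distance",
    "guess_multiplicity",
    "electron_count",
    "enumerate_stereoisomers",
    "derive_mapping",
    "read_xyz",
    "write_xyz",
]

#: Bond-order token for aromatic bonds (kept distinct from Kekulé orders).
AROMATIC = "ar"

#: Default minimum allowed interatomic distance in Å after sanitization.
D_MIN_DEFAULT = 0.5

#: Default number of re-embedding attempts before giving up.
EMBED_RESTARTS_DEFAULT = 5

#: Cap on enumerated stereoisomers per molecule (2**6 unspecified elements).
STEREO_CAP_DEFAULT = 64

BondOrder = Union[int, str]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed.

    ``position`` is the 0-based index of the offending token where it can be
    determined (lexical errors); otherwise ``None`` with the parser's own
    diagnostic in the message.
    """

    def __init__(self, smiles: str, message: str, position: Optional[int] = None):
        self.smiles = smiles
        self.position = position
        loc = f" at position {position}" if position is not None else ""
        super().__init__(f"cannot parse SMILES {smiles!r}{loc}: {message}")


class SanitizationError(RuntimeError):
    """Raised when a 3D structure cannot be brought to a sane geometry."""


class MappingError(ValueError):
    """Raised for non-bijective or otherwise unusable atom maps."""


# --------------------------------------------------------------------------
# graph types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """One heavy atom: element, formal charge (e), attached H count, map index.

    ``chirality`` records a specified tetrahedral center ("CW"/"CCW" parity)
    so that stereoisomer enumeration leaves assigned centers untouched.
    """

    element: str
    formal_charge: int = 0
    n_h: int = 0
    map_index: Optional[int] = None
    chirality: Optional[str] = None


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: BondOrder  # 1, 2, 3 or AROMATIC
    stereo: Optional[str] = None  # specified double-bond geometry, if any
    stereo_atoms: Optional[tuple[int, int]] = None


@dataclass(frozen=True)
class MolGraph:
    """Hydrogen-suppressed molecular connectivity with formal charges.

    Hydrogens are implicit (per-atom counts in :attr:`Atom.n_h`); they become
    explicit only when a 3D :class:`Structure` is built.
    """

    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]
    total_charge: int = 0

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if b.i == b.j or not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) has invalid endpoints for {n} atoms")
        if sum(a.formal_charge for a in self.atoms) != self.total_charge:
            raise ValueError("total_charge does not equal the sum of formal charges")
        maps = [a.map_index for a in self.atoms if a.map_index is not None]
        if len(maps) != len(set(maps)):
            raise ValueError("duplicate atom-map indices within one molecule")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class Structure:
    """One 3D conformer: explicit-H elements, coordinates (Å), charge, 2S+1."""

    graph: MolGraph
    elements: tuple[str, ...]
    coordinates: np.ndarray  # shape (n, 3), Å
    charge: int
    multiplicity: int
    d_min: float = D_MIN_DEFAULT

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if coords.shape != (len(self.elements), 3):
            raise ValueError("coordinate array shape does not match element list")
        if len(self.elements) > 1 and min_pair_distance(coords) < self.d_min:
            raise SanitizationError(
                f"minimum interatomic distance below {self.d_min} Å"
            )
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be a positive integer")
        nelec = _electron_count_elements(self.elements, self.charge)
        if (nelec + self.multiplicity) % 2 != 1:
            raise ValueError(
                f"multiplicity {self.multiplicity} inconsistent with "
                f"{nelec} electrons (parity rule)"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class AtomMapping:
    """Atom-to-atom correspondence between the two sides of a reaction.

    ``changed_atoms`` holds the map indices whose chemical environment
    (incident bond multiset, H count, or formal charge) differs between the
    reactant and product side — the atoms actually taking part in the
    reaction.  ``formed_pairs``/``broken_pairs`` are the specific bonds (as
    unordered map-index pairs) created or removed, used to focus bimolecular
    trial generation on the bond that must form.
    """

    pairs: tuple[tuple[int, int], ...]
    changed_atoms: frozenset[int]
    formed_pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    broken_pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)


# --------------------------------------------------------------------------
# SMILES parsing
# --------------------------------------------------------------------------

# lexical token set of Daylight SMILES (bracket atoms, organic subset, bonds,
# ring closures, branches, dots)
_SMILES_TOKEN = re.compile(
    r"""\[[^\]]+\]          # bracket atom
      | Br | Cl             # two-letter organic subset
      | [BCNOPSFI]          # one-letter organic subset
      | [bcnops]            # aromatic subset
      | %\d\d | \d          # ring closures
      | [-=\#:/\\~\.\(\)@]  # bonds, branches, dot
    """,
    re.X,
)


def _first_bad_token(smiles: str) -> Optional[int]:
    """0-based position of the first lexically invalid character, if any."""
    pos = 0
    while pos < len(smiles):
        m = _SMILES_TOKEN.match(smiles, pos)
        if m is None:
            return pos
        pos = m.end()
    return None


def _capture_rdkit_errors() -> io.StringIO:
    rdBase.LogToPythonLogger()
    buf = io.StringIO()
    handler = logging.StreamHandler(buf)
    logger = logging.getLogger("rdkit")
    logger.addHandler(handler)
    logger.setLevel(logging.WARNING)
    buf._handler = handler  # type: ignore[attr-defined]
    return buf


def _release_rdkit_errors(buf: io.StringIO) -> str:
    logging.getLogger("rdkit").removeHandler(buf._handler)  # type: ignore[attr-defined]
    return buf.getvalue().strip() or "parse failure"


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    buf = _capture_rdkit_errors()
    mol = Chem.MolFromSmiles(smiles)
    diagnostic = _release_rdkit_errors(buf)
    if mol is None:
        raise SmilesParseError(smiles, diagnostic, position=_first_bad_token(smiles))
    return mol


_CHIRAL_TO_NAME = {
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: "CW",
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: "CCW",
}
_NAME_TO_CHIRAL = {v: k for k, v in _CHIRAL_TO_NAME.items()}


def graph_from_rdkit(mol: Chem.Mol) -> MolGraph:
    """Convert an RDKit molecule (implicit-H) to a :class:`MolGraph`."""
    atoms = tuple(
        Atom(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            n_h=a.GetTotalNumHs(),
            map_index=a.GetAtomMapNum() or None,
            chirality=_CHIRAL_TO_NAME.get(a.GetChiralTag()),
        )
        for a in mol.GetAtoms()
    )
    bonds = []
    for b in mol.GetBonds():
        if b.GetIsAromatic() or b.GetBondType() == Chem.BondType.AROMATIC:
            order: BondOrder = AROMATIC
        else:
            order = int(b.GetBondTypeAsDouble())
        stereo = b.GetStereo()
        stereo_name = None
        stereo_atoms: Optional[tuple[int, int]] = None
        if stereo != Chem.BondStereo.STEREONONE:
            stereo_name = stereo.name
            ref = list(b.GetStereoAtoms())
            if len(ref) == 2:
                stereo_atoms = (ref[0], ref[1])
        bonds.append(
            Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order,
                 stereo=stereo_name, stereo_atoms=stereo_atoms)
        )
    return MolGraph(atoms=atoms, bonds=tuple(bonds), total_charge=Chem.GetFormalCharge(mol))


def graph_to_rdkit(graph: MolGraph) -> Chem.Mol:
    """Rebuild an RDKit molecule from a :class:`MolGraph`."""
    em = Chem.RWMol()
    for atom in graph.atoms:
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.formal_charge)
        a.SetNumExplicitHs(atom.n_h)
        a.SetNoImplicit(True)
        if atom.map_index is not None:
            a.SetAtomMapNum(atom.map_index)
        if atom.chirality is not None:
            a.SetChiralTag(_NAME_TO_CHIRAL[atom.chirality])
        em.AddAtom(a)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                 3: Chem.BondType.TRIPLE, AROMATIC: Chem.BondType.AROMATIC}
    for bond in graph.bonds:
        em.AddBond(bond.i, bond.j, order_map[bond.order])
    mol = em.GetMol()
    for bond, rd_bond in zip(graph.bonds, mol.GetBonds()):
        if bond.stereo is not None and bond.stereo_atoms is not None:
            rd_bond.SetStereoAtoms(*bond.stereo_atoms)
            rd_bond.SetStereo(Chem.BondStereo.names[bond.stereo])
    Chem.SanitizeMol(mol)
    return mol


def parse_smiles(smiles: str) -> MolGraph:
    """Parse a (possibly atom-mapped) SMILES string into a :class:`MolGraph`.

    Aromaticity is perceived by RDKit's default model; the total charge is
    read from the string's bracket-atom charge tokens.

    Raises
    ------
    SmilesParseError
        On syntactic or chemical (valence, kekulization) failure, with the
        position of the offending token when it can be located lexically.
    """
    return graph_from_rdkit(_mol_from_smiles(smiles))


def connectivity_key(graph: MolGraph) -> str:
    """Canonical, stereochemistry-free SMILES used as a compound identity key.

    Two structures with the same key share connectivity and formal charges
    and therefore belong to the same compound; 3D information and atom-map
    indices are deliberately excluded.
    """
    mol = graph_to_rdkit(graph)
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol, isomericSmiles=False)


# --------------------------------------------------------------------------
# 3D embedding and sanitization
# --------------------------------------------------------------------------


def min_pair_distance(coords: np.ndarray) -> float:
    """Smallest pairwise distance in a coordinate array (Å)."""
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff * diff).sum(-1))
    n = len(coords)
    if n < 2:
        return np.inf
    return float(dist[np.triu_indices(n, k=1)].min())


def enforce_min_distance(
    coords: np.ndarray, d_min: float = D_MIN_DEFAULT, max_iter: int = 200
) -> np.ndarray:
    """Push clashing atom pairs apart until every distance is ≥ ``d_min``.

    Overlapping nuclei make electronic-structure calculations fail outright,
    so embedded geometries are repaired by symmetrically displacing the
    closest pair along its separation vector (a fixed axis if coincident).
    Deterministic; raises :class:`SanitizationError` if the geometry cannot
    be repaired within ``max_iter`` sweeps.
    """
    out = np.array(coords, dtype=float, copy=True)
    n = len(out)
    if n < 2:
        return out
    for _ in range(max_iter):
        diff = out[:, None, :] - out[None, :, :]
        dist = np.sqrt((diff * diff).sum(-1))
        iu = np.triu_indices(n, k=1)
        flat = dist[iu]
        k = int(np.argmin(flat))
        if flat[k] >= d_min:
            return out
        i, j = iu[0][k], iu[1][k]
        v = out[i] - out[j]
        norm = np.linalg.norm(v)
        direction = v / norm if norm > 1e-8 else np.array([1.0, 0.0, 0.0])
        push = 0.5 * (d_min - norm) * 1.05  # 5% overshoot to avoid stalls
        out[i] += push * direction
        out[j] -= push * direction
    raise SanitizationError(f"could not reach minimum distance {d_min} Å")


def embed_3d(
    graph: MolGraph,
    seed: int,
    d_min: float = D_MIN_DEFAULT,
    max_restarts: int = EMBED_RESTARTS_DEFAULT,
    multiplicity: Optional[int] = None,
) -> Structure:
    """Generate a sanitized 3D conformer for ``graph``.

    Hydrogens are made explicit, coordinates come from RDKit's ETKDG
    distance-geometry embedding (deterministic for a fixed ``seed``), and the
    resulting geometry is clash-repaired so that every interatomic distance
    is at least ``d_min``.  Up to ``max_restarts`` embeddings with derived
    seeds are attempted before a :class:`SanitizationError` is raised.
    """
    if graph.n_atoms < 1:
        raise ValueError("cannot embed an empty molecular graph")
    mol = Chem.AddHs(graph_to_rdkit(graph))
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    mult = multiplicity if multiplicity is not None else guess_multiplicity(graph)
    last_error: Optional[Exception] = None
    for attempt in range(max_restarts):
        params = AllChem.ETKDGv3()
        params.randomSeed = (seed + 7919 * attempt) % (2**31 - 1)
        if AllChem.EmbedMolecule(mol, params) != 0:
            # distance geometry can fail for tiny molecules; fall back to a
            # deterministic linear placement that the clash repair spreads out
            coords = np.zeros((mol.GetNumAtoms(), 3))
            coords[:, 0] = 1.2 * np.arange(mol.GetNumAtoms())
        else:
            coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
        try:
            coords = enforce_min_distance(coords, d_min)
            return Structure(
                graph=graph,
                elements=elements,
                coordinates=coords,
                charge=graph.total_charge,
                multiplicity=mult,
                d_min=d_min,
            )
        except SanitizationError as exc:  # retry with a new seed
            last_error = exc
    raise SanitizationError(
        f"embedding failed after {max_restarts} restarts: {last_error}"
    )


# --------------------------------------------------------------------------
# electrons, spin, stereochemistry
# --------------------------------------------------------------------------

_PT = Chem.GetPeriodicTable()


def _electron_count_elements(elements: Sequence[str], charge: int) -> int:
    return sum(_PT.GetAtomicNumber(el) for el in elements) - charge


def electron_count(graph: MolGraph) -> int:
    """Total electron count including implicit hydrogens, net of charge."""
    z = sum(_PT.GetAtomicNumber(a.element) + a.n_h for a in graph.atoms)
    return z - graph.total_charge


def guess_multiplicity(graph: MolGraph) -> int:
    """Crude spin-multiplicity guess by electron parity.

    Even electron count → singlet (1); odd → doublet (2).  This is the
    fast-and-crude limit of automated multiplicity guessing; a backend may
    override it (e.g. from an extended-Hückel analysis) through the
    ``multiplicity`` argument of :func:`embed_3d`.
    """
    return 1 if electron_count(graph) % 2 == 0 else 2


def enumerate_stereoisomers(
    graph: MolGraph, cap: int = STEREO_CAP_DEFAULT
) -> list[MolGraph]:
    """Enumerate assignments of unspecified stereocenters and double bonds.

    Specified stereo elements are left untouched; each unspecified
    tetrahedral center or double-bond geometry doubles the count, capped at
    ``cap`` to bound the downstream exploration cost.  A molecule with no
    stereo elements yields exactly itself.
    """
    mol = graph_to_rdkit(graph)
    opts = StereoEnumerationOptions(onlyUnassigned=True, unique=True, maxIsomers=cap)
    isomers = list(EnumerateStereoisomers(mol, options=opts))
    if not isomers:
        return [graph]
    return [graph_from_rdkit(m) for m in isomers]


# --------------------------------------------------------------------------
# atom mapping
# --------------------------------------------------------------------------


def _side_signatures(mol: Chem.Mol) -> tuple[dict[int, tuple], set[tuple[int, int]]]:
    """Per-map-index environment signatures and the set of mapped-bond pairs."""
    sigs: dict[int, tuple] = {}
    for atom in mol.GetAtoms():
        m = atom.GetAtomMapNum()
        if m <= 0:
            continue
        if m in sigs:
            raise MappingError(f"map index {m} appears twice on one side")
        incident = []
        for b in atom.GetBonds():
            other = b.GetOtherAtom(atom)
            key = other.GetAtomMapNum() if other.GetAtomMapNum() > 0 else other.GetSymbol()
            order = AROMATIC if b.GetIsAromatic() else int(b.GetBondTypeAsDouble())
            incident.append((key, order))
        sigs[m] = (
            atom.GetSymbol(),
            atom.GetFormalCharge(),
            atom.GetTotalNumHs(),
            tuple(sorted(incident, key=repr)),
        )
    bonds = set()
    for b in mol.GetBonds():
        mi, mj = b.GetBeginAtom().GetAtomMapNum(), b.GetEndAtom().GetAtomMapNum()
        if mi > 0 and mj > 0:
            bonds.add((min(mi, mj), max(mi, mj)))
    return sigs, bonds


def derive_mapping(mapped_reaction_smiles: str) -> AtomMapping:
    """Derive changed atoms and formed/broken bonds from a mapped reaction SMILES.

    The input follows the ``reactants>agents>products`` convention with
    ``:n`` atom-map indices on heavy atoms.  An atom is *changed* when its
    incident bond multiset, hydrogen count, or formal charge differs between
    the two sides; spectator moieties (e.g. an untouched phenyl ring) drop
    out.  The comparison is connectivity-only, so conformational change never
    marks an atom as changed, and it is symmetric under reaction reversal.
    """
    parts = mapped_reaction_smiles.split(">")
    if len(parts) != 3:
        raise MappingError("reaction SMILES must have the form reactants>agents>products")
    reactants = _mol_from_smiles(parts[0])
    products = _mol_from_smiles(parts[2])
    r_sigs, r_bonds = _side_signatures(reactants)
    p_sigs, p_bonds = _side_signatures(products)
    if not r_sigs or not p_sigs:
        raise MappingError("both sides must carry atom-map indices on heavy atoms")
    if set(r_sigs) != set(p_sigs):
        raise MappingError(
            "atom map is not a bijection: indices "
            f"{sorted(set(r_sigs) ^ set(p_sigs))} appear on one side only"
        )
    shared = sorted(r_sigs)
    changed = frozenset(m for m in shared if r_sigs[m] != p_sigs[m])
    return AtomMapping(
        pairs=tuple((m, m) for m in shared),
        changed_atoms=changed,
        formed_pairs=frozenset(p_bonds - r_bonds),
        broken_pairs=frozenset(r_bonds - p_bonds),
    )


# --------------------------------------------------------------------------
# XYZ I/O
# --------------------------------------------------------------------------


def write_xyz(
    path: Union[str, Path],
    elements: Sequence[str],
    coordinates: np.ndarray,
    comment: str = "",
) -> None:
    """Write a standard XYZ file (count line, comment line, element x y z)."""
    coords = np.asarray(coordinates, dtype=float)
    lines = [str(len(elements)), comment.replace("\n", " ")]
    for el, (x, y, z) in zip(elements, coords):
        lines.append(f"{el} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_xyz(path: Union[str, Path]) -> tuple[tuple[str, ...], np.ndarray, str]:
    """Read an XYZ file; returns (elements, coordinates in Å, comment)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"empty XYZ file: {path}")
    n = int(lines[0].strip())
    comment = lines[1] if len(lines) > 1 else ""
    elements: list[str] = []
    coords = np.zeros((n, 3))
    for k, line in enumerate(lines[2 : 2 + n]):
        fields = line.split()
        elements.append(fields[0])
        coords[k] = [float(v) for v in fields[1:4]]
    if len(elements) != n:
        raise ValueError(f"XYZ file declares {n} atoms but contains {len(elements)}")
    return tuple(elements), coords, comment
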