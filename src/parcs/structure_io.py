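"""Reading protein structures and assigning collision radii.

PDB input is parsed with :mod:`gemmi`; this module applies the selection
policy used throughout the package (first MODEL, max-occupancy altloc,
waters dropped, HETATM off by default) and flattens the hierarchy into a
plain :class:`StructureModel` of atoms with coordinates and elements.

For collision-cross-section work every atom carries a *combined* radius:
an effective atomic cross-sectional radius (1.91 Å for heavy atoms, 1.21 Å
for hydrogen) plus the buffer-gas probe radius (1.0 Å helium, 1.82 Å
nitrogen).  :func:`assign_radii` produces that per-atom radius vector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

HEAVY_ELEMENTS = frozenset({"C", "N", "O", "S", "P"})
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: Buffer gases with an effective probe radius (Å).
GASES = ("helium", "nitrogen")


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed into at least one atom."""


@dataclass(frozen=True)
class Atom:
    """A single atom retained after selection.

    ``residue_index`` is an ordinal over distinct (chain, residue) pairs in
    file order, starting at 0 — decoys and natives with the same sequence
    therefore pair by ordinal regardless of author numbering.
    """

    element: str
    coords: tuple[float, float, float]
    residue_index: int
    chain_id: str
    name: str = ""
    res_name: str = ""
    is_hetero: bool = False
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("atom element must be non-empty")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates {self.coords!r}")


@dataclass
class StructureModel:
    """An ordered collection of atoms plus residue bookkeeping."""

    atoms: list[Atom]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("StructureModel requires at least one atom")

    @property
    def n_residues(self) -> int:
        return len({(a.chain_id, a.residue_index) for a in self.atoms})

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) float array of coordinates in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def select(self, predicate) -> "StructureModel":
        kept = [a for a in self.atoms if predicate(a)]
        if not kept:
            raise ValueError("selection removed every atom")
        return StructureModel(kept, source_id=self.source_id)

    def heavy_only(self) -> "StructureModel":
        return self.select(lambda a: a.element != "H")

    def ca_coordinates(self) -> np.ndarray:
        """(n_res, 3) coordinates of Cα atoms in residue order."""
        cas = [a for a in self.atoms if a.name == "CA"]
        if not cas:
            raise ValueError("structure has no CA atoms")
        return np.array([a.coords for a in cas], dtype=float)

    def with_coordinates(self, xyz: np.ndarray, source_id: str | None = None) -> "StructureModel":
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"expected shape {(len(self.atoms), 3)}, got {xyz.shape}")
        atoms = [replace(a, coords=tuple(c)) for a, c in zip(self.atoms, xyz)]
        return StructureModel(atoms, source_id=self.source_id if source_id is None else source_id)


@dataclass(frozen=True)
class RadiusTable:
    """Effective cross-sectional radii (Å) for the projection approximation."""

    heavy_radius: float = 1.91
    hydrogen_radius: float = 1.21
    probe_radius_helium: float = 1.0
    probe_radius_nitrogen: float = 1.82
    fallback_radius: float = 1.91

    def __post_init__(self) -> None:
        for name in ("heavy_radius", "hydrogen_radius", "probe_radius_helium",
                     "probe_radius_nitrogen", "fallback_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def probe_radius(self, gas: str) -> float:
        if gas == "helium":
            return self.probe_radius_helium
        if gas == "nitrogen":
            return self.probe_radius_nitrogen
        raise ValueError(f"unknown buffer gas {gas!r}; valid gases: {', '.join(GASES)}")

    def atomic_radius(self, element: str) -> float:
        el = element.upper()
        if el == "H":
            return self.hydrogen_radius
        if el in HEAVY_ELEMENTS:
            return self.heavy_radius
        warnings.warn(
            f"element {element!r} has no tabulated radius; "
            f"using fallback {self.fallback_radius} Å",
            stacklevel=3,
        )
        return self.fallback_radius


@dataclass(frozen=True)
class SelectionPolicy:
    """What to keep when flattening a PDB file."""

    heavy_only: bool = False
    keep_het: bool = False
    chain: str | None = None


def _validate_fixed_columns(path: Path) -> None:
    # gemmi tolerates garbage in the coordinate columns (it reads them as 0),
    # so scan ATOM/HETATM records up front and fail loudly with a line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"{path}: line {lineno}: truncated atom record")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"{path}: line {lineno}: unparseable {what} coordinate "
                        f"{line[lo:hi].strip()!r}"
                    ) from None


def read_pdb(path: str | Path, policy: SelectionPolicy | None = None) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Only the first MODEL is used.  Altloc duplicates are resolved by highest
    occupancy (ties: first encountered).  Waters are always dropped; other
    HETATM groups are dropped unless ``policy.keep_het``.
    """
    policy = policy or SelectionPolicy()
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    _validate_fixed_columns(path)

    structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    structure.setup_entities()
    if len(structure) == 0:
        raise PDBParseError(f"{path}: no ATOM records")
    model = structure[0]

    atoms: list[Atom] = []
    residue_ordinal = -1
    for chain in model:
        if policy.chain is not None and chain.name != policy.chain:
            continue
        for residue in chain:
            if residue.name in WATER_NAMES:
                continue
            is_het = residue.het_flag == "H"
            if is_het and not policy.keep_het:
                continue
            # altloc resolution: best occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            for at in residue:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            kept = [at for at in residue if best[at.name] is at]
            if not kept:
                continue
            residue_ordinal += 1
            for at in kept:
                element = (at.element.name.upper() if at.element.name
                           else _element_from_name(at.name))
                if policy.heavy_only and element.upper() == "H":
                    continue
                atoms.append(Atom(
                    element=element,
                    coords=(at.pos.x, at.pos.y, at.pos.z),
                    residue_index=residue_ordinal,
                    chain_id=chain.name or "A",
                    name=at.name,
                    res_name=residue.name,
                    is_hetero=is_het,
                    occupancy=at.occ,
                    altloc=at.altloc if at.altloc != "\0" else "",
                ))
    if not atoms:
        raise PDBParseError(f"{path}: no ATOM records after selection")
    return StructureModel(atoms, source_id=path.stem)


def _element_from_name(atom_name: str) -> str:
    stripped = atom_name.strip()
    if not stripped:
        raise PDBParseError("atom with empty name and no element field")
    # PDB convention: element right-justified in the name columns; digits lead
    # hydrogens like "1HB2".
    core = stripped.lstrip("0123456789")
    if core[:1].upper() == "H":
        return "H"
    return core[:1].upper()


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel back out as a minimal single-MODEL PDB file."""
    # gemmi's add_residue/add_chain copy their argument, so containers must
    # be fully populated before insertion (bottom-up assembly)
    groups: dict[str, dict[int, list[Atom]]] = {}
    for atom in model.atoms:
        groups.setdefault(atom.chain_id, {}).setdefault(atom.residue_index,
                                                        []).append(atom)
    st = gemmi.Structure()
    st.name = model.source_id or "model"
    gm = gemmi.Model("1")
    serial = 0
    for chain_id, residues in groups.items():
        chain = gemmi.Chain(chain_id)
        for res_index in sorted(residues):
            residue = gemmi.Residue()
            residue.name = residues[res_index][0].res_name or "UNK"
            residue.seqid = gemmi.SeqId(res_index + 1, " ")
            residue.het_flag = "H" if residues[res_index][0].is_hetero else "A"
            for atom in residues[res_index]:
                serial += 1
                ga = gemmi.Atom()
                ga.name = atom.name or atom.element
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.serial = serial
                residue.add_atom(ga)
            chain.add_residue(residue)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def assign_radii(
    model: StructureModel,
    gas: str = "nitrogen",
    table: RadiusTable | None = None,
) -> np.ndarray:
    """Per-atom combined radius (atomic + buffer-gas probe) in Å.

    A pure function of element and gas: permuting atoms permutes the output.
    """
    table = table or RadiusTable()
    probe = table.probe_radius(gas)
    return np.array([table.atomic_radius(a.element) + probe for a in model.atoms])
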