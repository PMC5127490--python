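"""Reference structures: PDB input and coarse-graining.

A :class:`Structure` is an ordered list of "moieties" — interaction sites
that may be heavy atoms, backbone beads, or single C-alpha beads depending
on the resolution of the model.  All coordinates are stored in nanometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Moiety",
    "Structure",
    "StructureError",
    "read_structure",
    "coarse_grain",
]

# PDB element symbols treated as hydrogen when filtering.
_HYDROGEN = {"H", "D"}

RESOLUTION_HEAVY = "heavy-atom"
RESOLUTION_CA = "ca"


class StructureError(ValueError):
    """Raised for unusable structural input (missing chain, missing CA...)."""


@dataclass(frozen=True)
class Moiety:
    """One interaction site of a structure."""

    moiety_id: int
    residue_index: int          # 1-based, as in the source file
    name: str                   # atom name, e.g. "CA", "CB"
    element: str


@dataclass
class Structure:
    """Ordered moieties plus an (n, 3) coordinate array in nm."""

    moieties: list[Moiety]
    coords: np.ndarray
    resolution: str = RESOLUTION_HEAVY
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.moieties), 3):
            raise StructureError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{len(self.moieties)} moieties"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        res = self.residue_indices
        if len(res) and np.any(np.diff(res) < 0):
            raise StructureError("residue indices must be non-decreasing")

    @property
    def n_moieties(self) -> int:
        return len(self.moieties)

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([m.residue_index for m in self.moieties], dtype=int)

    @property
    def residues(self) -> np.ndarray:
        """Sorted unique residue indices."""
        return np.unique(self.residue_indices)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Same topology, new coordinates."""
        return Structure(self.moieties, np.asarray(coords, dtype=float),
                         resolution=self.resolution, label=self.label)


def read_structure(path, chain: str, model: int = 0) -> Structure:
    """Read one chain of a PDB file into a heavy-atom :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by altloc label order, so 'A' wins).  Hydrogens are
    excluded.  Insertion codes are rejected: silently renumbering residues
    would corrupt downstream strand assignments.

    Parameters
    ----------
    path : str or Path
        PDB file.
    chain : str
        Chain identifier that must be present in the file.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    pdb = parser.get_structure("s", str(path))
    models = list(pdb)
    if model >= len(models):
        raise StructureError(f"model {model} not present ({len(models)} models)")
    mdl = models[model]
    chain_ids = [c.id for c in mdl]
    if chain not in chain_ids:
        raise StructureError(f"chain {chain!r} not found; available: {chain_ids}")
    ch = mdl[chain]

    moieties: list[Moiety] = []
    coords: list[np.ndarray] = []
    missing_ca: list[int] = []
    mid = 0
    for residue in ch:
        hetflag, resseq, icode = residue.id
        if hetflag.strip():
            continue  # waters / heteroatoms are not part of the chain
        if icode.strip():
            raise StructureError(
                f"insertion code {icode!r} at residue {resseq}: renumber the "
                "file explicitly before use"
            )
        # resolve altlocs per atom name by highest occupancy, label order
        by_name: dict[str, list] = {}
        for atom in residue.get_unpacked_list():
            if (atom.element or "").upper() in _HYDROGEN:
                continue
            by_name.setdefault(atom.get_name(), []).append(atom)
        if "CA" not in by_name:
            missing_ca.append(resseq)
        for name in by_name:
            atoms = by_name[name]
            atoms.sort(key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))
            best = atoms[0]
            moieties.append(
                Moiety(mid, resseq, name, (best.element or "").upper())
            )
            coords.append(best.get_coord() / 10.0)  # A -> nm
            mid += 1
    if missing_ca:
        raise StructureError(f"residues missing CA atoms: {missing_ca}")
    if not moieties:
        raise StructureError(f"chain {chain!r} contains no polymer residues")
    return Structure(moieties, np.array(coords), resolution=RESOLUTION_HEAVY,
                     label=f"{path}:{chain}")


def coarse_grain(structure: Structure, resolution: str) -> Structure:
    """Project a structure to the requested resolution.

    ``heavy-atom`` keeps all non-hydrogen sites; ``ca`` keeps one bead per
    residue at the C-alpha position.
    """
    if resolution not in (RESOLUTION_HEAVY, RESOLUTION_CA):
        raise ValueError(f"unknown resolution {resolution!r}")
    if resolution == structure.resolution:
        return structure
    if resolution == RESOLUTION_HEAVY:
        if structure.resolution == RESOLUTION_CA:
            raise StructureError("cannot recover heavy atoms from a CA structure")
        keep = [i for i, m in enumerate(structure.moieties)
                if m.element not in _HYDROGEN]
        moieties = [Moiety(k, structure.moieties[i].residue_index,
                           structure.moieties[i].name,
                           structure.moieties[i].element)
                    for k, i in enumerate(keep)]
        return Structure(moieties, structure.coords[keep],
                         resolution=RESOLUTION_HEAVY, label=structure.label)
    # -> CA
    moieties: list[Moiety] = []
    coords: list[np.ndarray] = []
    missing: list[int] = []
    for res in structure.residues:
        sel = [i for i, m in enumerate(structure.moieties)
               if m.residue_index == res and m.name == "CA"]
        if not sel:
            missing.append(int(res))
            continue
        i = sel[0]
        moieties.append(Moiety(len(moieties), int(res), "CA", "C"))
        coords.append(structure.coords[i])
    if missing:
        raise StructureError(f"residues missing CA atoms: {missing}")
    return Structure(moieties, np.array(coords), resolution=RESOLUTION_CA,
                     label=structure.label)


def ca_structure_from_coords(coords: np.ndarray, label: str = "") -> Structure:
    """Build a CA-resolution structure from an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    moieties = [Moiety(i, i + 1, "CA", "C") for i in range(len(coords))]
    return Structure(moieties, coords, resolution=RESOLUTION_CA, label=label)
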