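"""Quantum-cluster carving of the ion-binding pocket.

For cluster-model DFT energetics the pocket is reduced to the residues
whose backbone or side-chain oxygens sit within the Na+ hydration radius
(2.5 Å) of a bound ion, plus their sequence neighbours, together with
the three ions and the waters within 5 Å of them.  Residues enter whole;
only peptide bonds are cut, and every severed bond is terminated with a
hydrogen placed 1.09 Å along the severed-bond vector.  Alpha carbons are
frozen during optimisation, and the model's net charge follows from the
ion count and the number of deprotonated acidic side chains included.

A single-ion water shell (default radius 9 Å) provides the hydration
reference model of comparable size.

Structures are handled as Biotite ``AtomArray`` objects; decks are
emitted as an XYZ coordinate file plus a plain-text, engine-agnostic
input listing charge, multiplicity, frozen atoms and method keywords.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .states import ProtonationState, ResidueKey
from .trajectory import ION_NAMES, WATER_RESNAMES

__all__ = [
    "ClusterAtom",
    "ClusterModel",
    "WaterShellModel",
    "QMSettings",
    "CarveError",
    "CAP_BOND_LENGTH",
    "load_structure_pdb",
    "ion_mask",
    "water_mask",
    "select_cluster_residues",
    "carve_cluster",
    "cluster_to_structure",
    "extract_water_shell",
    "write_qm_deck",
]

logger = logging.getLogger(__name__)

#: Cap-hydrogen bond length in Å (standard C-H / N-H geometry).
CAP_BOND_LENGTH = 1.09

ACIDIC_RESNAMES = frozenset({"GLU", "ASP"})


class CarveError(ValueError):
    """Structure lacks atoms needed to carve the requested model."""


@dataclass(frozen=True)
class ClusterAtom:
    element: str
    coord: tuple[float, float, float]
    source: str  # residue | ion | water | cap
    label: str = ""


@dataclass
class ClusterModel:
    """Carved pocket model ready for QM deck emission."""

    atoms: list[ClusterAtom]
    residues: list[ResidueKey]
    frozen_atom_ids: list[int]  # 0-based indices into atoms (alpha carbons)
    net_charge: int
    multiplicity: int = 1

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def cap_count(self) -> int:
        return sum(1 for a in self.atoms if a.source == "cap")


@dataclass
class WaterShellModel:
    """A single ion with its surrounding water shell."""

    ion_position: tuple[float, float, float]
    waters: list[list[ClusterAtom]]  # whole molecules
    radius: float
    net_charge: int = 1
    multiplicity: int = 1

    @property
    def n_waters(self) -> int:
        return len(self.waters)

    @property
    def atoms(self) -> list[ClusterAtom]:
        out = [ClusterAtom("Na", self.ion_position, "ion", "NA")]
        for mol in self.waters:
            out.extend(mol)
        return out

    @property
    def frozen_atom_ids(self) -> list[int]:
        return []

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class QMSettings:
    method: str = "B3LYP"
    basis: str = "6-31G**"
    dispersion: str = "GD3"
    extra_keywords: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# structure helpers

def load_structure_pdb(path) -> struc.AtomArray:
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    if (atoms.element == "").any():
        atoms.element = struc.infer_elements(atoms)
    return atoms


def ion_mask(atoms: struc.AtomArray) -> np.ndarray:
    names = np.char.upper(atoms.atom_name.astype(str))
    resn = np.char.upper(atoms.res_name.astype(str))
    return (np.isin(names, list(ION_NAMES)) | np.isin(resn, list(ION_NAMES))
            | (np.char.upper(atoms.element.astype(str)) == "NA"))


def water_mask(atoms: struc.AtomArray) -> np.ndarray:
    return np.isin(np.char.upper(atoms.res_name.astype(str)),
                   list(WATER_RESNAMES))


def _residue_key(atoms: struc.AtomArray, i: int) -> ResidueKey:
    chain = str(atoms.chain_id[i]) or "A"
    return ResidueKey(chain, int(atoms.res_id[i]), str(atoms.res_name[i]).upper())


def _protein_mask(atoms: struc.AtomArray) -> np.ndarray:
    return ~(ion_mask(atoms) | water_mask(atoms))


def _atoms_of(atoms: struc.AtomArray, key: ResidueKey) -> np.ndarray:
    return np.flatnonzero((atoms.chain_id == key.chain_id)
                          & (atoms.res_id == key.residue_number)
                          & (np.char.upper(atoms.res_name.astype(str))
                             == key.residue_name))


def _residue_exists(atoms: struc.AtomArray, chain: str, num: int) -> bool:
    return bool(np.any((atoms.chain_id == chain) & (atoms.res_id == num)
                       & _protein_mask(atoms)))


# ---------------------------------------------------------------------------
# residue selection

def select_cluster_residues(structure: struc.AtomArray,
                            hydration_radius: float = 2.5
                            ) -> list[ResidueKey]:
    """Pocket residues: any O atom within the Na+ hydration radius of an
    ion, plus residues sequence-adjacent (±1, same chain) to those.

    Returns keys ordered by chain then residue number; empty (with a
    logged warning) when nothing qualifies.
    """
    if hydration_radius <= 0:
        raise ValueError("hydration_radius must be positive")
    ions = structure.coord[ion_mask(structure)]
    if ions.shape[0] == 0:
        raise CarveError("structure contains no ions")
    prot = _protein_mask(structure)
    is_oxygen = np.char.upper(structure.element.astype(str)) == "O"
    cand = np.flatnonzero(prot & is_oxygen)
    if cand.size:
        d = np.linalg.norm(structure.coord[cand][:, None, :]
                           - ions[None, :, :], axis=2)
        hits = cand[(d <= hydration_radius).any(axis=1)]
    else:
        hits = np.array([], dtype=int)

    core = {_residue_key(structure, int(i)) for i in hits}
    selected = set(core)
    for key in core:
        for num in (key.residue_number - 1, key.residue_number + 1):
            idx = np.flatnonzero((structure.chain_id == key.chain_id)
                                 & (structure.res_id == num)
                                 & _protein_mask(structure))
            if idx.size:
                selected.add(_residue_key(structure, int(idx[0])))
    if not selected:
        logger.warning("select_cluster_residues: no residue within "
                       f"{hydration_radius} Å of any ion")
    return sorted(selected, key=lambda k: (k.chain_id, k.residue_number))


# ---------------------------------------------------------------------------
# carving

def _formal_deprotonated_count(residues: Sequence[ResidueKey],
                               protonation: ProtonationState) -> int:
    n = 0
    for key in residues:
        if key.residue_name in ACIDIC_RESNAMES:
            if not protonation.flags.get(key, False):
                n += 1
    return n


def carve_cluster(structure: struc.AtomArray,
                  residues: Sequence[ResidueKey],
                  protonation: ProtonationState,
                  water_cutoff: float = 5.0,
                  extra_formal_charge: int = 0,
                  multiplicity: int = 1) -> ClusterModel:
    """Carve the pocket model: listed residues + ions + nearby waters.

    Every severed peptide bond (a listed residue whose sequence
    neighbour exists in the structure but is not listed) is capped with
    a hydrogen at 1.09 Å along the severed-bond vector.  All alpha
    carbons are frozen.  Net charge = +1 per ion − 1 per deprotonated
    Glu/Asp included, plus *extra_formal_charge*.
    """
    if water_cutoff <= 0:
        raise ValueError("water_cutoff must be positive")
    atoms: list[ClusterAtom] = []
    frozen: list[int] = []
    included = {(k.chain_id, k.residue_number) for k in residues}

    for key in residues:
        idx = _atoms_of(structure, key)
        if idx.size == 0:
            raise CarveError(f"residue {key} missing from structure")
        names = {str(structure.atom_name[i]).upper(): int(i) for i in idx}
        for i in idx:
            el = str(structure.element[i]).capitalize()
            a = ClusterAtom(el, tuple(np.round(structure.coord[i], 6)),
                            "residue", f"{key}:{structure.atom_name[i]}")
            if str(structure.atom_name[i]).upper() == "CA":
                frozen.append(len(atoms))
            atoms.append(a)
        # cap severed peptide bonds at this residue's N and C termini
        for neighbour, anchor_name, partner_name in (
                (key.residue_number - 1, "N", "C"),
                (key.residue_number + 1, "C", "N")):
            if (key.chain_id, neighbour) in included:
                continue
            if not _residue_exists(structure, key.chain_id, neighbour):
                continue  # true chain terminus: nothing severed
            if anchor_name not in names:
                continue
            partner_idx = np.flatnonzero(
                (structure.chain_id == key.chain_id)
                & (structure.res_id == neighbour)
                & (np.char.upper(structure.atom_name.astype(str))
                   == partner_name))
            if partner_idx.size == 0:
                continue
            anchor = structure.coord[names[anchor_name]]
            partner = structure.coord[int(partner_idx[0])]
            vec = partner - anchor
            norm = np.linalg.norm(vec)
            if norm == 0:
                raise CarveError(f"degenerate severed bond at {key}")
            cap = anchor + CAP_BOND_LENGTH * vec / norm
            atoms.append(ClusterAtom("H", tuple(np.round(cap, 6)), "cap",
                                     f"{key}:cap{anchor_name}"))

    ions_idx = np.flatnonzero(ion_mask(structure))
    for i in ions_idx:
        atoms.append(ClusterAtom("Na", tuple(np.round(structure.coord[i], 6)),
                                 "ion", f"ion:{structure.res_id[i]}"))

    # whole water molecules whose oxygen lies within cutoff of any ion
    wmask = water_mask(structure)
    ion_coords = structure.coord[ions_idx]
    water_res = sorted({(str(structure.chain_id[i]), int(structure.res_id[i]))
                        for i in np.flatnonzero(wmask)})
    for chain, rid in water_res:
        widx = np.flatnonzero((structure.chain_id == chain)
                              & (structure.res_id == rid) & wmask)
        oidx = [i for i in widx
                if str(structure.element[i]).upper() == "O"]
        if not oidx:
            continue
        d = np.linalg.norm(ion_coords - structure.coord[oidx[0]], axis=1)
        if ion_coords.shape[0] and d.min() <= water_cutoff:
            for i in widx:
                el = str(structure.element[i]).capitalize()
                atoms.append(ClusterAtom(el,
                                         tuple(np.round(structure.coord[i], 6)),
                                         "water", f"HOH:{rid}:{structure.atom_name[i]}"))

    net_charge = (int(ions_idx.size)
                  - _formal_deprotonated_count(residues, protonation)
                  + extra_formal_charge)
    return ClusterModel(atoms=atoms, residues=list(residues),
                        frozen_atom_ids=frozen, net_charge=net_charge,
                        multiplicity=multiplicity)


def cluster_to_structure(model: ClusterModel) -> struc.AtomArray:
    """Re-express a carved model as an AtomArray (caps ride along as H).

    Enables the idempotence check: carving the carved structure again
    with the same residue list adds no atoms, since severed-bond
    partners are no longer present.
    """
    n = model.n_atoms
    arr = struc.AtomArray(n)
    chain_of = {k.residue_number: k.chain_id for k in model.residues}
    for i, a in enumerate(model.atoms):
        parts = a.label.split(":")
        if a.source in ("residue", "cap"):
            resname = parts[0][:3]
            resnum = int("".join(ch for ch in parts[0] if ch.isdigit()))
            chain = chain_of.get(resnum, "A")
            name = parts[-1] if a.source == "residue" else "HC"
        elif a.source == "ion":
            resname, resnum, chain, name = "SOD", int(parts[1]), "W", "NA"
        else:
            resname, resnum, chain, name = "HOH", int(parts[1]), "W", parts[-1]
        arr.chain_id[i] = chain
        arr.res_id[i] = resnum
        arr.res_name[i] = resname
        arr.atom_name[i] = name
        arr.element[i] = a.element.upper()
        arr.coord[i] = a.coord
    return arr


def extract_water_shell(structure: struc.AtomArray, radius: float = 9.0,
                        ion_index: Optional[int] = None) -> WaterShellModel:
    """Whole water molecules whose oxygen lies within *radius* of the ion.

    With several ions present, *ion_index* picks one (0-based among the
    ions); a lone ion is used automatically.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    ions_idx = np.flatnonzero(ion_mask(structure))
    if ions_idx.size == 0:
        raise CarveError("structure contains no ion")
    if ions_idx.size > 1 and ion_index is None:
        raise CarveError("several ions present; pass ion_index")
    ion_i = int(ions_idx[ion_index or 0])
    center = structure.coord[ion_i]

    wmask = water_mask(structure)
    waters: list[list[ClusterAtom]] = []
    water_res = sorted({(str(structure.chain_id[i]), int(structure.res_id[i]))
                        for i in np.flatnonzero(wmask)})
    for chain, rid in water_res:
        widx = np.flatnonzero((structure.chain_id == chain)
                              & (structure.res_id == rid) & wmask)
        oidx = [i for i in widx if str(structure.element[i]).upper() == "O"]
        if not oidx:
            continue
        if np.linalg.norm(structure.coord[oidx[0]] - center) <= radius:
            waters.append([ClusterAtom(str(structure.element[i]).capitalize(),
                                       tuple(np.round(structure.coord[i], 6)),
                                       "water", f"HOH:{rid}:{structure.atom_name[i]}")
                           for i in widx])
    return WaterShellModel(ion_position=tuple(np.round(center, 6)),
                           waters=waters, radius=radius)


# ---------------------------------------------------------------------------
# deck emission

def write_qm_deck(model, settings: QMSettings = QMSettings(),
                  name: str = "cluster",
                  out_dir=None) -> tuple[str, str]:
    """Emit an XYZ coordinates file and a plain-text QM input deck.

    Output is byte-stable for identical inputs: fixed float formatting,
    no timestamps.  Returns ``(deck_text, xyz_text)``; files are written
    when *out_dir* is given (``<name>.xyz``, ``<name>.deck``).
    """
    atoms = model.atoms
    if not atoms:
        raise CarveError("model has no atoms")
    charge = getattr(model, "net_charge", None)
    if charge is None:
        raise CarveError("model net charge is unset")
    coords = np.array([a.coord for a in atoms], dtype=float)
    if not np.all(np.isfinite(coords)):
        raise CarveError("model has non-finite coordinates")

    xyz_lines = [str(len(atoms)), f"{name} carved model"]
    for a in atoms:
        x, y, z = a.coord
        xyz_lines.append(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    xyz_text = "\n".join(xyz_lines) + "\n"

    frozen = [i + 1 for i in model.frozen_atom_ids]  # 1-based for the deck
    deck_lines = [
        f"! {settings.method} {settings.basis} {settings.dispersion}".rstrip(),
        *(f"! {kw}" for kw in settings.extra_keywords),
        f"charge {charge}",
        f"multiplicity {model.multiplicity}",
        f"natoms {len(atoms)}",
        f"geometry {name}.xyz",
        "frozen " + (" ".join(map(str, frozen)) if frozen else "none"),
    ]
    deck_text = "\n".join(deck_lines) + "\n"

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"{name}.xyz").write_text(xyz_text)
        (out_dir / f"{name}.deck").write_text(deck_text)
    return deck_text, xyz_text
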