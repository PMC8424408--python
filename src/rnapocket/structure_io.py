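"""Reading and writing RNA (and RNA–ligand) structures.

Structures arrive as PDB or mmCIF files.  Parsing is delegated to gemmi;
this module flattens the hierarchy into :class:`AtomRecord` lists, separates
the RNA polymer from hetero content (ligands, waters, ions), and assigns
van der Waals radii so that downstream voxelization can build the molecular
surface.

Only single-stranded RNA is modelled: polymer residues are the four standard
nucleotides A, C, G, U.  Non-RNA polymer chains (e.g. protein) are ignored.
For multi-model (NMR-style) files the first model is used unless another is
requested explicitly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "MolecularModel",
    "FormatError",
    "EmptyModelError",
    "NoLigandError",
    "read_structure",
    "select_ligand",
    "write_pdb",
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "ION_RESNAMES",
    "WATER_RESNAMES",
]

#: Bondi-style van der Waals radii in Å, keyed by element symbol.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "H": 1.20,
}
#: Fallback radius (Å) for elements missing from :data:`VDW_RADII`.
DEFAULT_VDW_RADIUS: float = 1.70

#: Monoatomic ions excluded from both the polymer and the ligand by default.
ION_RESNAMES: frozenset[str] = frozenset(
    {"MG", "NA", "K", "CL", "ZN", "MN", "CA", "SR", "CS", "BR", "IOD"}
)
WATER_RESNAMES: frozenset[str] = frozenset({"HOH", "WAT", "DOD"})
RNA_RESNAMES: frozenset[str] = frozenset({"A", "C", "G", "U"})


class FormatError(ValueError):
    """The input file could not be parsed as PDB or mmCIF."""


class EmptyModelError(ValueError):
    """The selected model contains no RNA polymer nucleotides."""


class NoLigandError(ValueError):
    """No hetero residue qualifies as a ligand after exclusions."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom site with resolved element and van der Waals radius."""

    serial: int
    element: str
    atom_name: str
    coords: np.ndarray  # shape (3,), Å
    residue_name: str
    residue_index: int  # author numbering
    chain_id: str
    is_hetero: bool
    vdw_radius: float

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if not self.vdw_radius > 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be > 0")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class MolecularModel:
    """An RNA chain (plus any designated ligand) ready for analysis.

    ``sequence`` holds one letter per distinct polymer residue, in file
    order; ``ligand_atoms`` is a subset of ``atoms`` and never contains
    water or atoms from the configured ion list.
    """

    atoms: list[AtomRecord]
    sequence: str
    ligand_atoms: list[AtomRecord] = field(default_factory=list)
    model_index: int = 1
    name: str = "model"

    def __post_init__(self) -> None:
        n_res = len(self.polymer_residues())
        if len(self.sequence) != n_res:
            raise ValueError(
                f"sequence length {len(self.sequence)} != {n_res} polymer residues"
            )

    # -- selections -------------------------------------------------------

    @property
    def polymer_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hetero]

    def polymer_residues(self) -> list[tuple[str, int, str]]:
        """Distinct polymer residues as (chain_id, residue_index, name), in order."""
        seen: list[tuple[str, int, str]] = []
        prev = None
        for a in self.atoms:
            if a.is_hetero:
                continue
            key = (a.chain_id, a.residue_index, a.residue_name)
            if key != prev:
                seen.append(key)
                prev = key
        return seen

    def heavy_polymer_atoms(self) -> list[AtomRecord]:
        return [a for a in self.polymer_atoms if not a.is_hydrogen]

    def heavy_ligand_atoms(self) -> list[AtomRecord]:
        return [a for a in self.ligand_atoms if not a.is_hydrogen]

    def coords_of(self, atoms: Sequence[AtomRecord]) -> np.ndarray:
        if not atoms:
            return np.empty((0, 3))
        return np.stack([a.coords for a in atoms])

    def without_ligand(self) -> "MolecularModel":
        """Polymer-only copy (pockets are a property of the RNA alone)."""
        return dataclasses.replace(
            self, atoms=list(self.polymer_atoms), ligand_atoms=[]
        )


def _resolve_element(atom: gemmi.Atom) -> str:
    el = atom.element.name
    if el and el not in ("X", ""):
        return el
    # fall back to leading alphabetic characters of the atom name
    name = atom.name.strip()
    if name[:1].upper() in VDW_RADII:
        return name[:1].upper()
    raise FormatError(f"cannot resolve element for atom {atom.name!r}")


def vdw_radius(element: str) -> float:
    """Van der Waals radius for ``element`` (Å); total over all elements."""
    return VDW_RADII.get(element, DEFAULT_VDW_RADIUS)


def _pick_altloc(atoms: Iterable[gemmi.Atom]) -> list[gemmi.Atom]:
    """Resolve alternate locations: highest occupancy, ties alphabetical."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for at in atoms:
        by_name.setdefault(at.name, []).append(at)
    picked = []
    for name, group in by_name.items():
        if len(group) == 1:
            picked.append(group[0])
        else:
            picked.append(min(group, key=lambda a: (-a.occ, a.altloc or "~")))
    return picked


def read_structure(
    path: str | Path,
    model_choice: int = 1,
    ion_resnames: frozenset[str] = ION_RESNAMES,
) -> MolecularModel:
    """Read a PDB or mmCIF file into a :class:`MolecularModel`.

    Parameters
    ----------
    path:
        Input file; the format is detected from content/extension.
    model_choice:
        1-based model number.  NMR ensembles default to the first model.
    ion_resnames:
        Residue names treated as ions (neither polymer nor ligand).

    Raises
    ------
    FormatError
        If the file cannot be parsed.
    EmptyModelError
        If no RNA nucleotide is present in the chosen model.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models found")

    model = None
    for m in st:
        if m.num == model_choice:
            model = m
            break
    if model is None:
        if model_choice == 1:
            model = st[0]
        else:
            raise FormatError(f"{path}: model {model_choice} not present")

    atoms: list[AtomRecord] = []
    ligand_atoms: list[AtomRecord] = []
    sequence: list[str] = []
    serial = 0
    for chain in model:
        for res in chain:
            rname = res.name.strip().upper()
            is_rna = rname in RNA_RESNAMES
            is_water = rname in WATER_RESNAMES
            is_ion = rname in ion_resnames
            is_het = not is_rna
            if is_rna:
                sequence.append(rname)
            for at in _pick_altloc(res):
                serial += 1
                rec = AtomRecord(
                    serial=serial,
                    element=_resolve_element(at),
                    atom_name=at.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    residue_name=rname,
                    residue_index=res.seqid.num,
                    chain_id=chain.name,
                    is_hetero=is_het,
                    vdw_radius=vdw_radius(_resolve_element(at)),
                )
                atoms.append(rec)
                if is_het and not is_water and not is_ion:
                    ligand_atoms.append(rec)

    if not sequence:
        raise EmptyModelError(f"{path}: no RNA polymer nucleotides in model")
    return MolecularModel(
        atoms=atoms,
        sequence="".join(sequence),
        ligand_atoms=ligand_atoms,
        model_index=model.num,
        name=path.stem,
    )


def select_ligand(
    model: MolecularModel,
    resname: str = "auto",
    ion_resnames: frozenset[str] = ION_RESNAMES,
) -> MolecularModel:
    """Narrow ``ligand_atoms`` to one ligand species.

    ``"auto"`` picks the hetero residue (a single residue instance) with the
    most heavy atoms after excluding water and ions; an explicit residue name
    selects every matching hetero residue (all copies).
    """
    candidates: dict[tuple[str, int, str], list[AtomRecord]] = {}
    for a in model.atoms:
        rn = a.residue_name
        if not a.is_hetero or rn in WATER_RESNAMES or rn in ion_resnames:
            continue
        candidates.setdefault((a.chain_id, a.residue_index, rn), []).append(a)
    if not candidates:
        raise NoLigandError(f"{model.name}: no hetero residue after exclusions")

    if resname == "auto":
        key = max(
            candidates,
            key=lambda k: (sum(1 for a in candidates[k] if not a.is_hydrogen), k[2]),
        )
        chosen = [a for a in model.atoms if (a.chain_id, a.residue_index, a.residue_name) == key]
    else:
        wanted = resname.strip().upper()
        chosen = [
            a
            for key, group in candidates.items()
            if key[2] == wanted
            for a in group
        ]
        if not chosen:
            raise NoLigandError(f"{model.name}: no hetero residue named {wanted!r}")
    return dataclasses.replace(model, ligand_atoms=chosen)


def write_pdb(model: MolecularModel, path: str | Path) -> None:
    """Write a model as a PDB file (fixture/export path; via gemmi)."""
    st = gemmi.Structure()
    st.name = model.name
    gm = gemmi.Model(str(model.model_index))
    # gemmi's add_* methods copy their argument, so build bottom-up:
    # group atoms per residue per chain first, then assemble.
    chain_order: list[str] = []
    grouped: dict[str, dict[tuple[int, str], list[AtomRecord]]] = {}
    for a in model.atoms:
        if a.chain_id not in grouped:
            grouped[a.chain_id] = {}
            chain_order.append(a.chain_id)
        grouped[a.chain_id].setdefault((a.residue_index, a.residue_name), []).append(a)
    for cid in chain_order:
        chain = gemmi.Chain(cid)
        for (ridx, rname), recs in grouped[cid].items():
            res = gemmi.Residue()
            res.name = rname
            res.seqid = gemmi.SeqId(ridx, " ")
            res.het_flag = "H" if recs[0].is_hetero else "A"
            for a in recs:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.coords)
                at.occ = 1.0
                res.add_atom(at)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
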