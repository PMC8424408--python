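"""RNA–ligand binding sites, pocket labelling, contacts and sequence motifs.

A nucleotide is a binding site when any of its heavy atoms lies strictly
closer than 4 Å to a ligand heavy atom.  Contact classification is a simple
distance-based surrogate (no donor/acceptor geometry): N/O pairs under
3.5 Å are counted as hydrogen-bond-like, any other heavy-atom pair under
4 Å as a non-bonded contact.

Sequence motifs are enumerated from maximal runs of sequence-consecutive
binding nucleotides; every contiguous substring of length 2–3 inside a run
is one motif occurrence, and a motif is identified with its reversal
(GU ≡ UG), represented by the lexicographically smaller string.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .pocket_detection import Pocket
from .structure_io import MolecularModel, NoLigandError

__all__ = [
    "BindingSite",
    "Contact",
    "MotifTable",
    "binding_nucleotides",
    "label_pockets",
    "classify_contacts",
    "composition",
    "motif_counts",
    "canonical_motif",
]


@dataclass(frozen=True)
class Contact:
    rna_atom: str  # "chain/resid resname/atom"
    ligand_atom: str
    distance: float  # Å
    kind: str  # "hbond_like" | "nonbond"


@dataclass
class BindingSite:
    """One binding-site nucleotide (closest heavy-atom pair < cutoff)."""

    chain_id: str
    residue_index: int
    base: str
    min_distance: float
    contacts: list[Contact] = field(default_factory=list)


@dataclass
class MotifTable:
    """Canonical-motif counts plus per-base composition of binding sites."""

    motifs: dict[str, int]
    composition: dict[str, float]


def _require_ligand(model: MolecularModel) -> list:
    lig = model.heavy_ligand_atoms()
    if not lig:
        raise NoLigandError(f"{model.name}: model has no ligand heavy atoms")
    return lig


def binding_nucleotides(
    model: MolecularModel,
    cutoff: float = 4.0,
    include_hydrogens: bool = False,
) -> list[BindingSite]:
    """Nucleotides with any (heavy-)atom pair strictly within ``cutoff`` Å."""
    lig = (
        list(model.ligand_atoms) if include_hydrogens else _require_ligand(model)
    )
    if not lig:
        raise NoLigandError(f"{model.name}: model has no ligand atoms")
    rna = (
        model.polymer_atoms if include_hydrogens else model.heavy_polymer_atoms()
    )
    tree = cKDTree(model.coords_of(lig))
    per_res: dict[tuple[str, int], tuple[str, float]] = {}
    for a in rna:
        d, _ = tree.query(a.coords)
        key = (a.chain_id, a.residue_index)
        prev = per_res.get(key)
        if prev is None or d < prev[1]:
            per_res[key] = (a.residue_name, float(d))
    sites = [
        BindingSite(chain_id=c, residue_index=i, base=base, min_distance=d)
        for (c, i), (base, d) in per_res.items()
        if d < cutoff
    ]
    sites.sort(key=lambda s: (s.chain_id, s.residue_index))
    return sites


def label_pockets(
    pockets: Sequence[Pocket], model: MolecularModel
) -> list[bool]:
    """Ligand-binding labels: True when a ligand heavy atom sits inside.

    A pocket binds the ligand when at least one ligand heavy atom lies
    within one grid spacing of an occupied pocket voxel center.
    """
    lig = model.heavy_ligand_atoms()
    if not lig:
        return [False] * len(pockets)
    coords = model.coords_of(lig)
    labels = []
    for p in pockets:
        centers = p.mask.voxel_centers()
        tree = cKDTree(centers)
        d, _ = tree.query(coords)
        labels.append(bool(np.min(d) <= p.mask.spacing))
    return labels


def classify_contacts(
    model: MolecularModel,
    hbond_cutoff: float = 3.5,
    contact_cutoff: float = 4.0,
) -> list[Contact]:
    """Distance-based contact list between RNA and ligand heavy atoms.

    Pairs with both elements in {N, O} and distance < ``hbond_cutoff`` are
    hydrogen-bond-like; any other heavy-atom pair under ``contact_cutoff``
    is a non-bonded contact.  Each atom pair is reported once.
    """
    if hbond_cutoff > contact_cutoff:
        raise ValueError("hbond_cutoff must be <= contact_cutoff")
    lig = _require_ligand(model)
    rna = model.heavy_polymer_atoms()
    if not rna:
        return []
    rna_xyz = model.coords_of(rna)
    lig_xyz = model.coords_of(lig)
    pairs = cKDTree(rna_xyz).query_ball_tree(cKDTree(lig_xyz), contact_cutoff)
    contacts: list[Contact] = []
    polar = {"N", "O"}
    for i, js in enumerate(pairs):
        ra = rna[i]
        for j in js:
            la = lig[j]
            d = float(np.linalg.norm(ra.coords - la.coords))
            if d >= contact_cutoff:
                continue
            kind = (
                "hbond_like"
                if ra.element in polar and la.element in polar and d < hbond_cutoff
                else "nonbond"
            )
            contacts.append(
                Contact(
                    rna_atom=f"{ra.chain_id}/{ra.residue_index} "
                    f"{ra.residue_name}/{ra.atom_name}",
                    ligand_atom=f"{la.residue_name}/{la.atom_name}",
                    distance=d,
                    kind=kind,
                )
            )
    contacts.sort(key=lambda c: (c.rna_atom, c.ligand_atom))
    return contacts


def composition(sites: Sequence[BindingSite]) -> dict[str, float]:
    """Per-base fraction of binding-site nucleotides (sums to 1)."""
    if not sites:
        raise ValueError("composition undefined for an empty site list")
    counts = Counter(s.base for s in sites)
    total = sum(counts.values())
    return {base: counts.get(base, 0) / total for base in "ACGU"}


def canonical_motif(s: str) -> str:
    """Identify a motif with its reversal; keep the lexicographic minimum."""
    return min(s, s[::-1])


def motif_counts(
    model: MolecularModel,
    sites: Sequence[BindingSite],
    min_len: int = 2,
    max_len: int = 3,
) -> MotifTable:
    """Count canonical sequence motifs among binding nucleotides.

    Binding nucleotides that are consecutive in the chain (author numbering
    differing by 1 on one chain) form runs; every contiguous substring with
    length in ``[min_len, max_len]`` inside a run contributes one occurrence
    to its canonical motif.  Isolated nucleotides (run length < min_len)
    contribute nothing.
    """
    ordered = sorted(sites, key=lambda s: (s.chain_id, s.residue_index))
    runs: list[str] = []
    current = ""
    prev: tuple[str, int] | None = None
    for s in ordered:
        if prev is not None and s.chain_id == prev[0] and s.residue_index == prev[1] + 1:
            current += s.base
        else:
            if current:
                runs.append(current)
            current = s.base
        prev = (s.chain_id, s.residue_index)
    if current:
        runs.append(current)

    counts: Counter[str] = Counter()
    for run in runs:
        for length in range(min_len, max_len + 1):
            for start in range(0, len(run) - length + 1):
                counts[canonical_motif(run[start : start + length])] += 1
    comp = composition(sites) if sites else {}
    return MotifTable(motifs=dict(sorted(counts.items())), composition=comp)
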