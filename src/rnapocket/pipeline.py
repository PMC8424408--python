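"""End-to-end pocket analysis pipeline and tabular reporting.

``run_pipeline`` ties the stages together: read structure → detect pockets
→ (optional) volume-outlier filter → shape descriptors → ligand labels →
binding sites, contacts and motifs → secondary-structure patterns.  The
result is a :class:`PocketReport` whose tables serialise deterministically
(byte-identical TSV/JSON for identical inputs and config).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ligand_interface, pocket_detection, rpdescriptor, secstruct_topology
from .structure_io import MolecularModel, NoLigandError, read_structure, select_ligand

__all__ = ["PipelineConfig", "PocketReport", "run_pipeline", "write_report"]

logger = logging.getLogger("rnapocket")

POCKET_COLUMNS = [
    "pocket_id", "volume", "area", "r_eff", "sphericity",
    "centroid_x", "centroid_y", "centroid_z",
    "rpd1", "rpd2", "s1", "s2", "s3", "shape_class", "similarity",
    "ligand_binding", "pattern",
]


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with the standard defaults."""

    spacing: float = 0.5  # detection grid δ, Å
    descriptor_spacing: float = 1.0  # descriptor grid, Å
    shell: float = 10.0  # shell probe radius, Å
    solvent: float = 3.0  # solvent probe radius, Å
    min_volume: float = 50.0  # Å³
    site_cutoff: float = 4.0  # binding-site distance, Å
    lining_cutoff: float = 4.0  # pocket-lining distance, Å
    hbond_cutoff: float = 3.5  # Å
    contact_cutoff: float = 4.0  # Å
    motif_min_len: int = 2
    motif_max_len: int = 3
    ligand: str = "auto"  # residue name or "auto" or "" (skip ligand stages)
    outlier_filter: bool = False  # m + 3σ filter (dataset-scale option)
    model_choice: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PocketReport:
    """Pipeline output: pocket table plus per-complex site/motif tables."""

    name: str
    config: PipelineConfig
    pockets: pd.DataFrame
    sites: pd.DataFrame
    contacts: pd.DataFrame
    motifs: pd.DataFrame
    composition: dict[str, float]
    removed_outliers: list[str] = field(default_factory=list)
    outlier_mean: float | None = None
    outlier_sigma: float | None = None
    pocket_masks: list[pocket_detection.Pocket] = field(default_factory=list)


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(
    structure: str | Path | MolecularModel,
    config: PipelineConfig | None = None,
    dotbracket: str | None = None,
) -> PocketReport:
    """Run the full pocket-analysis pipeline on one structure.

    ``structure`` may be a file path (PDB/mmCIF) or an in-memory model.
    ``dotbracket`` optionally provides the secondary structure for pattern
    labelling.  Deterministic given config: no randomness anywhere.
    """
    cfg = config or PipelineConfig()
    if isinstance(structure, MolecularModel):
        model = structure
    else:
        t0 = _stage(f"read {structure}")
        model = read_structure(structure, model_choice=cfg.model_choice)
        logger.info("read done in %.2fs", time.perf_counter() - t0)

    if cfg.ligand:
        try:
            model = select_ligand(model, cfg.ligand)
        except NoLigandError:
            model = dataclasses.replace(model, ligand_atoms=[])

    t0 = _stage("detect")
    pockets = pocket_detection.detect_pockets(
        model,
        shell=cfg.shell,
        solvent=cfg.solvent,
        spacing=cfg.spacing,
        min_volume=cfg.min_volume,
    )
    logger.info("detect: %d pockets in %.2fs", len(pockets), time.perf_counter() - t0)

    removed_ids: list[str] = []
    m = sigma = None
    if cfg.outlier_filter and len(pockets) >= 2:
        pockets, removed, m, sigma = pocket_detection.filter_volume_outliers(pockets)
        removed_ids = [p.pocket_id for p in removed]

    ss = (
        secstruct_topology.parse_dotbracket(model.sequence, dotbracket)
        if dotbracket
        else None
    )
    labels = ligand_interface.label_pockets(pockets, model)

    rows = []
    for p, binding in zip(pockets, labels):
        desc = rpdescriptor.describe_pocket(p.mask, cfg.descriptor_spacing)
        pattern = ""
        if ss is not None:
            pattern = secstruct_topology.pocket_pattern(
                p, model, ss, cfg.lining_cutoff
            ).label
        rows.append(
            {
                "pocket_id": p.pocket_id,
                "volume": p.volume,
                "area": p.area,
                "r_eff": p.r_eff,
                "sphericity": p.sphericity,
                "centroid_x": p.centroid[0],
                "centroid_y": p.centroid[1],
                "centroid_z": p.centroid[2],
                "rpd1": desc.rpd1,
                "rpd2": desc.rpd2,
                "s1": desc.s1,
                "s2": desc.s2,
                "s3": desc.s3,
                "shape_class": desc.shape_class,
                "similarity": desc.similarity,
                "ligand_binding": binding,
                "pattern": pattern,
            }
        )
    pocket_df = pd.DataFrame(rows, columns=POCKET_COLUMNS)

    sites_rows, contact_rows, motif_rows = [], [], []
    comp: dict[str, float] = {}
    if model.heavy_ligand_atoms():
        sites = ligand_interface.binding_nucleotides(model, cfg.site_cutoff)
        for s in sites:
            sites_rows.append(
                {
                    "chain": s.chain_id,
                    "residue_index": s.residue_index,
                    "base": s.base,
                    "min_distance": s.min_distance,
                }
            )
        for c in ligand_interface.classify_contacts(
            model, cfg.hbond_cutoff, cfg.contact_cutoff
        ):
            contact_rows.append(dataclasses.asdict(c))
        if sites:
            table = ligand_interface.motif_counts(
                model, sites, cfg.motif_min_len, cfg.motif_max_len
            )
            comp = table.composition
            motif_rows = [
                {"motif": k, "count": v} for k, v in sorted(table.motifs.items())
            ]

    return PocketReport(
        name=model.name,
        config=cfg,
        pockets=pocket_df,
        sites=pd.DataFrame(
            sites_rows, columns=["chain", "residue_index", "base", "min_distance"]
        ),
        contacts=pd.DataFrame(
            contact_rows, columns=["rna_atom", "ligand_atom", "distance", "kind"]
        ),
        motifs=pd.DataFrame(motif_rows, columns=["motif", "count"]),
        composition=comp,
        removed_outliers=removed_ids,
        outlier_mean=m,
        outlier_sigma=sigma,
        pocket_masks=pockets,
    )


def _write_tsv(df: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_report(report: PocketReport, outdir: str | Path) -> None:
    """Write pockets/sites/contacts/motifs TSVs, report.json and MRC masks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(report.pockets, outdir / "pockets.tsv")
    _write_tsv(report.sites, outdir / "sites.tsv")
    _write_tsv(report.contacts, outdir / "contacts.tsv")
    _write_tsv(report.motifs, outdir / "motifs.tsv")
    payload = {
        "name": report.name,
        "config": report.config.to_dict(),
        "n_pockets": int(len(report.pockets)),
        "composition": report.composition,
        "removed_outliers": report.removed_outliers,
        "outlier_mean": report.outlier_mean,
        "outlier_sigma": report.outlier_sigma,
        "pockets": json.loads(report.pockets.to_json(orient="records")),
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    masks = outdir / "masks"
    masks.mkdir(exist_ok=True)
    for p in report.pocket_masks:
        mask1 = rpdescriptor.resample_mask(p.mask, report.config.descriptor_spacing)
        pocket_detection.write_mask(masks / f"{p.pocket_id}.mrc", mask1)
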