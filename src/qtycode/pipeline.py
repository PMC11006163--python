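"""End-to-end pipeline: design + variant classification + reports.

Reads a YAML (or in-memory) configuration naming the inputs, runs each
stage that has inputs available, and writes plain-text reports:

* ``design_report.tsv`` — per protein: native/variant pI and MW, TM and
  overall variation percentages; plus ``qty_variants.fasta``
* ``variants_classified.tsv`` and ``variant_summary.json`` — the classified
  variant table and its direction/location/effect cross-tabulation
* ``codon_paths.tsv`` — single-nucleotide paths for the QTY/rQTY pairs
* ``superposition.tsv`` — Kabsch RMSD when two structures are supplied

Logs go to stderr; data only to files, so the TSV outputs are pipe-safe.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from . import codons, qty, structure, variants
from .sequences import SegmentKind, read_fasta, read_topology, write_fasta

PathLike = Union[str, Path]

logger = logging.getLogger("qtycode")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
logger.setLevel(logging.INFO)

SUMMARY_SCHEMA_VERSION = 1

QTY_PAIR_NAMES = [("L", "Q"), ("I", "T"), ("V", "T"), ("F", "Y"),
                  ("Q", "L"), ("T", "I"), ("T", "V"), ("Y", "F")]


@dataclass
class PipelineConfig:
    fasta: Path | None = None
    topology: Path | None = None       # single file, or directory of <id>.json
    variants: Path | None = None       # None -> packaged reference table
    pdb_reference: Path | None = None
    pdb_mobile: Path | None = None
    msa: Path | None = None
    segment_kinds: list[str] = field(default_factory=lambda: ["TM_HELIX"])
    grade_threshold: int = 8
    burial_radius: float = 10.0
    burial_cutoff: int = 14
    out_dir: Path = Path("qty_out")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, value in raw.items():
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            if key in {"fasta", "topology", "variants", "pdb_reference", "pdb_mobile", "msa", "out_dir"}:
                value = Path(value)
            kwargs[key] = value
        return cls(**kwargs)

    def target_kinds(self) -> set[SegmentKind]:
        return {SegmentKind(k) for k in self.segment_kinds}


def _topology_for(record_id: str, topology_path: Path):
    if topology_path.is_dir():
        for ext in (".json", ".tsv"):
            cand = topology_path / f"{record_id}{ext}"
            if cand.exists():
                return read_topology(cand, protein_id=record_id)
        raise FileNotFoundError(f"no topology file for {record_id} under {topology_path}")
    return read_topology(topology_path, protein_id=record_id)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns a dict of output paths and summaries."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}

    # --- design stage -----------------------------------------------------
    if config.fasta is not None:
        logger.info("design stage: %s", config.fasta)
        if not Path(config.fasta).exists():
            raise FileNotFoundError(f"FASTA not found: {config.fasta}")
        if config.topology is None or not Path(config.topology).exists():
            raise FileNotFoundError(f"topology not found: {config.topology}")
        records = read_fasta(config.fasta)
        rows = []
        variant_records = []
        for rec in records:
            topo = _topology_for(rec.id, Path(config.topology))
            result = qty.apply_qty(rec, topo, config.target_kinds())
            variant_records.append(result.variant_record)
            rows.append({
                "id": rec.id,
                "pI_native": result.native_pI,
                "pI_qty": result.variant_pI,
                "MW_native": round(result.native_mw, 2),
                "MW_qty": round(result.variant_mw, 2),
                "tm_variation_pct": round(result.tm_variation_pct, 2),
                "overall_variation_pct": round(result.overall_variation_pct, 2),
                "n_substitutions": len(result.substitutions),
            })
        design_path = out_dir / "design_report.tsv"
        pd.DataFrame(rows).to_csv(design_path, sep="\t", index=False)
        fasta_path = out_dir / "qty_variants.fasta"
        write_fasta(variant_records, fasta_path)
        outputs["design_report"] = design_path
        outputs["variant_fasta"] = fasta_path

    # --- variant stage ----------------------------------------------------
    logger.info("variant stage")
    if config.variants is not None:
        if not Path(config.variants).exists():
            raise FileNotFoundError(f"variant table not found: {config.variants}")
        table = variants.read_variant_table(config.variants)
    else:
        table = variants.load_reference_variants()
    classified_path = out_dir / "variants_classified.tsv"
    variants.write_variant_table(table, classified_path)
    summary = variants.summarize(table)
    summary_payload = {"schema_version": SUMMARY_SCHEMA_VERSION, **summary.as_dict()}
    summary_path = out_dir / "variant_summary.json"
    summary_path.write_text(json.dumps(summary_payload, indent=1, sort_keys=True) + "\n")
    outputs["variants_classified"] = classified_path
    outputs["variant_summary"] = summary_path
    outputs["summary"] = summary

    # --- codon stage ------------------------------------------------------
    logger.info("codon stage")
    codon_rows = []
    for ref, alt in QTY_PAIR_NAMES:
        paths = codons.single_change_paths(ref, alt)
        if not paths:
            codon_rows.append({
                "from_aa": ref, "to_aa": alt, "codon_from": "-", "codon_to": "-",
                "position": "-", "base_change": "-", "change_class": "-",
                "min_nt_changes": codons.min_nt_changes(ref, alt),
            })
        for p in paths:
            codon_rows.append({
                "from_aa": ref, "to_aa": alt, "codon_from": p.codon_from,
                "codon_to": p.codon_to, "position": p.position,
                "base_change": f"{p.base_from}->{p.base_to}",
                "change_class": p.change_class.value,
                "min_nt_changes": 1,
            })
    codon_path = out_dir / "codon_paths.tsv"
    pd.DataFrame(codon_rows).to_csv(codon_path, sep="\t", index=False)
    outputs["codon_paths"] = codon_path

    # --- superposition stage ---------------------------------------------
    if config.pdb_reference is not None and config.pdb_mobile is not None:
        logger.info("superposition stage")
        ref_model = structure.read_pdb_ca(config.pdb_reference)
        mob_model = structure.read_pdb_ca(config.pdb_mobile)
        sup = structure.kabsch_superpose(mob_model, ref_model)
        sup_path = out_dir / "superposition.tsv"
        pd.DataFrame([{
            "reference": str(config.pdb_reference),
            "mobile": str(config.pdb_mobile),
            "rmsd_A": round(sup.rmsd, 4),
            "n_pairs": sup.n_pairs,
            "degenerate": sup.degenerate,
        }]).to_csv(sup_path, sep="\t", index=False)
        outputs["superposition"] = sup_path

    logger.info("pipeline complete: %d output file(s) in %s",
                sum(1 for v in outputs.values() if isinstance(v, Path)), out_dir)
    return outputs
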