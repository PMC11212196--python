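"""End-to-end pipeline: extract -> canonicalize -> filter -> curate -> report.

Deterministic given the same config and inputs. Every removed record id is
logged with its reason, and the configuration is serialized next to the
outputs for provenance.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .curation import CurationConfig, ValenceTable, curate_reaction
from .errors import RxncureError
from .io import parse_records, read_reaction_records, write_curated_csv
from .templates import extract_template_library

logger = logging.getLogger("rxncure")


@dataclass
class PipelineConfig:
    """Pipeline settings; serialized alongside every output for provenance."""

    input_path: str = ""
    reaction_col: str = "reaction"
    id_col: str = "id"
    min_frequency: int = 5
    enable_byproducts: bool = False
    reinstate_spectators: bool = False
    valence_overrides: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "rxncure_output"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _valence_table(cfg: PipelineConfig) -> ValenceTable:
    overrides = {}
    for key, vals in (cfg.valence_overrides or {}).items():
        elem, _, charge = key.partition(":")
        overrides[(elem, int(charge or 0))] = tuple(vals)
    return ValenceTable(overrides)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the two-stage protocol on a reactions file; returns the summary.

    Writes ``templates.jsonl``, ``curated.csv``, ``summary.json``,
    ``removed.json`` (record ids with reasons) and ``config.yaml`` into the
    output directory. Aborts with :class:`RxncureError` when the filtered
    template library is empty (curation would remove everything).
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = read_reaction_records(cfg.input_path, cfg.reaction_col,
                                    cfg.id_col)
    if not records:
        raise RxncureError(f"no records in {cfg.input_path}")
    reactions, parse_errors = parse_records(records)
    if not reactions:
        raise RxncureError("no record parsed successfully")

    lib, extract_errors = extract_template_library(
        reactions, min_frequency=cfg.min_frequency)
    if len(lib) == 0:
        raise RxncureError(
            "empty template library after frequency filtering "
            f"(threshold {cfg.min_frequency}); every record would be removed")
    lib.to_jsonl(outdir / "templates.jsonl")

    vt = _valence_table(cfg)
    ccfg = CurationConfig(add_byproducts=cfg.enable_byproducts,
                          reinstate_spectators=cfg.reinstate_spectators)
    original_text = dict(records)
    rows = []
    removed: dict[str, str] = dict(parse_errors)
    tallies = {"validated": 0, "repaired": 0, "removed": 0}
    n_missing_repaired = n_mapping_repaired = 0
    for rxn in reactions:
        out = curate_reaction(rxn, lib, vt, ccfg)
        tallies[out.status] += 1
        if out.status == "removed":
            removed[out.record_id] = out.notes or "no template matched"
            logger.info("removed %s: %s", out.record_id, removed[out.record_id])
        else:
            if out.added_fragments:
                n_missing_repaired += 1
            if out.mapping_changed:
                n_mapping_repaired += 1
        rows.append({
            "id": out.record_id,
            "original_reaction": original_text.get(out.record_id, ""),
            "curated_reaction": (out.curated_reaction.to_smiles()
                                 if out.curated_reaction else ""),
            "status": out.status,
        })
    write_curated_csv(outdir / "curated.csv", rows)

    n = len(reactions)
    summary = {
        "n_records": len(records),
        "n_parsed": n,
        "n_parse_errors": len(parse_errors),
        "n_extraction_skipped": len(extract_errors),
        "n_templates": len(lib),
        "validated": tallies["validated"],
        "repaired": tallies["repaired"],
        "removed": tallies["removed"],
        "repaired_missing_reactants": n_missing_repaired,
        "repaired_mappings": n_mapping_repaired,
        "residual_proportion": 100.0 * (n - tallies["removed"]) / n,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(outdir / "removed.json", "w") as fh:
        json.dump(removed, fh, indent=2)
    cfg.to_yaml(outdir / "config.yaml")
    return summary
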