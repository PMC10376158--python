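"""End-to-end typing pipeline: digest -> annotate -> classify -> summarize ->
networks, with provenance stamped into every output.

Outputs under the configured directory: ``profiles.tsv`` (DraI digests),
``structures.tsv`` (element architecture and lineage), ``calls.tsv``
(haplogroup/haplotype calls), ``report.json`` (frequency report) and one
GML + Nexus network per allele class.  Reruns with the same configuration
are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .annotate import annotate, call_lineage
from .classify import ReferenceDB, default_reference_db, match_haplotype
from .digest import digest, digest_table, profile_key
from .io import read_fasta, read_sample_sheet, write_json, write_tsv
from .model import HaplotypeCall, LocusSequence
from .network import align_sequences, build_mjn, export_network
from .popgen import summarize
from .templates import TemplateLibrary, default_templates

logger = logging.getLogger("beehap")


class PipelineConfig(BaseModel):
    input_fasta: Path
    sample_sheet: Path | None = None
    refdb: Path | None = None  # TSV or JSON; default: shipped synthetic DB
    tolerance: int = Field(default=0, ge=0, le=1)
    epsilon: int = Field(default=0, ge=0)
    seed: int = 1
    outdir: Path = Path("beehap-out")
    log_level: str = "INFO"

    def config_hash(self) -> str:
        # analysis parameters only: where outputs land does not change them
        digest_input = self.model_dump_json(
            exclude={"outdir", "log_level"}
        ).encode()
        return hashlib.sha256(digest_input).hexdigest()[:12]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_refdb(cfg: PipelineConfig, library: TemplateLibrary) -> ReferenceDB:
    if cfg.refdb is None:
        return default_reference_db(library)
    path = Path(cfg.refdb)
    if path.suffix.lower() == ".json":
        return ReferenceDB.from_json(path)
    return ReferenceDB.from_tsv(path)


def run_pipeline(
    cfg: PipelineConfig,
    library: TemplateLibrary | None = None,
    refdb: ReferenceDB | None = None,
) -> dict:
    """Run the full workflow; returns the report dict (also written to disk)."""
    logging.basicConfig(level=cfg.log_level)
    library = library or default_templates(cfg.seed)
    try:
        refdb = refdb or _load_refdb(cfg, library)
    except (OSError, ValueError) as exc:
        raise PipelineError("refdb", str(exc)) from exc

    try:
        seqs = read_fasta(cfg.input_fasta)
    except (OSError, ValueError) as exc:
        raise PipelineError("input", str(exc)) from exc
    if not seqs:
        raise PipelineError("input", f"no sequences in {cfg.input_fasta}")
    sheet = None
    if cfg.sample_sheet is not None:
        sheet_df = read_sample_sheet(cfg.sample_sheet)
        sheet = dict(zip(sheet_df["sample_id"], sheet_df["region"]))

    provenance = {
        "tool": "beehap",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "refdb_version": refdb.version,
        "templates": library.version,
    }
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # stage: digest
    try:
        profiles_df = digest_table(seqs)
    except ValueError as exc:
        raise PipelineError("digest", str(exc)) from exc
    write_tsv(profiles_df, outdir / "profiles.tsv", provenance)
    for s in seqs:
        logger.info("digest %s: %s", s.sample_id, profile_key(digest(s)))

    # stage: annotate + classify
    calls: list[HaplotypeCall] = []
    structures = []
    try:
        for s in seqs:
            structure = annotate(s, library=library)
            lineage = call_lineage(structure)
            structures.append(
                {
                    "sample_id": s.sample_id,
                    "p_form": structure.p_form,
                    "q_count": structure.q_count,
                    "allele": structure.allele_string,
                    "lineage": lineage.lineage,
                    "resolved": structure.resolved,
                }
            )
            logger.info("annotate %s: %s", s.sample_id, structure.allele_string)
            call = match_haplotype(
                s, refdb, library=library, tolerance=cfg.tolerance
            )
            calls.append(call)
            logger.info("classify %s: %s", s.sample_id, call.haplotype)
    except ValueError as exc:
        raise PipelineError("classify", str(exc)) from exc
    write_tsv(pd.DataFrame(structures), outdir / "structures.tsv", provenance)
    calls_df = pd.DataFrame(
        {
            "sample_id": c.sample_id,
            "lineage": c.lineage,
            "haplogroup": c.haplogroup,
            "haplotype": c.haplotype,
            "novelty": c.novelty,
            "n_diffs_to_nearest": c.n_diffs_to_nearest,
            "nearest_known": c.nearest_known,
        }
        for c in calls
    )
    write_tsv(calls_df, outdir / "calls.tsv", provenance)

    # stage: summarize
    try:
        report = summarize(calls, sheet)
    except ValueError as exc:
        raise PipelineError("summarize", str(exc)) from exc

    # stage: networks, one per allele class
    networks = {}
    netdir = outdir / "networks"
    netdir.mkdir(exist_ok=True)
    by_class: dict[str, dict] = {}
    for s, st, call in zip(seqs, structures, calls):
        if not st["resolved"]:
            continue
        cls = st["allele"]
        group = by_class.setdefault(cls, {"seqs": {}, "freqs": {}})
        label = call.haplotype
        if label in group["seqs"] and group["seqs"][label] != s.sequence:
            i = 2
            while f"{label}#{i}" in group["seqs"]:
                i += 1
            label = f"{label}#{i}"
        group["seqs"].setdefault(label, s.sequence)
        group["freqs"][label] = group["freqs"].get(label, 0) + 1
    try:
        for cls, group in sorted(by_class.items()):
            aligned = align_sequences(group["seqs"])
            net = build_mjn(aligned, group["freqs"], epsilon=cfg.epsilon)
            gml = export_network(net, netdir / f"{cls}.gml")
            nex = export_network(net, netdir / f"{cls}.nex")
            networks[cls] = {
                "nodes": net.graph.number_of_nodes(),
                "edges": net.graph.number_of_edges(),
                "medians": len(net.median_nodes),
                "n_samples": net.n_samples,
                "files": [
                    str(gml.relative_to(outdir)),
                    str(nex.relative_to(outdir)),
                ],
            }
            logger.info("network %s: %s", cls, networks[cls])
    except (ValueError, RuntimeError) as exc:
        raise PipelineError("network", str(exc)) from exc

    payload = {"report": report.to_dict(), "networks": networks}
    write_json(payload, outdir / "report.json", provenance)
    return {"provenance": provenance, **payload}
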