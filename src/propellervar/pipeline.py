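"""End-to-end orchestration: structure -> geometry -> blades/motif -> tetrads
-> annotation -> group statistics, from a single validated config.

Outputs are deterministic given config + seed; every stage either produces
its output or logs a skip reason into the report.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .structure import DomainStructure, read_structure, extract_domain
from .geometry import AxisMode, compute_axis, project_residues, interpolate_missing
from .blades import segment_blades, superpose_blades, assign_motif_positions, format_alignment
from .tetrads import detect_hbonds, identify_tetrads
from .variants import (parse_variant_table, filter_domain_variants, annotate,
                       compute_rsasa, conservation_scores, read_external_scores,
                       annotated_to_frame)
from .stats import run_group_suite, comparisons_to_records

logger = logging.getLogger("propellervar")

__all__ = ["PipelineConfig", "PipelineReport", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    structure_path: str
    variant_table: str | None = None
    structure_format: str = "auto"
    chain_id: str | None = None
    domain_range: tuple[int, int] | None = None
    numbering_offset: int = 0          # variant number + offset = structure number
    axis_mode: str = "principal"
    orient_flip: bool = False
    projection_atom: str = "C"
    blade_ranges: list[tuple[int, int]] | None = None
    msa_path: str | None = None
    msa_reference_id: str = "reference"
    external_scores_path: str | None = None
    hotspot_residues: list[int] | None = None
    stats_method: str = "mann_whitney"
    unique_residues: bool = True
    holm: bool = False
    features: tuple[str, ...] = ("z", "rsasa", "conservation")
    sasa_points: int = 240
    output_dir: str | None = None
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        if not Path(self.structure_path).exists():
            problems.append(f"structure file not found: {self.structure_path}")
        for name in ("variant_table", "msa_path", "external_scores_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                problems.append(f"{name} not found: {p}")
        if self.axis_mode not in ("principal", "crystal_z"):
            problems.append(f"unknown axis_mode {self.axis_mode!r}")
        if self.stats_method not in ("mann_whitney", "welch_t"):
            problems.append(f"unknown stats_method {self.stats_method!r}")
        if self.domain_range is not None and self.domain_range[0] > self.domain_range[1]:
            problems.append(f"invalid domain_range {self.domain_range}")
        return problems


@dataclass
class PipelineReport:
    config: dict
    n_residues: int = 0
    n_blades: int = 0
    n_complete_tetrads: int = 0
    n_incomplete_tetrads: int = 0
    n_variants: int = 0
    warnings: list[str] = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    # in-memory stage results
    domain: DomainStructure | None = None
    frame: object = None
    projection: object = None
    segmentation: object = None
    motif: object = None
    tetrads: list = field(default_factory=list)
    annotated: list = field(default_factory=list)
    comparisons: list = field(default_factory=list)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    problems = config.validate()
    if problems:
        raise PipelineError("config invalid: " + "; ".join(problems))
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    report = PipelineReport(config={k: v for k, v in asdict(config).items()})

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # structure
        domain = _stage("structure")(read_structure)(
            config.structure_path, format=config.structure_format,
            chain_id=config.chain_id)
        if config.domain_range is not None:
            domain = _stage("structure")(extract_domain)(
                domain, config.domain_range[0], config.domain_range[1])
        report.domain = domain
        report.n_residues = len(domain.residues)
        logger.info("structure: %d residues in chain %s", report.n_residues, domain.chain_id)

        # blades & motif (axis-independent)
        segmentation = _stage("blades")(segment_blades)(domain, config.blade_ranges)
        superposition = _stage("blades")(superpose_blades)(domain, segmentation)
        motif = _stage("motif")(assign_motif_positions)(segmentation, superposition, domain)
        report.segmentation, report.motif = segmentation, motif
        report.n_blades = segmentation.n_blades

        # tetrads
        hbonds = _stage("tetrads")(detect_hbonds)(domain)
        tetrads = _stage("tetrads")(identify_tetrads)(motif, domain, hbonds)
        report.tetrads = tetrads
        report.n_complete_tetrads = sum(t.complete for t in tetrads)
        report.n_incomplete_tetrads = sum(not t.complete for t in tetrads)

        # geometry: orient the axis on the tetrad aspartates (top face)
        asp_anchor = {t.members["D"] for t in tetrads if t.members["D"] is not None}
        frame = _stage("geometry")(compute_axis)(
            domain, mode=config.axis_mode, anchor_residues=asp_anchor or None,
            flip=config.orient_flip)
        projection = _stage("geometry")(project_residues)(
            domain, frame, atom_name=config.projection_atom, ca_fallback=True)
        projection = _stage("geometry")(interpolate_missing)(projection, domain)
        report.frame, report.projection = frame, projection

        # burial
        rsasa = None
        if "rsasa" in config.features:
            rsasa = _stage("burial")(compute_rsasa)(domain, n_points=config.sasa_points)

        # conservation
        conservation = None
        if config.msa_path:
            conservation = _stage("conservation")(conservation_scores)(
                config.msa_path, config.msa_reference_id,
                [r.author_number for r in domain.residues])
        else:
            report.skipped["conservation"] = "no MSA supplied"

        # variants
        annotated = []
        if config.variant_table:
            variants = _stage("variants")(parse_variant_table)(config.variant_table)
            if config.numbering_offset:
                from dataclasses import replace as _replace
                variants = [
                    _replace(v, protein_change=(v.protein_change[0],
                                                v.protein_change[1] + config.numbering_offset,
                                                v.protein_change[2]))
                    for v in variants
                ]
            variants = filter_domain_variants(variants, domain.domain_range)
            ext = (read_external_scores(config.external_scores_path)
                   if config.external_scores_path else None)
            hotspots = set(config.hotspot_residues) if config.hotspot_residues else None
            annotated = _stage("annotation")(annotate)(
                variants, projection=projection, motif=motif, tetrads=tetrads,
                rsasa=rsasa, conservation=conservation,
                hotspot_residues=hotspots, external_scores=ext, domain=domain)
            report.annotated = annotated
            report.n_variants = len(annotated)

            # statistics
            feature_values: dict[str, dict[int, float]] = {}
            if "z" in config.features:
                feature_values["z"] = {n: e.z for n, e in projection.entries.items()}
            if "rsasa" in config.features and rsasa:
                feature_values["rsasa"] = rsasa
            if "conservation" in config.features and conservation is not None:
                feature_values["conservation"] = conservation.by_residue
            if ext:
                for score in sorted({s for d in ext.values() for s in d}):
                    per_res = {}
                    for a in annotated:
                        if score in a.external_scores:
                            per_res[a.variant.residue_number] = a.external_scores[score]
                    if per_res:
                        feature_values[score] = per_res
            report.comparisons = _stage("statistics")(run_group_suite)(
                annotated, feature_values, motif=motif, tetrads=tetrads,
                hotspot_residues=hotspots,
                all_residue_numbers=[r.author_number for r in domain.residues],
                method=config.stats_method, unique_residues=config.unique_residues,
                holm=config.holm)
        else:
            report.skipped["variants"] = "no variant table supplied"
            report.skipped["statistics"] = "no variant table supplied"

        report.warnings = [str(w.message) for w in caught]

    if outdir:
        _write_outputs(report, domain, outdir)
    return report


def _write_outputs(report: PipelineReport, domain: DomainStructure, outdir: Path) -> None:
    proj_rows = [{"residue": n, "z": round(e.z, 4), "status": e.status}
                 for n, e in sorted(report.projection.entries.items())]
    pd.DataFrame(proj_rows).to_csv(outdir / "projection.tsv", sep="\t", index=False)
    report.outputs["projection"] = str(outdir / "projection.tsv")

    (outdir / "alignment.txt").write_text(format_alignment(report.motif, domain) + "\n")
    report.outputs["alignment"] = str(outdir / "alignment.txt")

    tet_rows = []
    for t in report.tetrads:
        tet_rows.append({
            "blade": t.blade_index, "D": t.members["D"], "H": t.members["H"],
            "S_T": t.members["S_T"], "W": t.members["W"],
            "complete": t.complete, "n_hbonds": len(t.hbonds),
            "n_asp_backbone_bonds": len(t.asp_backbone_bonds),
        })
    pd.DataFrame(tet_rows).to_csv(outdir / "tetrads.tsv", sep="\t", index=False)
    report.outputs["tetrads"] = str(outdir / "tetrads.tsv")

    if report.annotated:
        annotated_to_frame(report.annotated).to_csv(
            outdir / "annotated_variants.tsv", sep="\t", index=False)
        report.outputs["annotated_variants"] = str(outdir / "annotated_variants.tsv")
    if report.comparisons:
        with open(outdir / "comparisons.json", "w") as fh:
            json.dump(comparisons_to_records(report.comparisons), fh, indent=1)
        report.outputs["comparisons"] = str(outdir / "comparisons.json")

    meta = {
        "n_residues": report.n_residues, "n_blades": report.n_blades,
        "n_complete_tetrads": report.n_complete_tetrads,
        "n_incomplete_tetrads": report.n_incomplete_tetrads,
        "n_variants": report.n_variants,
        "warnings": report.warnings, "skipped": report.skipped,
        "config": report.config,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
    report.outputs["report"] = str(outdir / "report.json")
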