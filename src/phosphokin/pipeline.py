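"""End-to-end orchestration: quant -> map -> kinase activity -> network.

A :class:`PipelineConfig` collects paths and thresholds (all of which
default to the study's fixed constants: site FDR 0.05, edge score 0.4,
minimum two measured substrates, redundancy cutoff 0.5, up to ten
expansion nodes). ``run_pipeline`` executes the stages in order and writes
a manifest with input hashes and seeds so deterministic stages rerun
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .simulate import (
    SimulationDesign,
    read_fasta,
    read_measurements,
    read_ortholog_pairs,
    simulate_interaction_edges,
    simulate_study,
    simulate_term_annotation,
    write_study,
)
from .quant import parse_sites, quantify, select_changed_proteins
from .ortholog import AlignmentScoring, map_sites
from .kinase import annotation_from_frame, contrast_deltas, infer_activities, read_ks_annotation
from .network import (
    attach_phospho_states,
    build_network,
    expand_network,
    hypergeom_enrichment,
    read_edge_table,
    read_gmt,
    remove_redundant_terms,
    write_gmt,
    write_network,
)

logger = logging.getLogger(__name__)


class ValidationError(Exception):
    """Raised when configuration or inputs fail validation."""


@dataclass
class PipelineConfig:
    """Paths, contrast definitions, and thresholds for one pipeline run."""

    out_dir: str = "phosphokin_run"
    measurements: str | None = None
    fasta_source: str | None = None
    fasta_target: str | None = None
    ortholog_pairs: str | None = None
    ks_annotation: str | None = None
    edges: str | None = None
    terms: str | None = None

    control: str = "US"
    fdr: float = 0.05
    edge_threshold: float = 0.4
    min_substrates: int = 2
    redundancy_cutoff: float = 0.5
    max_expansion_nodes: int = 10
    kinase_alpha: float = 0.05
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5

    simulate: bool = False
    seed: int = 42
    simulate_kwargs: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name, value, lo, hi in [
            ("fdr", self.fdr, 0.0, 1.0),
            ("edge_threshold", self.edge_threshold, 0.0, 1.0),
            ("redundancy_cutoff", self.redundancy_cutoff, 0.0, 1.0),
            ("kinase_alpha", self.kinase_alpha, 0.0, 1.0),
        ]:
            if not lo < value <= hi:
                raise ValidationError(f"{name} must be in ({lo}, {hi}]: got {value}")
        if self.min_substrates < 2:
            raise ValidationError("min_substrates must be >= 2")
        if self.max_expansion_nodes < 0:
            raise ValidationError("max_expansion_nodes must be >= 0")
        if not self.simulate and self.measurements is None:
            raise ValidationError("measurements path required unless simulate=true")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def scoring(self) -> AlignmentScoring:
        return AlignmentScoring(self.substitution_matrix, self.gap_open, self.gap_extend)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Schema and cross-reference checks on every configured input file."""
    report = ValidationReport()
    try:
        config.validate()
    except ValidationError as exc:
        report.errors.append(str(exc))
        return report
    if config.simulate:
        return report

    for name in ("measurements", "fasta_source", "fasta_target", "ortholog_pairs", "ks_annotation", "edges", "terms"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            report.errors.append(f"{name}: file not found: {path}")
    if report.errors:
        return report

    try:
        meas = read_measurements(config.measurements)
    except Exception as exc:
        report.errors.append(f"measurements: {exc}")
        return report

    sequences = read_fasta(config.fasta_source) if config.fasta_source else None
    for i, (prot, sites) in enumerate(zip(meas["protein"], meas["site_positions"])):
        try:
            parsed = parse_sites(sites)
        except ValueError as exc:
            report.errors.append(f"measurements row {i}: {exc}")
            continue
        if sequences is not None:
            seq = sequences.get(prot)
            if seq is None:
                report.errors.append(f"measurements row {i}: protein {prot} not in FASTA")
            else:
                for pos, res in parsed:
                    if pos > len(seq):
                        report.errors.append(
                            f"measurements row {i}: site {res}{pos} beyond length "
                            f"{len(seq)} of protein {prot}"
                        )

    groups = meas.groupby(["condition", "timepoint"])["replicate"].nunique()
    conditions = set(meas["condition"])
    if config.control not in conditions:
        report.errors.append(f"control condition {config.control!r} absent from measurements")
    else:
        for (cond, tp), n in groups.items():
            if n < 2:
                report.warnings.append(f"condition {cond}/{tp}: only {n} replicate(s)")
        ligand_tps = {tp for (c, tp) in groups.index if c != config.control}
        control_tps = {tp for (c, tp) in groups.index if c == config.control}
        for tp in sorted(ligand_tps - control_tps):
            report.errors.append(f"timepoint {tp}: no time-matched control runs")

    if config.ks_annotation:
        try:
            ann = read_ks_annotation(config.ks_annotation)
        except Exception as exc:
            report.errors.append(f"ks_annotation: {exc}")
        else:
            known = (
                set(read_fasta(config.fasta_target))
                if config.fasta_target
                else set(meas["protein"])
            )
            unknown = {p for subs in ann.values() for p, _ in subs} - known
            if unknown:
                report.warnings.append(
                    f"kinase annotation references {len(unknown)} unknown protein(s), "
                    f"e.g. {sorted(unknown)[:3]}"
                )
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute quant -> map -> kinact -> network and write all outputs.

    Returns a mapping of output names to paths. Any stage failure raises
    with a stage-tagged message. Reruns with the same config and inputs
    produce byte-identical deterministic outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    input_paths: dict[str, str] = {}

    if config.simulate:
        design = SimulationDesign(seed=config.seed)
        study = simulate_study(design, **config.simulate_kwargs)
        in_dir = out / "inputs"
        paths = write_study(study, in_dir)
        edges_df = simulate_interaction_edges(sorted(study.proteins), seed=design.seed + 101)
        edges_df.to_csv(in_dir / "edges.tsv", sep="\t", index=False)
        terms = simulate_term_annotation(sorted(study.proteins), seed=design.seed + 102)
        write_gmt(terms, in_dir / "terms.gmt")
        config = dataclasses.replace(
            config,
            measurements=str(paths["measurements"]),
            fasta_source=str(paths["fasta_source"]),
            fasta_target=str(paths["fasta_target"]),
            ortholog_pairs=str(paths["ortholog_pairs"]),
            ks_annotation=str(paths["ks_annotation_target"]),
            edges=str(in_dir / "edges.tsv"),
            terms=str(in_dir / "terms.gmt"),
        )

    report = validate_inputs(config)
    if not report.ok:
        raise ValidationError("; ".join(report.errors))
    for w in report.warnings:
        logger.warning("validate: %s", w)

    def _stage(name):
        logger.info("stage %s", name)

    try:
        _stage("quant")
        meas = read_measurements(config.measurements)
        sequences = read_fasta(config.fasta_source) if config.fasta_source else None
        site_stats, site_fc = quantify(meas, sequences, control=config.control)
        outputs["site_stats"] = out / "site_stats.tsv"
        outputs["site_fc"] = out / "site_fc.tsv"
        site_stats.to_csv(outputs["site_stats"], sep="\t", index=False)
        site_fc.to_csv(outputs["site_fc"], sep="\t", index=False)
    except ValidationError:
        raise
    except Exception as exc:
        raise RuntimeError(f"[quant] {exc}") from exc

    fc_for_kinase = site_fc
    if config.fasta_source and config.fasta_target and config.ortholog_pairs:
        try:
            _stage("map")
            pairs = read_ortholog_pairs(config.ortholog_pairs)
            mapped = map_sites(
                site_fc,
                read_fasta(config.fasta_source),
                read_fasta(config.fasta_target),
                pairs,
                scoring=config.scoring(),
            )
            outputs["mapped_fc"] = out / "mapped_fc.tsv"
            mapped.to_csv(outputs["mapped_fc"], sep="\t", index=False)
            fc_for_kinase = mapped
        except Exception as exc:
            raise RuntimeError(f"[map] {exc}") from exc

    if config.ks_annotation:
        try:
            _stage("kinact")
            annotation = read_ks_annotation(config.ks_annotation)
            activities = infer_activities(
                fc_for_kinase,
                annotation,
                min_substrates=config.min_substrates,
                alpha=config.kinase_alpha,
            )
            outputs["kinase_activity"] = out / "kinase_activity.tsv"
            activities.to_csv(outputs["kinase_activity"], sep="\t", index=False, float_format="%.10g")
            ligs = sorted(set(activities["condition"]))
            if len(ligs) >= 2:
                dz = contrast_deltas(activities, ligs[0], ligs[1])
                outputs["kinase_contrast_dz"] = out / "kinase_contrast_dz.tsv"
                dz.to_csv(outputs["kinase_contrast_dz"], sep="\t", index=False, float_format="%.10g")
        except Exception as exc:
            raise RuntimeError(f"[kinact] {exc}") from exc

    if config.edges:
        try:
            _stage("network")
            edges_df = read_edge_table(config.edges)
            terms = read_gmt(config.terms) if config.terms else None
            universe = set(site_stats["site_key"].str.split("_").str[0])
            timepoints = sorted(site_stats["timepoint"].astype(str).unique())
            for ligand in sorted(set(site_stats["condition"])):
                core = select_changed_proteins(site_stats, fdr=config.fdr, ligand=ligand)
                g = build_network(core, edges_df, threshold=config.edge_threshold)
                g = expand_network(
                    g, edges_df, threshold=config.edge_threshold,
                    max_added=config.max_expansion_nodes,
                )
                g = attach_phospho_states(g, site_stats, ligand, timepoints, alpha=config.fdr)
                outputs[f"network_{ligand}"] = out / f"network_{ligand}.json"
                outputs[f"network_{ligand}_edges"] = out / f"network_{ligand}_edges.tsv"
                write_network(g, outputs[f"network_{ligand}"], outputs[f"network_{ligand}_edges"])
                if terms is not None and core:
                    enr = hypergeom_enrichment(core & universe, terms, universe, fdr_threshold=config.fdr)
                    enr = remove_redundant_terms(enr, cutoff=config.redundancy_cutoff)
                    outputs[f"enrichment_{ligand}"] = out / f"enrichment_{ligand}.tsv"
                    enr.to_csv(outputs[f"enrichment_{ligand}"], sep="\t", index=False, float_format="%.10g")
        except Exception as exc:
            raise RuntimeError(f"[network] {exc}") from exc

    for name in ("measurements", "fasta_source", "fasta_target", "ortholog_pairs", "ks_annotation", "edges", "terms"):
        path = getattr(config, name)
        if path and Path(path).exists():
            input_paths[name] = _sha256(Path(path))
    manifest = {
        "phosphokin_version": __version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "simulate_kwargs"
        },
        "input_sha256": input_paths,
        "outputs": {k: str(v) for k, v in sorted(outputs.items())},
    }
    outputs["manifest"] = out / "manifest.json"
    outputs["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return outputs
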