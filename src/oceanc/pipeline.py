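"""End-to-end pipeline: config validation, stage chaining, run manifest.

Stages run in the analysis order: digest -> filter-pairs -> call-hoci ->
annotate -> network -> gene-types, with optional super-enhancer, broad
domain and contact-matrix/compartment stages.  Every stage exchanges data
only through declared file formats in the output directory, so any stage
can be re-run from its upstream files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import domains as dom
from . import genes as gn
from . import hoci as hc
from . import matrix as mx
from . import network as net
from . import pairs as pr
from .genome import GenomeAssembly, digest, write_bed

log = logging.getLogger("oceanc")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """All stage parameters with their standard defaults."""

    genome_fasta: str = ""
    pairs_bedpe: str = ""
    genes_bed: str = ""
    expression_tsv: str = ""
    h3k4me3_bed: str = ""
    h3k4me1_bed: str = ""
    h3k27ac_bed: str = ""
    out_dir: str = "oceanc_out"
    chromosomes: list[str] | None = None  # include-list; None = all in FASTA

    restriction_site: str = "GATC"
    mapq_min: int = 1
    min_separation: int = 1000
    deduplicate: bool = True
    bin_bp: int = 50
    q_threshold: float = 0.05
    min_peak_width: int = 150
    merge_gap: int = 200
    peak_mode: str = "narrow"
    promoter_up: int = 2000
    stitch_gap: int = 12500
    tss_exclusion: int = 2000
    broad_fraction: float = 0.05
    resolution: int = 40000
    rpkm_cutoff: float = 0.5
    min_edge_weight: int = 1
    seed: int = 0
    run_matrix: bool = True

    def validate(self) -> None:
        problems = []
        if not (0 < self.q_threshold <= 1):
            problems.append(f"q_threshold {self.q_threshold} outside (0, 1]")
        if not (0 < self.broad_fraction <= 1):
            problems.append(f"broad_fraction {self.broad_fraction} outside (0, 1]")
        if self.min_separation < 0:
            problems.append("min_separation must be >= 0")
        if self.bin_bp <= 0 or self.resolution <= 0:
            problems.append("bin_bp and resolution must be positive")
        if self.peak_mode not in ("narrow", "broad"):
            problems.append(f"unknown peak_mode {self.peak_mode!r}")
        for label, path in [("genome_fasta", self.genome_fasta),
                            ("pairs_bedpe", self.pairs_bedpe)]:
            if not path or not Path(path).exists():
                problems.append(f"missing required input {label}: {path!r}")
        for label, path in [("genes_bed", self.genes_bed),
                            ("expression_tsv", self.expression_tsv),
                            ("h3k4me3_bed", self.h3k4me3_bed),
                            ("h3k4me1_bed", self.h3k4me1_bed),
                            ("h3k27ac_bed", self.h3k27ac_bed)]:
            if path and not Path(path).exists():
                problems.append(f"input {label} does not exist: {path!r}")
        if problems:
            raise ValueError("invalid pipeline config:\n  " + "\n  ".join(problems))

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


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the run manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": dataclasses.asdict(config),
        "inputs": {},
        "stages": {},
    }
    for label in ("genome_fasta", "pairs_bedpe", "genes_bed", "expression_tsv",
                  "h3k4me3_bed", "h3k4me1_bed", "h3k27ac_bed"):
        path = getattr(config, label)
        if path:
            manifest["inputs"][label] = {"path": path, "sha256_16": _checksum(path)}

    def _stage(name):
        log.info("stage %s", name)

    try:
        _stage("digest")
        assembly = GenomeAssembly.from_fasta(config.genome_fasta, config.chromosomes)
        fragmap = digest(assembly, config.restriction_site)
        write_bed(out / "fragments.bed", fragmap.to_bed(),
                  columns=["chrom", "start", "end", "name"])
        manifest["stages"]["digest"] = {"n_fragments": fragmap.n_fragments}
    except Exception as e:  # noqa: BLE001
        raise StageError("digest", e) from e

    try:
        _stage("filter-pairs")
        raw = pr.read_bedpe(config.pairs_bedpe)
        on_included = raw["chrom1"].isin(assembly.lengths) & raw["chrom2"].isin(assembly.lengths)
        raw = raw[on_included].reset_index(drop=True)
        valid, counts = pr.filter_pairs(raw, fragmap, config.mapq_min,
                                        config.min_separation,
                                        deduplicate=config.deduplicate)
        pr.write_pairs(out / "valid.pairs", valid)
        pd.Series(counts).rename_axis("class").to_frame("count").to_csv(
            out / "pair_classes.tsv", sep="\t")
        manifest["stages"]["filter_pairs"] = counts
    except Exception as e:  # noqa: BLE001
        raise StageError("filter-pairs", e) from e

    try:
        _stage("call-hoci")
        track = hc.build_coverage(valid, assembly, config.bin_bp)
        hocis = hc.call_hoci(track, config.q_threshold,
                             min_width=config.min_peak_width,
                             merge_gap=config.merge_gap, mode=config.peak_mode)
        manifest["stages"]["call_hoci"] = {"n_hoci": len(hocis),
                                           "total_ends": track.total_ends}
    except Exception as e:  # noqa: BLE001
        raise StageError("call-hoci", e) from e

    genes = gn.read_genes_bed(config.genes_bed) if config.genes_bed else None
    have_marks = all([config.h3k4me3_bed, config.h3k4me1_bed, config.h3k27ac_bed])
    if genes is not None and have_marks:
        try:
            _stage("annotate")
            from .genome import read_bed

            hocis = ann.classify_hoci(
                hocis, read_bed(config.h3k4me3_bed), read_bed(config.h3k4me1_bed),
                read_bed(config.h3k27ac_bed), genes, assembly, config.promoter_up)
            manifest["stages"]["annotate"] = (
                hocis["hoci_class"].value_counts().to_dict())
        except Exception as e:  # noqa: BLE001
            raise StageError("annotate", e) from e
    hocis.to_csv(out / "hoci.tsv", sep="\t", index=False)
    write_bed(out / "hoci.bed", hocis.assign(
        name=[f"hoci_{i}" for i in range(len(hocis))], score=hocis["score"].round(2),
        strand="."))

    if "hoci_class" in hocis.columns:
        try:
            _stage("network")
            g = net.build_network(valid, hocis, config.min_edge_weight)
            net.network_to_edgelist(g).to_csv(out / "network_edges.tsv", sep="\t",
                                              index=False)
            cat = net.categorize_pairs(valid, hocis)
            dist = net.distance_summary(cat)
            dist.to_csv(out / "distance_by_category.tsv", sep="\t", index=False)
            manifest["stages"]["network"] = {
                "n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges(),
                "mean_interactions": float(np.mean([
                    d["interaction_count"] for _, d in g.nodes(data=True)
                ])) if g.number_of_nodes() else 0.0,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("network", e) from e

    if genes is not None and config.expression_tsv:
        try:
            _stage("gene-types")
            expr = gn.read_expression(config.expression_tsv)
            types = gn.type_genes(genes, hocis, valid, assembly, config.promoter_up)
            summary = gn.expression_by_type(genes, types, expr, config.rpkm_cutoff)
            typed = genes[["gene_id", "chrom", "strand", "tss"]].copy()
            typed["gene_type"] = typed["gene_id"].map(types)
            typed["rpkm"] = typed["gene_id"].map(expr)
            typed.to_csv(out / "gene_types.tsv", sep="\t", index=False)
            with open(out / "gene_type_summary.json", "w") as fh:
                json.dump(summary, fh, indent=1)
            manifest["stages"]["gene_types"] = {
                t: summary["per_type"][t]["n"] for t in summary["per_type"]}
        except Exception as e:  # noqa: BLE001
            raise StageError("gene-types", e) from e

    if config.run_matrix:
        try:
            _stage("matrix")
            mats = mx.bin_pairs(valid, assembly, config.resolution)
            comp_rows = []
            for chrom, m in mats.items():
                if m.counts.sum() == 0:
                    continue
                bal = mx.ice_balance(m)
                try:
                    comp = mx.compartments(bal, hocis[hocis["chrom"] == chrom])
                except ValueError:
                    continue
                comp["chrom"] = chrom
                comp_rows.append(comp)
            if comp_rows:
                pd.concat(comp_rows, ignore_index=True).to_csv(
                    out / "compartments.tsv", sep="\t", index=False)
            manifest["stages"]["matrix"] = {"n_chroms": len(mats),
                                            "resolution": config.resolution}
        except Exception as e:  # noqa: BLE001
            raise StageError("matrix", e) from e

    # Table-S1-style run summary
    summary_rows = [{"metric": k, "value": v}
                    for k, v in manifest["stages"].get("filter_pairs", {}).items()]
    summary_rows.append({"metric": "n_hoci",
                         "value": manifest["stages"]["call_hoci"]["n_hoci"]})
    pd.DataFrame(summary_rows).to_csv(out / "summary.tsv", sep="\t", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
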