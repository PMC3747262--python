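"""End-to-end orchestration from a single run configuration.

A run either simulates a synthetic study (``simulate`` section) or loads
existing tables (``inputs`` section), then processes each cell type
independently: normalization, probe statistics, region calls for the group
contrast and for each requested phenotype analyte, and annotation of called
regions.  All outputs are plain TSV/BED files with a provenance comment
(package version + configuration hash) and the run is deterministic for a
fixed configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as tio
from .annotate import annotate_regions, summarize_overlaps
from .errors import InvalidSpecError
from .normalize import normalize_study
from .probestats import GroupDesign, moderated_t
from .regions import CallingThresholds, run_contrast_pipeline, run_correlation_pipeline
from .simulate import (
    LocusSpec,
    PhenotypeLink,
    PlantedDMR,
    SimulationSpec,
    simulate_cohort,
    simulate_phenotype,
    simulate_tracks,
    study_gene_models,
)

log = logging.getLogger("tilemeth")


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    thresholds: CallingThresholds = field(default_factory=CallingThresholds)
    cell_types: list[str] | None = None
    analytes: list[str] | None = None
    replicate_reduction: str = "mean"
    tracks_spec: dict | None = None  # simulate-mode regulatory tracks

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "out_dir" not in raw:
            raise InvalidSpecError("config: out_dir is required")
        thr = raw.pop("thresholds", {})
        known = {f.name for f in fields(CallingThresholds)}
        unknown = set(thr) - known
        if unknown:
            raise InvalidSpecError(f"config: unknown threshold fields {sorted(unknown)}")
        cfg = cls(
            out_dir=str(raw.pop("out_dir")),
            seed=int(raw.pop("seed", 0)),
            simulate=raw.pop("simulate", None),
            inputs=raw.pop("inputs", None),
            thresholds=CallingThresholds(**thr),
            cell_types=raw.pop("cell_types", None),
            analytes=raw.pop("analytes", None),
            replicate_reduction=raw.pop("replicate_reduction", "mean"),
            tracks_spec=raw.pop("tracks", None),
        )
        if raw:
            raise InvalidSpecError(f"config: unknown top-level keys {sorted(raw)}")
        if (cfg.simulate is None) == (cfg.inputs is None):
            raise InvalidSpecError("config: exactly one of 'simulate' or 'inputs' is required")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise InvalidSpecError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def digest(self) -> str:
        payload = {
            "seed": self.seed,
            "simulate": self.simulate,
            "inputs": self.inputs,
            "thresholds": asdict(self.thresholds),
            "cell_types": self.cell_types,
            "analytes": self.analytes,
            "replicate_reduction": self.replicate_reduction,
            "tracks": self.tracks_spec,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def build_simulation_spec(raw: dict, seed: int) -> SimulationSpec:
    """Assemble a SimulationSpec from the plain-dict form used in YAML configs."""
    raw = dict(raw)

    def _as(cls, item):
        return cls(**item) if isinstance(item, dict) else cls(*item)

    loci = tuple(_as(LocusSpec, l) for l in raw.pop("loci"))
    dmrs = tuple(_as(PlantedDMR, d) for d in raw.pop("planted_dmrs", []))
    links = tuple(_as(PhenotypeLink, l) for l in raw.pop("phenotype_links", []))
    return SimulationSpec(loci=loci, planted_dmrs=dmrs, phenotype_links=links, seed=seed, **raw)


def _prov(config: RunConfig) -> list[str]:
    return [f"tilemeth {__version__} config={config.digest()}"]


def _load_inputs(config: RunConfig):
    paths = config.inputs
    design = tio.read_probe_design(paths["design"])
    intensities = tio.read_intensities(paths["intensities"], design)
    sheet = tio.read_sample_sheet(paths["samples"])
    phenotype = tio.read_phenotypes(paths["phenotype"]) if paths.get("phenotype") else None
    genes = tio.read_gene_models(paths["genes"]) if paths.get("genes") else None
    tracks = [tio.read_bed(p) for p in paths.get("tracks", [])]
    return design, intensities, sheet, phenotype, genes, tracks, None


def _simulate_inputs(config: RunConfig, out_inputs: str):
    spec = build_simulation_spec(config.simulate, config.seed)
    intensities, sheet, truth = simulate_cohort(spec)
    design = truth.design
    phenotype = simulate_phenotype(truth) if spec.phenotype_links else None
    genes = study_gene_models(spec.loci)
    tspec = config.tracks_spec or {}
    tracks = simulate_tracks(
        design,
        density=tspec.get("density", 1.0),
        mean_width=tspec.get("mean_width", 500),
        names=tspec.get("names", ["NFkB", "PU.1", "c-Jun", "STAT1"]),
        seed=config.seed,
        track_names=tspec.get("track_names", ("TFBS", "DNase")),
    )
    prov = _prov(config)
    tio.write_probe_design(design, os.path.join(out_inputs, "design.tsv"))
    tio.write_sample_sheet(sheet, os.path.join(out_inputs, "samples.tsv"))
    if phenotype is not None:
        tio.write_phenotypes(phenotype, os.path.join(out_inputs, "phenotype.tsv"))
    truth_bed = truth.dmr_table()
    tio._write_table(truth_bed, os.path.join(out_inputs, "truth.bed"), provenance=prov)
    for track in tracks:
        tio.write_bed(track, os.path.join(out_inputs, f"track_{track.name}.bed"))
    return design, intensities, sheet, phenotype, genes, tracks, truth


def _calls_to_bed(calls: pd.DataFrame) -> pd.DataFrame:
    called = calls[calls["called"]]
    q = called["q_region"].clip(lower=1e-30)
    return pd.DataFrame(
        {
            "chrom": called["chrom"],
            "start": called["start"],
            "end": called["end"],
            "name": called["direction"],
            "score": -10.0 * np.log10(q),
        }
    )


def run_all(config: RunConfig) -> dict:
    """Execute the configured study end to end; returns the run report dict."""
    t_start = time.time()
    os.makedirs(config.out_dir, exist_ok=True)
    out_inputs = os.path.join(config.out_dir, "inputs")
    os.makedirs(out_inputs, exist_ok=True)
    prov = _prov(config)

    stage = "load-inputs"
    try:
        if config.simulate is not None:
            design, intensities, sheet, phenotype, genes, tracks, truth = _simulate_inputs(
                config, out_inputs
            )
        else:
            design, intensities, sheet, phenotype, genes, tracks, truth = _load_inputs(config)

        cell_types = config.cell_types or sorted(sheet["cell_type"].unique())
        analytes = config.analytes
        if analytes is None and phenotype is not None:
            analytes = sorted(phenotype["analyte"].unique())
        analytes = analytes or []

        report: dict = {
            "version": __version__,
            "config_hash": config.digest(),
            "seed": config.seed,
            "thresholds": asdict(config.thresholds),
            "cell_types": {},
        }
        group_design = GroupDesign.from_sample_sheet(sheet)
        for cell in cell_types:
            stage = f"normalize[{cell}]"
            log.info("stage %s", stage)
            matrix = normalize_study(intensities, sheet, cell, method=config.replicate_reduction)
            tio.write_matrix(matrix, os.path.join(config.out_dir, f"matrix_{cell}.tsv"), prov)

            stage = f"probe-stats[{cell}]"
            probe_table, eb = moderated_t(matrix, group_design)
            tio._write_table(
                probe_table, os.path.join(config.out_dir, f"probes_{cell}.tsv"), provenance=prov
            )

            stage = f"dmr-call[{cell}]"
            calls = run_contrast_pipeline(matrix, group_design, design, config.thresholds)
            tio._write_table(
                calls, os.path.join(config.out_dir, f"calls_{cell}.tsv"), provenance=prov
            )
            tio._write_table(
                _calls_to_bed(calls), os.path.join(config.out_dir, f"calls_{cell}.bed"), provenance=prov
            )

            corr_counts = {}
            corr_frames = []
            for analyte in analytes:
                stage = f"correlate[{cell}:{analyte}]"
                corr = run_correlation_pipeline(
                    matrix, phenotype, analyte, design, config.thresholds
                )
                corr_frames.append(corr)
                corr_counts[analyte] = int(corr["called"].sum())
                tio._write_table(
                    corr,
                    os.path.join(config.out_dir, f"corr_{cell}_{analyte}.tsv"),
                    provenance=prov,
                )

            stage = f"annotate[{cell}]"
            cell_report = {
                "n_regions_tested": int(calls["testable"].sum()),
                "n_dmrs_called": int(calls["called"].sum()),
                "dmrs_per_locus": calls[calls["called"]].groupby("locus_id").size().to_dict(),
                "correlation_calls": corr_counts,
            }
            if genes is not None:
                called = calls[calls["called"]].reset_index(drop=True)
                records = annotate_regions(called, genes, tracks)
                tio._write_table(
                    records.astype({"promoter": str} | {f"{t.name}_overlap": str for t in tracks}),
                    os.path.join(config.out_dir, f"annotated_{cell}.tsv"),
                    provenance=prov,
                )
                cell_report["n_promoter_dmrs"] = int(records["promoter"].sum())
                cell_report["track_overlap_counts"] = summarize_overlaps(records, tracks)
            report["cell_types"][cell] = cell_report

        if truth is not None and truth.spec.planted_dmrs:
            report["ground_truth"] = {"n_planted_dmrs": len(truth.spec.planted_dmrs)}
        report["elapsed_s"] = round(time.time() - t_start, 3)
        report_path = os.path.join(config.out_dir, "report.json")
        with open(report_path, "w") as fh:
            json.dump({k: v for k, v in report.items() if k != "elapsed_s"}, fh, sort_keys=True, indent=2, default=str)
        return report
    except Exception as exc:
        from .errors import PipelineError

        raise PipelineError(f"stage {stage}: {exc}") from exc
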