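"""End-to-end pipeline: one config, one output directory, one manifest.

Stage order: (simulate?) -> read -> clean -> half-minimum imputation ->
log2 + autoscale -> paired fold change -> Spearman matrix -> NRR matrix ->
NRR histogram -> NRR filter -> lipid-lipid pruning -> network assembly ->
strong candidates -> per-feature group tests -> antipsychotic confounder
scan. Every stage writes its tabular output; the run manifest echoes every
parameter (so "default parameters" is never ambiguous), lists dropped
features, and records stage timings. Output depends only on (inputs,
config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import group_stats, io, network, preprocess, simulate
from .association import NRRConfig, nrr_histogram, nrr_matrix, spearman_matrix
from .io import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of inputs / simulate present."""

    output_dir: str = "nrrnet_out"
    seed: int = 0
    # real inputs
    feature_table: str | None = None
    metadata: str | None = None
    catalog: str | None = None
    # or a synthetic cohort
    simulate: dict[str, Any] | None = None
    # NRR estimation
    nrr: dict[str, Any] = field(default_factory=dict)
    # thresholds
    nrr_threshold: float = 0.1
    rho_threshold: float = 0.5
    group_test_scale: str = "log2"
    autoscale_ddof: int = 1

    def __post_init__(self) -> None:
        has_inputs = self.feature_table is not None
        if has_inputs == (self.simulate is not None):
            raise ValidationError(
                "config must provide exactly one of {feature_table/metadata/catalog, simulate}"
            )
        if has_inputs and (self.metadata is None or self.catalog is None):
            raise ValidationError("feature_table requires metadata and catalog paths")
        for name, t in (("nrr_threshold", self.nrr_threshold), ("rho_threshold", self.rho_threshold)):
            if not 0 <= t <= 1:
                raise ValidationError(f"{name} must be in [0,1], got {t}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def nrr_config(self) -> NRRConfig:
        params = dict(self.nrr)
        params.setdefault("seed", self.seed)
        return NRRConfig(**params)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_matrix(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.17g")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": {k: v for k, v in asdict(config).items()},
        "nrr_config": asdict(config.nrr_config()),
        "seed": config.seed,
        "outputs": {},
        "dropped_features": [],
        "timings_s": {},
    }
    written: list[Path] = []
    stage = "setup"

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path)
        written.append(path)

    t_stage = time.perf_counter()

    def tick(name: str) -> None:
        nonlocal t_stage
        manifest["timings_s"][name] = round(time.perf_counter() - t_stage, 4)
        t_stage = time.perf_counter()

    try:
        stage = "inputs"
        if config.simulate is not None:
            sim = dict(config.simulate)
            sim_keys = {"n_pairs", "pair_effect_sd", "antipsychotic_fraction"}
            cohort_kwargs = {k: sim.pop(k) for k in list(sim) if k in sim_keys}
            sim.setdefault("seed", config.seed)
            truth = simulate.make_ground_truth(**sim)
            cohort = simulate.simulate_cohort(truth, seed=config.seed, **cohort_kwargs)
            table, metadata, catalog = cohort.table, cohort.metadata, cohort.catalog
            paths = simulate.write_cohort(cohort, out / "cohort")
            for k, v in paths.items():
                emit(k, Path(v))
            logger.info("simulated cohort: %d samples x %d features",
                        len(table.sample_ids), len(table.feature_ids))
        else:
            table = io.read_feature_table(config.feature_table)
            metadata = io.read_metadata(config.metadata)
            catalog = io.read_catalog(config.catalog)
        tick("inputs")

        stage = "preprocess"
        n_before = list(table.feature_ids)
        scaled, fc = preprocess.preprocess_table(table, metadata, ddof=config.autoscale_ddof)
        manifest["dropped_features"] = sorted(set(n_before) - set(scaled.feature_ids))
        manifest["conventions"] = {
            "autoscale_sd": "sample (ddof=1)" if config.autoscale_ddof == 1 else
            f"ddof={config.autoscale_ddof}",
            "autoscale_stratum": "all samples jointly, before pairing",
            "half_minimum": "half of the minimum strictly-positive value per feature",
        }
        _write_matrix(fc.to_frame(), out / "fold_change.tsv")
        emit("fold_change", out / "fold_change.tsv")
        tick("preprocess")

        stage = "association"
        rho = spearman_matrix(fc)
        nrr = nrr_matrix(fc, config.nrr_config())
        hist = nrr_histogram(nrr)
        _write_matrix(rho.to_frame(), out / "spearman.tsv")
        _write_matrix(nrr.to_frame(), out / "nrr.tsv")
        hist.to_csv(out / "nrr_histogram.tsv", sep="\t", index=False, float_format="%.17g")
        emit("spearman", out / "spearman.tsv")
        emit("nrr", out / "nrr.tsv")
        emit("nrr_histogram", out / "nrr_histogram.tsv")
        tick("association")

        stage = "network"
        edges = network.filter_nonspurious(rho, nrr, config.nrr_threshold, catalog=catalog)
        edges = network.prune_lipid_lipid(edges, catalog)
        graph = network.build_network(edges, catalog)
        io.write_edge_list(edges, out / "edges.tsv", catalog=catalog)
        io.write_graphml(graph, out / "network.graphml")
        emit("edges", out / "edges.tsv")
        emit("network", out / "network.graphml")
        logger.info("retained %d non-spurious mediator-involved edges", len(edges))
        tick("network")

        stage = "group_tests"
        group_results = group_stats.per_feature_group_test(
            table, metadata, scale=config.group_test_scale
        )
        gt_frame = pd.DataFrame(
            [
                (r.feature_id, r.mean_patient, r.mean_control, r.p_value, r.significant)
                for r in group_results
            ],
            columns=["feature_id", "mean_patient", "mean_control", "p_value", "significant"],
        )
        gt_frame.to_csv(out / "group_tests.tsv", sep="\t", index=False, float_format="%.17g")
        emit("group_tests", out / "group_tests.tsv")
        tick("group_tests")

        stage = "candidates"
        cands = network.strong_candidates(edges, config.rho_threshold)
        cands = network.orient_candidates(cands, catalog)
        p_by_feature = {r.feature_id: r for r in group_results}
        cands = [
            network.CandidateRecord(
                c.mediator,
                c.lipid,
                c.rho,
                c.nrr,
                p_by_feature[c.lipid].p_value if c.lipid in p_by_feature else None,
                p_by_feature[c.lipid].significant if c.lipid in p_by_feature else None,
            )
            for c in cands
        ]
        io.write_candidates(cands, out / "candidates.tsv")
        emit("candidates", out / "candidates.tsv")
        logger.info("identified %d strong candidate associations", len(cands))
        tick("candidates")

        stage = "confounders"
        scan_frames = []
        for scale in ("log2", "concentration"):
            scan = group_stats.confounder_scan(table, metadata, scale=scale)
            scan_frames.append(
                pd.DataFrame(
                    [
                        (scale, r.feature_id, r.coefficient, r.p_raw, r.p_bh,
                         r.p_bonferroni, r.flagged)
                        for r in scan
                    ],
                    columns=["scale", "feature_id", "coefficient", "p_raw", "p_bh",
                             "p_bonferroni", "flagged"],
                )
            )
        pd.concat(scan_frames, ignore_index=True).to_csv(
            out / "confounder_scan.tsv", sep="\t", index=False, float_format="%.17g"
        )
        emit("confounder_scan", out / "confounder_scan.tsv")
        tick("confounders")

    except Exception as exc:
        for path in written:
            if path.exists() and path.is_file():
                path.rename(path.with_name(path.name + ".partial"))
        raise PipelineError(stage, exc) from exc

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
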