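"""End-to-end saturation workflow: ingest/simulate, QC, cluster, downsample,
re-cluster, compare, complexity, verdict — with a reproducibility manifest."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .cluster import ClusteringParams, cluster_pipeline
from .complexity import cluster_centroids, complexity_index, saturation_report
from .downsample import nested_halving
from .errors import ConfigError
from .io import CountMatrix, read_10x_h5, read_mtx_dir, write_labels, write_overlap_csv
from .metrics import compare_analyses
from .qc import QCParams, qc_filter
from .simulate import SimConfig, simulate

logger = logging.getLogger("satkit.pipeline")

DEFAULT_CONFIG = {
    "input": None,  # path to an MTX directory or 10x h5; or null with simulate
    "simulate": None,  # SimConfig fields, or null
    "seed": 0,
    "qc": {},  # QCParams fields
    "clustering": {},  # ClusteringParams fields
    "n_levels": 4,
    "n_replicates": 2,
    "threshold": 0.6,
    "min_points": 3,
}


def _load_matrix(config: dict, seed: int) -> CountMatrix:
    if config.get("input"):
        path = Path(config["input"])
        if not path.exists():
            raise ConfigError(f"input path does not exist: {path}")
        if path.is_dir():
            return read_mtx_dir(path)
        return read_10x_h5(path)
    if config.get("simulate") is not None:
        sim = dict(config["simulate"])
        sim.setdefault("seed", seed)
        return simulate(SimConfig(**sim))
    raise ConfigError("config needs either an 'input' path or a 'simulate' section")


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run every stage and write labels, comparisons, curves and the verdict.

    ``config`` may be a dict or the path of a JSON file with the
    :data:`DEFAULT_CONFIG` keys. Returns the summary dict that is also
    written as ``report.json``. Fails fast with the offending stage named.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = json.load(fh)
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"version": __version__, "config": cfg, "stages": {}}

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"started": time.time()}

    def done(name, **extra):
        rec = manifest["stages"][name]
        rec["seconds"] = round(time.time() - rec.pop("started"), 3)
        rec.update(extra)

    try:
        stage("load")
        matrix = _load_matrix(cfg, seed)
        done("load", n_genes=matrix.n_genes, n_cells=matrix.n_cells)

        stage("qc")
        matrix, report = qc_filter(matrix, QCParams(**cfg["qc"]))
        report.write_tsv(out / "qc_report.tsv")
        done("qc", kept=report.n_kept, removed=report.n_removed)

        stage("cluster_full")
        params = ClusteringParams(**{**cfg["clustering"], "louvain_seed": seed})
        full, space = cluster_pipeline(matrix, params, analysis_id="full")
        write_labels(full, out / "labels_full.tsv")
        done("cluster_full", n_clusters=len(set(full.labels)), n_significant=space.n_significant)

        stage("downsample_and_compare")
        records = []
        rng = np.random.default_rng(seed)
        for rep in range(int(cfg["n_replicates"])):
            rep_seed = int(rng.integers(2**31 - 1))
            series = nested_halving(matrix.barcodes, int(cfg["n_levels"]), seed=rep_seed)
            for level, subset in enumerate(series, start=1):
                sub_matrix = matrix.subset_cells(subset)
                sub_params = ClusteringParams(**{**cfg["clustering"], "louvain_seed": rep_seed + level})
                sub_assign, _ = cluster_pipeline(
                    sub_matrix, sub_params, analysis_id=f"r{rep}_l{level}"
                )
                write_labels(sub_assign, out / f"labels_r{rep}_l{level}.tsv")
                summary = compare_analyses(full, sub_assign)
                write_overlap_csv(summary.overlap, out / f"overlap_r{rep}_l{level}.csv")
                labels, cents = cluster_centroids(space, sub_assign)
                tree = complexity_index(labels, cents)
                records.append(
                    {
                        "replicate": rep,
                        "level": level,
                        "n_cells": len(subset),
                        "n_clusters": len(set(sub_assign.labels)),
                        "mean_preservation": summary.mean_preservation,
                        "mean_conservation": summary.mean_conservation,
                        "adjusted_rand": summary.adjusted_rand,
                        "complexity": tree.index,
                    }
                )
        done("downsample_and_compare", n_comparisons=len(records))

        stage("saturation")
        full_labels_list, full_cents = cluster_centroids(space, full)
        full_tree = complexity_index(full_labels_list, full_cents)
        report_dict = saturation_report(
            records, threshold=float(cfg["threshold"]), min_points=int(cfg["min_points"])
        )
        curves = report_dict["by_cells"]
        curves.points.to_csv(out / "curve_cells.tsv", sep="\t", index=False)
        curves.r2_scan.to_csv(out / "r2_scan_cells.tsv", sep="\t", index=False)
        report_dict["by_complexity"].points.to_csv(out / "curve_complexity.tsv", sep="\t", index=False)
        report_dict["by_complexity"].r2_scan.to_csv(out / "r2_scan_complexity.tsv", sep="\t", index=False)
        report_dict["cluster_counts"].to_csv(out / "cluster_counts.tsv", sep="\t", index=False)
        from .complexity import plot_saturation

        plot_saturation(report_dict["by_cells"], out / "saturation_cells.png")
        plot_saturation(report_dict["by_complexity"], out / "saturation_complexity.png")
        done("saturation", verdict=report_dict["verdict"])
    except Exception as exc:
        failing = next(
            (n for n, r in manifest["stages"].items() if "seconds" not in r), "unknown"
        )
        raise type(exc)(f"stage {failing!r} failed: {exc}") from exc

    summary = {
        "verdict": report_dict["verdict"],
        "verdict_by_cells": report_dict["by_cells"].verdict,
        "verdict_by_complexity": report_dict["by_complexity"].verdict,
        "n_clusters_full": len(set(full.labels)),
        "complexity_full": full_tree.index,
        "records": records,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return summary
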