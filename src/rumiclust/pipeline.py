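"""End-to-end pipeline: cohort filter -> DTW -> clustering -> selection ->
phenotype statistics, with every intermediate written to a run directory.

The stages are the library functions; this module only sequences them,
logs one line per stage, and writes the artifacts (distance matrix, merge
history, assignments, ordination, selection, LS means, fitted circadian
curves, 2-h correlations) plus a manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .cluster import (agglomerative_cluster, cut_tree, pcoa, select_extremes)
from .dtw import DTWConfig, UnusableCowError, pairwise_distances, preprocess_series
from .simulate import (SimConfig, config_from_dict, config_to_dict,
                       simulate_herd, truth_table, write_fixture)
from .stats import RESPONSES, correlate_2h, derive_daily, fit_gam, fit_lmm

__all__ = ["PipelineConfig", "PipelineStageError", "filter_cohort",
           "run_pipeline", "load_config", "save_config"]

logger = logging.getLogger("rumiclust")


class PipelineStageError(RuntimeError):
    """A stage failed; earlier artifacts are preserved in the run directory."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Either ``simulate`` holds a :class:`~rumiclust.simulate.SimConfig` or the
    three input CSV paths (and a truth-style metadata CSV with parity/DIM)
    must be given.
    """

    simulate: SimConfig | None = None
    sensor_path: str | None = None
    emissions_path: str | None = None
    production_path: str | None = None
    metadata_path: str | None = None
    dim_max: int = 150
    max_gap_hours: int = 3
    dtw: DTWConfig = field(default_factory=DTWConfig)
    linkage: str = "average"
    k: int = 2
    n_per_cluster: int = 10
    blocking: tuple[str, ...] = ("parity", "dim", "my")
    window: tuple[str, str] | None = None   # inclusive ISO date range
    out_dir: str = "run"
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.dim_max <= 0:
            raise ValueError("dim_max must be > 0")
        if self.simulate is None:
            for name in ("sensor_path", "emissions_path", "production_path",
                         "metadata_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} must point to an existing file "
                                     "when no simulate block is given")


def config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.simulate is not None:
        d["simulate"] = config_to_dict(config.simulate)
    d["dtw"] = {"window_radius": config.dtw.window_radius,
                "normalize": config.dtw.normalize}
    d["blocking"] = list(config.blocking)
    if config.window is not None:
        d["window"] = list(config.window)
    return d


def config_from_mapping(d: dict) -> PipelineConfig:
    d = dict(d)
    sim = d.pop("simulate", None)
    dtw = d.pop("dtw", None)
    cfg = PipelineConfig(
        simulate=config_from_dict(sim) if sim is not None else None,
        dtw=DTWConfig(**dtw) if dtw else DTWConfig(),
        **{k: (tuple(v) if k in ("blocking", "window") and v is not None else v)
           for k, v in d.items()})
    return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_mapping(yaml.safe_load(fh))


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict(config), fh, sort_keys=False)


def filter_cohort(metadata: pd.DataFrame, dim_max: int = 150) -> list[str]:
    """Cows with 0 < DIM <= dim_max (early-to-mid lactation)."""
    if "dim" not in metadata.columns:
        raise ValueError("metadata needs a 'dim' column")
    keep = metadata[(metadata["dim"] > 0) & (metadata["dim"] <= dim_max)]
    excluded = len(metadata) - len(keep)
    logger.info("filter_cohort: kept %d cows, excluded %d (DIM > %d or <= 0)",
                len(keep), excluded, dim_max)
    if len(keep) == 0:
        raise ValueError(f"no cows left with 0 < DIM <= {dim_max}")
    return [str(c) for c in keep["cow_id"]]


def _apply_window(df: pd.DataFrame, window) -> pd.DataFrame:
    if window is None:
        return df
    lo, hi = window
    return df[(df["date"] >= lo) & (df["date"] <= hi)]


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and return the artifact paths."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.setLevel(config.log_level.upper())
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)

    artifacts: dict[str, Path] = {}
    stage = "inputs"
    try:
        if config.simulate is not None:
            sim = config.simulate
            if config.seed is not None:
                sim = dataclasses.replace(sim, seed=config.seed)
            dataset, truths = simulate_herd(sim)
            write_fixture(dataset, out / "inputs")
            sensor, emissions, production = (dataset.sensor, dataset.emissions,
                                             dataset.production)
            metadata = truth_table(truths)
            artifacts["inputs"] = out / "inputs"
        else:
            sensor = hio.read_sensor(config.sensor_path)
            emissions = hio.read_emissions(config.emissions_path)
            production = hio.read_production(config.production_path)
            metadata = hio.read_truth(config.metadata_path)
        sensor = _apply_window(sensor, config.window)
        emissions = _apply_window(emissions, config.window)
        production = _apply_window(production, config.window)
        logger.info("inputs: %d sensor, %d emission, %d production rows",
                    len(sensor), len(emissions), len(production))

        stage = "filter_cohort"
        cohort = filter_cohort(metadata, config.dim_max)

        stage = "preprocess"
        series = []
        for cow in cohort:
            rows = sensor[sensor["cow_id"] == cow]
            try:
                series.append(preprocess_series(
                    rows, config.max_gap_hours,
                    normalize=config.dtw.normalize, cow_id=cow))
            except UnusableCowError as exc:
                logger.warning("preprocess: dropping %s (%s)", cow, exc)
        logger.info("preprocess: %d usable cows", len(series))

        stage = "pairwise_dtw"
        dmat = pairwise_distances(series, config.dtw)
        artifacts["distance_matrix"] = out / "distance_matrix.csv"
        dmat.to_csv(artifacts["distance_matrix"])
        logger.info("pairwise_dtw: %d x %d distance matrix",
                    *dmat.values.shape)

        stage = "cluster"
        tree = agglomerative_cluster(dmat, config.linkage)
        assignment = cut_tree(tree, config.k)
        merges = pd.DataFrame(tree.linkage_matrix,
                              columns=["node_a", "node_b", "height", "size"])
        artifacts["merges"] = out / "merges.csv"
        merges.to_csv(artifacts["merges"], index=False)
        logger.info("cluster: %s linkage, AC=%.3f, sizes=%s", config.linkage,
                    assignment.agglomerative_coefficient,
                    {l: len(assignment.members(l))
                     for l in range(1, config.k + 1)})

        # name clusters by mean hourly RT: lower -> LR
        cluster_rt = {}
        for lab in range(1, config.k + 1):
            members = assignment.members(lab)
            cluster_rt[lab] = float(
                sensor[sensor["cow_id"].isin(members)]["rt_s"].mean())
        if config.k == 2:
            lr = min(cluster_rt, key=cluster_rt.get)
            names = {lr: "LR", ({1, 2} - {lr}).pop(): "HR"}
        else:
            names = {lab: f"C{lab}" for lab in cluster_rt}
        assign_df = pd.DataFrame(
            {"cow_id": list(assignment.labels),
             "cluster": [assignment.labels[c] for c in assignment.labels],
             "cluster_name": [names[assignment.labels[c]]
                              for c in assignment.labels]})
        artifacts["assignments"] = out / "assignments.csv"
        assign_df.to_csv(artifacts["assignments"], index=False)

        stage = "ordination"
        ordination = pcoa(dmat)
        artifacts["ordination"] = out / "ordination.csv"
        ordination.frame().to_csv(artifacts["ordination"], index=False,
                                  float_format="%.12g")

        stage = "select"
        if config.k != 2:
            raise ValueError("extreme selection requires k=2")
        my_per_cow = (production.groupby("cow_id")["my_kg"].mean()
                      .rename("my"))
        block_meta = (metadata.set_index("cow_id")[["parity", "dim"]]
                      .join(my_per_cow, how="left"))
        block_meta = block_meta.loc[[c for c in assignment.labels]]
        selection = select_extremes(ordination, assignment, block_meta,
                                    config.n_per_cluster, config.blocking)
        sel_rows = []
        for lab, cows in selection.selected.items():
            for rank, cow in enumerate(cows, start=1):
                sel_rows.append({"cow_id": cow, "cluster": lab,
                                 "cluster_name": names[lab], "rank": rank})
        sel_df = pd.DataFrame(sel_rows)
        artifacts["selection"] = out / "selection.csv"
        sel_df.to_csv(artifacts["selection"], index=False)
        artifacts["blocking_report"] = out / "blocking_report.csv"
        selection.blocking_report.to_csv(artifacts["blocking_report"],
                                         index=False)
        logger.info("select: %s cows per cluster",
                    {l: len(c) for l, c in selection.selected.items()})

        stage = "derive_daily"
        selected = sel_df["cow_id"].tolist()
        cow_cluster = dict(zip(sel_df["cow_id"], sel_df["cluster_name"]))
        daily = derive_daily(sensor, emissions, production, cohort=selected)
        daily["cluster"] = daily["cow_id"].map(cow_cluster)
        artifacts["daily"] = out / "daily_phenotypes.csv"
        daily.to_csv(artifacts["daily"], index=False, float_format="%.12g")
        logger.info("derive_daily: %d cow-days", len(daily))

        stage = "lmm"
        lmm_rows = []
        for resp in RESPONSES:
            res = fit_lmm(daily, resp)
            for lev in res.cluster_levels:
                lmm_rows.append({"response": resp, "cluster": lev,
                                 "lsmean": res.lsmeans[lev],
                                 "se": res.lsmean_se[lev],
                                 "p": res.p_value,
                                 "difference": res.difference,
                                 "difference_se": res.difference_se,
                                 "n_cows": res.n_cows, "n_obs": res.n_obs,
                                 "singular": res.singular})
        artifacts["lsmeans"] = out / "lsmeans.csv"
        pd.DataFrame(lmm_rows).to_csv(artifacts["lsmeans"], index=False,
                                      float_format="%.12g")
        logger.info("lmm: %d responses", len(RESPONSES))

        stage = "gam"
        hourly = sensor[sensor["cow_id"].isin(selected)].copy()
        hourly["cluster"] = hourly["cow_id"].map(cow_cluster)
        gam_rows = []
        gam_summary = {}
        for resp in ("RT", "ET"):
            res = fit_gam(hourly, resp)
            cdf = res.curves.copy()
            cdf.insert(0, "response", resp)
            gam_rows.append(cdf)
            gam_summary[resp] = {"cluster_effect": res.cluster_effect,
                                 "se": res.cluster_se, "p": res.p_value,
                                 "edf": res.edf, "lambdas": res.lambdas}
        artifacts["gam_curves"] = out / "gam_curves.csv"
        pd.concat(gam_rows).to_csv(artifacts["gam_curves"], index=False,
                                   float_format="%.12g")
        logger.info("gam: fitted RT and ET circadian curves")

        stage = "correlations"
        merged = hourly.merge(
            emissions[emissions["cow_id"].isin(selected)],
            on=["cow_id", "date", "hour"], how="inner")
        corr = correlate_2h(merged)
        artifacts["correlations"] = out / "correlations.csv"
        corr.to_csv(artifacts["correlations"], index=False,
                    float_format="%.12g")
        logger.info("correlations: %d rows", len(corr))

        stage = "manifest"
        cfg = config_dict(config)
        cfg_hash = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()
        manifest = {
            "config": cfg,
            "config_sha256": cfg_hash,
            "seed": config.seed,
            "versions": {"python": sys.version.split()[0],
                         "numpy": np.__version__,
                         "pandas": pd.__version__},
            "agglomerative_coefficient": assignment.agglomerative_coefficient,
            "cluster_names": {str(k): v for k, v in names.items()},
            "gam": gam_summary,
            "n_cows_clustered": len(series),
            "n_selected": {str(l): len(c)
                           for l, c in selection.selected.items()},
        }
        artifacts["manifest"] = out / "manifest.json"
        with open(artifacts["manifest"], "w") as fhj:
            json.dump(manifest, fhj, indent=2)
    except PipelineStageError:
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineStageError(stage, exc) from exc
    finally:
        logger.removeHandler(fh)
        fh.close()
    return artifacts
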