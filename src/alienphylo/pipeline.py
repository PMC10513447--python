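"""End-to-end orchestration: simulate (or load) inputs, clean and thin
occurrences, build per-scale communities, compute NRI/NTI and anomalies, and
run the comparative statistics, with a JSON manifest recording seeds and
per-stage row counts.

Every stage reads and writes plain text (newick, CSV, GeoJSON, JSON), so a
run is fully reproducible from its config: the same config and seed yield
byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import communities as comm
from . import metrics as met
from . import simulate as sim
from . import stats as dst
from . import phylo

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_simulate", "run_all", "validate_inputs"]

#: stage-seed offsets from the master seed (kept < 2**31)
_SEED_OFFSETS = {
    "tree": 0, "regions": 1, "climate": 2, "niche": 3,
    "statuses": 4, "occurrences": 5, "null": 6,
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``simulation`` holds generator parameters (merged over paper-scale
    defaults); alternatively ``inputs`` maps the four data sources (tree,
    occurrences, regions, climate) to files, in which case the simulation
    block must be absent.
    """

    seed: int = 0
    outdir: str = "alienphylo_out"
    simulation: dict = field(default_factory=dict)
    inputs: dict | None = None
    replicates: int = 9999
    thin_km: float = 5.0
    modes: tuple = ("presence", "abundance")
    anomaly_sign: str = "all_minus_subset"

    SIM_DEFAULTS = {
        "n_species": 706,
        "birth_rate": 1.0,
        "sigma2": 8.0,
        "root_optimum": 12.0,
        "tolerance": 2.0,
        "status_proportions": sim.DEFAULT_STATUS_PROPORTIONS,
        "status_mode": "clade_biased",
        "points_per_species": 124,
        "extent": sim.DEFAULT_EXTENT,
        "units_per_scale": sim.DEFAULT_SCALE_UNITS,
        "grid_cells": (62, 36),
        "temp_gradient": -0.7,
        "precip_gradient": 20.0,
        "noise_sd": 1.0,
    }

    def __post_init__(self):
        if self.inputs and self.simulation:
            raise ValueError("give either input paths or a simulation block")
        if self.anomaly_sign not in ("all_minus_subset", "subset_minus_all"):
            raise ValueError(f"bad anomaly_sign {self.anomaly_sign!r}")
        self.modes = tuple(self.modes)
        unknown = set(self.modes) - {"presence", "abundance"}
        if unknown:
            raise ValueError(f"unknown data modes: {sorted(unknown)}")

    @property
    def sim_params(self) -> dict:
        merged = dict(self.SIM_DEFAULTS)
        merged.update(self.simulation)
        return merged

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 16 + _SEED_OFFSETS[stage]) % (2 ** 31)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["modes"] = list(self.modes)
        return d


def _outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_simulate(config: RunConfig) -> dict:
    """Generate the synthetic world and write tree.nwk, occurrences.csv,
    regions.geojson and climate.csv into the output directory."""
    p = config.sim_params
    out = _outdir(config)
    tree = sim.simulate_yule_tree(
        p["n_species"], p["birth_rate"], seed=config.stage_seed("tree")
    )
    statuses = sim.assign_statuses(
        phylo.tip_labels(tree),
        proportions=p["status_proportions"],
        mode=p["status_mode"],
        tree=tree,
        seed=config.stage_seed("statuses"),
    )
    partitions = sim.simulate_regions(
        p["extent"], p["units_per_scale"], seed=config.stage_seed("regions")
    )
    grid = sim.simulate_climate_grid(
        p["extent"],
        n_cells=tuple(p["grid_cells"]),
        temp_gradient=p["temp_gradient"],
        precip_gradient=p["precip_gradient"],
        noise_sd=p["noise_sd"],
        seed=config.stage_seed("climate"),
    )
    niche = sim.NicheModel.evolve(
        tree,
        sigma2=p["sigma2"],
        root_optimum=p["root_optimum"],
        tolerance=p["tolerance"],
        seed=config.stage_seed("niche"),
    )
    records = sim.simulate_occurrences(
        tree, statuses, niche, grid,
        points_per_species=p["points_per_species"],
        seed=config.stage_seed("occurrences"),
    )
    phylo.write_newick(tree, out / "tree.nwk")
    records.to_csv(out / "occurrences.csv", index=False)
    grid.to_csv(out / "climate.csv", index=False)
    with open(out / "regions.geojson", "w") as fh:
        json.dump(sim.regions_to_geojson(partitions), fh)
    logger.info("simulated %d species, %d records", p["n_species"], len(records))
    return {
        "tree": tree, "records": records, "partitions": partitions,
        "grid": grid, "statuses": statuses, "niche": niche,
    }


def load_inputs(config: RunConfig) -> dict:
    paths = config.inputs
    tree = phylo.read_newick(paths["tree"])
    records = comm.validate_records(pd.read_csv(paths["occurrences"]))
    partitions = sim.regions_from_geojson(paths["regions"])
    grid = pd.read_csv(paths["climate"]) if paths.get("climate") else None
    statuses = records.groupby("species")["status"].first().to_dict()
    return {
        "tree": tree, "records": records, "partitions": partitions,
        "grid": grid, "statuses": statuses,
    }


def validate_inputs(tree, records: pd.DataFrame, partitions: dict) -> dict:
    """Structured pre-flight report: species on tree, legal statuses,
    coordinate ranges, disjoint regions."""
    checks = []

    def check(name, passed, detail=""):
        checks.append({"name": name, "passed": bool(passed), "detail": detail})

    tips = set(phylo.tip_labels(tree))
    missing = sorted(set(records["species"].unique()) - tips)
    check("species_on_tree", not missing,
          f"absent from tree: {missing[:10]}" if missing else "")
    bad = sorted(set(records["status"].unique()) - set(sim.STATUSES))
    check("status_values", not bad, f"bad values: {bad}" if bad else "")
    in_range = (
        records["lat"].abs().le(90).all() and records["lon"].abs().le(180).all()
    )
    check("coordinates_in_range", in_range)
    for scale, units in partitions.items():
        try:
            comm._check_disjoint(sorted(units, key=lambda u: u[0]))
            check(f"regions_disjoint[{scale}]", True)
        except ValueError as exc:
            check(f"regions_disjoint[{scale}]", False, str(exc))
    return {"passed": all(c["passed"] for c in checks), "checks": checks}


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order and write a manifest.

    On stage failure, outputs of completed stages are left in place and the
    manifest names the failed stage before the error is re-raised.
    """
    out = _outdir(config)
    manifest = {
        "config": config.to_dict(),
        "package": "alienphylo 0.1.0",
        "started": datetime.now(timezone.utc).isoformat(),
        "stages": {},
        "failed_stage": None,
    }
    stage = "simulate"
    try:
        if config.inputs:
            stage = "load_inputs"
            world = load_inputs(config)
        else:
            world = run_simulate(config)
        manifest["stages"]["records_read"] = len(world["records"])

        stage = "validate"
        report = validate_inputs(world["tree"], world["records"],
                                 world["partitions"])
        if not report["passed"]:
            raise ValueError(f"input validation failed: {report['checks']}")

        stage = "thin"
        records = comm.dedupe(world["records"])
        manifest["stages"]["records_deduped"] = len(records)
        records = comm.thin_occurrences(records, config.thin_km, sort=True)
        manifest["stages"]["records_thinned"] = len(records)
        records.to_csv(out / "occurrences_thinned.csv", index=False)

        stage = "communities"
        matrices, all_assemblages = {}, []
        dropped = 0
        for scale, units in world["partitions"].items():
            m = comm.assign_to_regions(records, units, scale=scale)
            matrices[scale] = m
            dropped += m.n_dropped
            all_assemblages.extend(
                comm.build_assemblages(m, world["statuses"])
            )
        manifest["stages"]["records_outside_regions"] = dropped
        manifest["stages"]["assemblages_total"] = len(all_assemblages)
        manifest["stages"]["assemblages_usable"] = sum(
            a.usable for a in all_assemblages
        )
        pd.concat([m.to_long() for m in matrices.values()]).to_csv(
            out / "communities.csv", index=False
        )

        stage = "metrics"
        dist_full = phylo.patristic_distances(world["tree"])
        null_cfg = met.NullModelConfig(
            replicates=config.replicates, seed=config.stage_seed("null")
        )
        results = pd.concat(
            [
                met.compute_metrics(dist_full, all_assemblages, mode, null_cfg)
                for mode in config.modes
            ],
            ignore_index=True,
        )
        results.to_csv(out / "metrics.csv", index=False)
        manifest["stages"]["metric_rows"] = len(results)

        stage = "anomalies"
        anom = met.anomalies(results, convention=config.anomaly_sign)
        anom.to_csv(out / "anomalies.csv", index=False)

        stage = "stats"
        stats_out = run_stats(config, results, world["grid"],
                              world["partitions"])
        manifest["stages"].update(stats_out)

        manifest["finished"] = datetime.now(timezone.utc).isoformat()
    except Exception:
        manifest["failed_stage"] = stage
        _write_manifest(out, manifest)
        raise
    _write_manifest(out, manifest)
    return manifest


def run_stats(
    config: RunConfig,
    results: pd.DataFrame,
    grid: pd.DataFrame | None,
    partitions: dict,
) -> dict:
    """Statistics layer over a metrics table; writes stats/*.csv."""
    out = _outdir(config) / "stats"
    out.mkdir(exist_ok=True)
    info: dict = {}
    usable = results.dropna(subset=["NRI", "NTI"])

    if set(config.modes) == {"presence", "abundance"}:
        by_mode = {m: usable[usable["data_mode"] == m] for m in config.modes}
        sel = dst.select_data_mode(by_mode)
        info["selected_mode"] = sel["selected"]
        pd.DataFrame(
            [{"mode": m, "aicc": sel["aicc"][m]} for m in sel["aicc"]]
        ).to_csv(out / "mode_selection.csv", index=False)
        working = by_mode[sel["selected"]]
    else:
        working = usable[usable["data_mode"] == config.modes[0]]
        info["selected_mode"] = config.modes[0]

    sub = working[working["community_type"] != "All"]
    for metric in ("NRI", "NTI"):
        anova = dst.two_way_anova(sub, metric)
        anova.insert(0, "metric", metric)
        anova.to_csv(out / f"anova_{metric.lower()}.csv", index=False)
        ph = dst.posthoc_pairwise(sub, metric, "community_type")
        ph.insert(0, "metric", metric)
        ph.to_csv(out / f"posthoc_{metric.lower()}.csv", index=False)

    if grid is not None:
        covs = dst.aggregate_climate(grid, partitions)
        covs.to_csv(out / "climate_covariates.csv", index=False)
        regs = dst.climate_regressions(sub, covs)
        regs.to_csv(out / "climate_regressions.csv", index=False)
        info["climate_regressions"] = len(regs)

    corr = dst.community_type_correlations(working)
    corr.to_csv(out / "correlations.csv", index=False)
    info["correlations"] = len(corr)
    return info


def _write_manifest(out: Path, manifest: dict) -> None:
    tmp = out / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    tmp.replace(out / "manifest.json")
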