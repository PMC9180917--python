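"""End-to-end orchestration: simulate/ingest -> score -> cluster -> fit -> project.

A :class:`PipelineConfig` names either a synthetic world configuration or a
pair of real input files (trade CSV in the CITES dialect plus a covariate
CSV), the two analysis periods, and stage options.  :func:`run_pipeline`
executes every stage, writes all tabular artifacts as CSV into the output
directory together with a machine-readable JSON manifest (config echo,
seeds, row counts, exclusion counts), and returns the in-memory results.
Identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cites_io, fuzzy, ordinal, projection, scores, synthetic
from .errors import BirdTradeError, ConfigurationError

ROLES = (scores.ROLE_SUPPLIER, scores.ROLE_DEMANDER)


class PipelineError(BirdTradeError):
    """A stage failure, carrying the stage name and the underlying cause."""


@dataclass
class PipelineConfig:
    synthetic: synthetic.SyntheticWorldConfig | None = None
    trade_csv: str | None = None
    covariates_csv: str | None = None
    periods: dict = field(
        default_factory=lambda: {"preban": (1995, 2005), "postban": (2006, 2017)}
    )
    volume_log_range: tuple[float, float] | None = None
    cluster_candidates: tuple[int, ...] = (2, 3, 4, 5)
    cluster_m: float = 2.0
    cluster_seed: int = 0
    scenario_n_reps: int = 1000
    scenario_seed: int = 0
    scenario_mode: str = "sample"
    projection_period: str = "postban"
    outdir: str = "birdtrade_run"

    def validate(self) -> None:
        has_synthetic = self.synthetic is not None
        has_real = self.trade_csv is not None or self.covariates_csv is not None
        if has_synthetic == has_real:
            raise ConfigurationError(
                "exactly one of a synthetic config or real input files must be given"
            )
        if has_real and (self.trade_csv is None or self.covariates_csv is None):
            raise ConfigurationError("real input needs both trade_csv and covariates_csv")
        windows = sorted(tuple(map(int, w)) for w in self.periods.values())
        for (lo1, hi1), (lo2, hi2) in zip(windows, windows[1:]):
            if hi1 >= lo2:
                raise ConfigurationError(f"periods overlap: {(lo1, hi1)} and {(lo2, hi2)}")
        for lo, hi in windows:
            if lo > hi:
                raise ConfigurationError(f"period bounds reversed: {(lo, hi)}")
        if self.projection_period not in self.periods:
            raise ConfigurationError(
                f"projection_period {self.projection_period!r} not among periods"
            )
        if has_synthetic:
            self.synthetic.validate()

    @property
    def effective_volume_log_range(self) -> tuple[float, float] | None:
        """Synthetic runs default to the generator's own calibration span."""
        if self.volume_log_range is not None:
            return tuple(self.volume_log_range)
        if self.synthetic is not None:
            return self.synthetic.volume_log_range
        return None


@dataclass
class PipelineResult:
    config: PipelineConfig
    score_tables: dict          # period -> scores.ScoreTable
    role_assignments: dict      # period -> scores.RoleAssignment
    cluster_fits: dict          # (period, role) -> fuzzy.ClusterMembership
    clm_fits: dict              # (period, role) -> ordinal.CLMFit
    projections: dict           # scenario -> projection.ScenarioProjection
    global_totals: pd.DataFrame
    manifest: dict
    outdir: Path


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    cfg = PipelineConfig()
    if "synthetic" in raw and raw["synthetic"] is not None:
        syn = dict(raw["synthetic"])
        if "thresholds" in syn:
            syn["thresholds"] = tuple(syn["thresholds"])
        cfg.synthetic = synthetic.SyntheticWorldConfig(**syn)
    inputs = raw.get("inputs", {}) or {}
    cfg.trade_csv = inputs.get("trade_csv")
    cfg.covariates_csv = inputs.get("covariates_csv")
    if "periods" in raw:
        cfg.periods = {k: tuple(v) for k, v in raw["periods"].items()}
    binning = raw.get("binning", {}) or {}
    if binning.get("volume_log_range") is not None:
        cfg.volume_log_range = tuple(binning["volume_log_range"])
    clustering = raw.get("clustering", {}) or {}
    cfg.cluster_candidates = tuple(clustering.get("candidates", cfg.cluster_candidates))
    cfg.cluster_m = float(clustering.get("m", cfg.cluster_m))
    cfg.cluster_seed = int(clustering.get("seed", cfg.cluster_seed))
    scen = raw.get("scenarios", {}) or {}
    cfg.scenario_n_reps = int(scen.get("n_reps", cfg.scenario_n_reps))
    cfg.scenario_seed = int(scen.get("seed", cfg.scenario_seed))
    cfg.scenario_mode = scen.get("mode", cfg.scenario_mode)
    cfg.projection_period = scen.get("projection_period", cfg.projection_period)
    cfg.outdir = raw.get("outdir", cfg.outdir)
    return cfg


def config_to_manifest(cfg: PipelineConfig) -> dict:
    out = dataclasses.asdict(cfg)
    if cfg.synthetic is not None:
        out["synthetic"] = synthetic.config_to_dict(cfg.synthetic)
    out["periods"] = {k: list(map(int, v)) for k, v in cfg.periods.items()}
    return out


def _stage(name: str):
    """Decorator wrapping a stage so failures name the stage and cause."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


@_stage("simulate")
def write_synthetic_inputs(cfg: PipelineConfig, outdir: Path) -> tuple[Path, Path]:
    """Generate the world and write its trade and covariate CSVs."""
    world = synthetic.generate_world(cfg.synthetic)
    record_sets = [synthetic.emit_trade_records(world, p) for p in cfg.periods]
    records = cites_io.TradeRecordSet(
        records=pd.concat([rs.records for rs in record_sets], ignore_index=True),
        provenance="synthetic",
    )
    trade_path = outdir / "trade.csv"
    cites_io.write_trade_csv(records, trade_path)
    cov = pd.concat(
        [synthetic.emit_covariates(world, p).table for p in cfg.periods],
        ignore_index=True,
    )
    cov_path = outdir / "covariates.csv"
    cites_io.write_covariates(cites_io.CovariateTable(table=cov), cov_path)
    truth_path = outdir / "world_truth.csv"
    world.countries.to_csv(truth_path, index=False)
    return trade_path, cov_path


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage and write all artifacts under ``cfg.outdir``."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    if cfg.synthetic is not None:
        trade_path, cov_path = write_synthetic_inputs(cfg, outdir)
    else:
        trade_path, cov_path = Path(cfg.trade_csv), Path(cfg.covariates_csv)

    records, covariates = _ingest(trade_path, cov_path, counts)

    score_tables: dict = {}
    role_assignments: dict = {}
    for period, window in cfg.periods.items():
        table, roles_p = _score_period(
            records, covariates, period, window, cfg.effective_volume_log_range, counts
        )
        score_tables[period] = table
        role_assignments[period] = roles_p
        table.table.to_csv(outdir / f"scores_{period}.csv", index=False)
        roles_p.roles.to_csv(outdir / f"roles_{period}.csv")

    cluster_fits = _cluster(cfg, covariates, score_tables, outdir, counts)
    clm_fits = _fit_models(score_tables, outdir)
    projections, totals = _project(cfg, role_assignments, score_tables, clm_fits, outdir)

    manifest = {
        "config": config_to_manifest(cfg),
        "counts": counts,
        "model_fits": {
            f"{period}_{role}": {
                "n": fit.n,
                "beta": fit.beta,
                "se_beta": fit.se_beta,
                "p_value": fit.p_value,
                "nagelkerke_r2": fit.nagelkerke_r2,
                "mcfadden_r2": fit.mcfadden_r2,
                "converged": fit.converged,
            }
            for (period, role), fit in clm_fits.items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(
        config=cfg,
        score_tables=score_tables,
        role_assignments=role_assignments,
        cluster_fits=cluster_fits,
        clm_fits=clm_fits,
        projections=projections,
        global_totals=totals,
        manifest=manifest,
        outdir=outdir,
    )


@_stage("ingest")
def _ingest(trade_path: Path, cov_path: Path, counts: dict):
    records = cites_io.read_trade_csv(trade_path)
    covariates = cites_io.read_covariates(cov_path)
    counts["trade_rows_read"] = records.log_summary.get("rows_read", len(records))
    counts["trade_rows_dropped"] = records.log_summary.get("rows_dropped", 0)
    counts["covariate_rows"] = len(covariates.table)
    return records, covariates


@_stage("score")
def _score_period(records, covariates, period, window, volume_log_range, counts):
    filtered = cites_io.filter_wild_live_birds(records, tuple(window))
    totals = cites_io.aggregate_totals(filtered)
    totals.period = period
    roles_p = scores.assign_roles(totals)
    table = scores.build_score_table(
        roles_p, covariates, period, volume_log_range=volume_log_range
    )
    counts[f"{period}_records"] = len(filtered)
    counts[f"{period}_countries"] = len(totals.totals)
    counts[f"{period}_ties_excluded"] = roles_p.n_ties
    counts[f"{period}_missing_covariates"] = table.n_excluded_missing_covariates
    return table, roles_p


@_stage("cluster")
def _cluster(cfg, covariates, score_tables, outdir: Path, counts: dict):
    cluster_fits = {}
    for period, table in score_tables.items():
        for role in ROLES:
            sub = table.table[table.table["role"] == role]
            if len(sub) < max(cfg.cluster_candidates) + 1:
                counts[f"{period}_{role}_cluster_skipped"] = len(sub)
                continue
            cov = covariates.table
            cov = cov[cov["period"] == period].set_index("country")
            barrier_col = "export_cost" if role == scores.ROLE_SUPPLIER else "import_tariff"
            pts = fuzzy.normalize_axes(
                np.column_stack(
                    [
                        cov.loc[sub["country"], "rule_of_law"],
                        cov.loc[sub["country"], barrier_col],
                    ]
                )
            )
            c = fuzzy.select_cluster_count(
                pts, cfg.cluster_candidates, m=cfg.cluster_m, seed=cfg.cluster_seed
            )
            fit = fuzzy.fcm(pts, c=c, m=cfg.cluster_m, seed=cfg.cluster_seed)
            labels = fuzzy.scenario_quadrant_labels(fit.centers)
            out = pd.DataFrame(
                fit.memberships,
                columns=[f"membership_{lab}_{j}" for j, lab in enumerate(labels)],
            )
            out.insert(0, "country", sub["country"].to_numpy())
            out.insert(1, "closest_scenario", [labels[j] for j in fit.memberships.argmax(axis=1)])
            out.to_csv(outdir / f"clusters_{period}_{role}.csv", index=False)
            cluster_fits[(period, role)] = fit
    return cluster_fits


@_stage("fit")
def _fit_models(score_tables, outdir: Path):
    clm_fits = {}
    summaries = []
    for period, table in score_tables.items():
        for role in ROLES:
            sub = table.table[table.table["role"] == role]
            if sub.empty:
                continue
            data = ordinal.CLMData(
                E=sub["expected_score"].to_numpy(),
                T=sub["real_trade_score"].to_numpy(),
                role=role,
                period=period,
            )
            fit = ordinal.fit_clm(data)
            clm_fits[(period, role)] = fit
            summaries.append(
                {
                    "period": period,
                    "role": role,
                    "n": fit.n,
                    "beta": fit.beta,
                    "se_beta": fit.se_beta,
                    "z": fit.z,
                    "p_value": fit.p_value,
                    **{f"theta_{k + 1}": fit.theta[k] for k in range(4)},
                    "loglik_null": fit.loglik_null,
                    "loglik": fit.loglik,
                    "nagelkerke_r2": fit.nagelkerke_r2,
                    "mcfadden_r2": fit.mcfadden_r2,
                    "converged": fit.converged,
                }
            )
    pd.DataFrame(summaries).to_csv(outdir / "clm_fits.csv", index=False)
    return clm_fits


@_stage("project")
def _project(cfg, role_assignments, score_tables, clm_fits, outdir: Path):
    period = cfg.projection_period
    table = score_tables[period]
    fit_s = clm_fits.get((period, scores.ROLE_SUPPLIER))
    fit_d = clm_fits.get((period, scores.ROLE_DEMANDER))
    calib_s = (table.calibrations or {}).get(scores.ROLE_SUPPLIER)
    calib_d = (table.calibrations or {}).get(scores.ROLE_DEMANDER)
    # project only scored countries (e.g. partners without covariates drop out)
    ra = role_assignments[period]
    keep = ra.roles.index.isin(table.table["country"])
    ra = scores.RoleAssignment(roles=ra.roles.loc[keep], period=ra.period, n_ties=ra.n_ties)
    projections = {}
    totals_frames = []
    country_frames = []
    for name, spec in projection.DEFAULT_SCENARIOS.items():
        proj = projection.project_scenario(
            fit_s,
            fit_d,
            ra,
            spec,
            calib_s,
            calib_d,
            n_reps=cfg.scenario_n_reps,
            seed=cfg.scenario_seed,
            mode=cfg.scenario_mode,
        )
        projections[name] = proj
        country_frames.append(proj.country_summary)
        totals_frames.append(projection.global_totals(proj))
    pd.concat(country_frames, ignore_index=True).to_csv(
        outdir / "projections_countries.csv", index=False
    )
    totals = pd.concat(totals_frames, ignore_index=True)
    totals.to_csv(outdir / "projections_global.csv", index=False)
    return projections, totals
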