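"""End-to-end orchestration: simulate or load, filter, impute/standardise,
fit per population, estimate effects with every requested estimator, and
write tables, logs and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_EVEN
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (GeneratorConfig, default_config, generate_cohort,
                     inject_missingness, PRESENTATIONS, OUTCOME_FAMILIES,
                     WINDOWS)
from .preprocessing import (apply_cohort_filters, derive_outcome_matrix,
                            impute_missing, standardize_continuous,
                            FilterThresholds)
from .model import LatentHealthModel, make_model_frame
from .effects import estimate_ate, estimate_subgroup_ate, standard_subgroups
from .comparators import unadjusted_rd, ipw_rd, g_computation_rd

__all__ = ["PipelineConfig", "run_pipeline", "render_effect_table",
           "format_rd", "format_effect_cell"]

SMALL_POPULATION = 200
ALL_ESTIMATORS = ("unadjusted", "ipw", "gcomp", "latent")


@dataclass
class PipelineConfig:
    """One config drives a full reproducible run."""
    source: str = "default"            # scenario name or path to a CSV
    n_visits: int = 5000
    seed: int = 0
    populations: tuple = ("overall",)  # "overall" and/or presentation names
    outcomes: tuple = tuple(f"{f}_{w}d" for f in OUTCOME_FAMILIES
                            for w in WINDOWS)
    estimators: tuple = ALL_ESTIMATORS
    subgroups: bool = True
    alpha: float = 0.05
    sample_end_date: str = "2018-09-27"
    em_n_restarts: int = 2
    em_max_iter: int = 200
    em_rel_tol: float = 1e-7
    em_threshold_maxiter: int = 12
    n_boot: int = 500
    out_dir: str = "edlatent_run"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.estimators:
            raise ValueError("at least one estimator must be selected")
        if not self.outcomes:
            raise ValueError("at least one outcome must be selected")
        bad = set(self.estimators) - set(ALL_ESTIMATORS)
        if bad:
            raise ValueError(f"unknown estimators: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("populations", "outcomes", "estimators"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def format_rd(value: float) -> str:
    """Probability -> percentage points with one decimal, half-even."""
    pct = Decimal(repr(float(value) * 100.0))
    return str(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


def format_effect_cell(rd: float, ci_low: float, ci_high: float) -> str:
    """The report's cell style, e.g. ``5.8 (5.0 to 6.5)``."""
    return (f"{format_rd(rd)} ({format_rd(ci_low)} "
            f"to {format_rd(ci_high)})")


def render_effect_table(estimates: list, layout: str = "main") -> pd.DataFrame:
    """Format estimates as a presentation table.

    ``main``: one outcome+window per table; rows are populations, columns
    estimators.  ``subgroup``: rows are subgroup populations, columns are
    outcome families (single estimator, single window).
    """
    if not estimates:
        raise ValueError("no estimates to render")
    windows = {e.window for e in estimates}
    if len(windows) != 1:
        raise ValueError("mixed windows in one table")
    cells = {}
    for e in estimates:
        key = e.population
        col = (e.estimator if layout == "main" else e.outcome)
        label = format_effect_cell(e.rd, e.ci_low, e.ci_high)
        if "imprecise" in e.flags or "below_subgroup_floor" in e.flags:
            label += " [imprecise]"
        cells.setdefault(key, {})[col] = label
    tab = pd.DataFrame.from_dict(cells, orient="index")
    tab.index.name = "population"
    return tab


def _seed_for(base: int, tag: str) -> int:
    h = hashlib.sha256(f"{base}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _load_or_simulate(cfg: PipelineConfig, out: Path, log: list):
    src = Path(cfg.source)
    if src.suffix == ".csv" and src.exists():
        table = pd.read_csv(src)
        gt = None
        log.append(f"loaded {len(table)} visits from {src}")
        return table, gt
    gen = default_config(cfg.n_visits, _seed_for(cfg.seed, "generate"),
                         scenario=cfg.source)
    table, gt = generate_cohort(gen)
    table = inject_missingness(table, gen.missingness_rates,
                               _seed_for(cfg.seed, "missingness"))
    table.to_csv(out / "cohort.csv", index=False)
    gt.to_json(out / "ground_truth.json")
    gen.to_yaml(out / "generator_config.yaml")
    log.append(f"simulated scenario '{cfg.source}' with "
               f"{len(table)} visits")
    return table, gt


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list = []
    timing: dict = {}
    manifest = {"config": asdict(config), "config_digest": config.digest(),
                "version": __version__, "stages": log, "warnings": []}

    def stage(name):
        timing[name] = time.perf_counter()

    def done(name):
        timing[name] = round(time.perf_counter() - timing[name], 3)

    try:
        stage("simulate")
        table, gt = _load_or_simulate(config, out, log)
        done("simulate")

        stage("filter")
        filtered, report = apply_cohort_filters(
            table, config.sample_end_date, FilterThresholds())
        with open(out / "filter_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        log.append(f"filter: kept {report.n_retained}/{report.n_input}; "
                   f"exclusions {report.exclusions}")
        done("filter")

        stage("preprocess")
        imputed, imp_log = impute_missing(filtered)
        standardized, scaler = standardize_continuous(imputed)
        outcome_matrix = derive_outcome_matrix(imputed)
        frame_all = make_model_frame(standardized, outcome_matrix)
        manifest["imputation"] = imp_log
        manifest["scaling"] = {k: list(v) for k, v in scaler.stats.items()}
        done("preprocess")

        populations = {}
        for pop in config.populations:
            if pop == "overall":
                populations[pop] = np.ones(len(frame_all), dtype=bool)
            elif pop in PRESENTATIONS:
                populations[pop] = (imputed["presentation"] == pop
                                    ).to_numpy()
            else:
                raise ValueError(f"unknown population '{pop}'")

        level = 1.0 - config.alpha
        estimates = []
        fits = {}
        stage("fit")
        for pop, mask in populations.items():
            fr = frame_all.loc[mask].reset_index(drop=True)
            if len(fr) < SMALL_POPULATION:
                manifest["warnings"].append(
                    f"population '{pop}' has n={len(fr)} < "
                    f"{SMALL_POPULATION}: estimates flagged imprecise")
            if "latent" in config.estimators:
                model = LatentHealthModel(
                    outcomes=list(config.outcomes),
                    n_restarts=config.em_n_restarts,
                    max_iter=config.em_max_iter,
                    rel_tol=config.em_rel_tol,
                    threshold_maxiter=config.em_threshold_maxiter,
                    seed=_seed_for(config.seed, f"em:{pop}"))
                model.fit(fr)
                fits[pop] = model.result_
                fits[pop].to_json(out / f"fit_{pop}.json")
                if model.result_.flags:
                    manifest["warnings"].append(
                        f"fit '{pop}': {sorted(model.result_.flags)}")
        done("fit")

        stage("effects")
        for pop, mask in populations.items():
            fr = frame_all.loc[mask].reset_index(drop=True)
            small = len(fr) < SMALL_POPULATION
            for outcome in config.outcomes:
                for est_name in config.estimators:
                    if est_name == "latent":
                        e = estimate_ate(fits[pop], fr, outcome,
                                         level=level, population=pop)
                    elif est_name == "unadjusted":
                        e = unadjusted_rd(fr, outcome, level=level,
                                          population=pop)
                    elif est_name == "ipw":
                        e = ipw_rd(fr, outcome, n_boot=config.n_boot,
                                   seed=_seed_for(config.seed,
                                                  f"ipw:{pop}:{outcome}"),
                                   level=level, population=pop)
                    else:
                        e = g_computation_rd(
                            fr, outcome, n_boot=config.n_boot,
                            seed=_seed_for(config.seed,
                                           f"gcomp:{pop}:{outcome}"),
                            level=level, population=pop)
                    if small:
                        e.flags["imprecise"] = True
                    estimates.append(e)

        subgroup_estimates = []
        if config.subgroups and "latent" in config.estimators \
                and "overall" in populations:
            fr = frame_all
            for name, mask in standard_subgroups(imputed).items():
                for outcome in config.outcomes:
                    if not outcome.endswith("_30d"):
                        continue
                    subgroup_estimates.append(estimate_subgroup_ate(
                        fits["overall"], fr, outcome, mask, name,
                        level=level))
        done("effects")

        stage("report")
        rows = [e.to_row() for e in estimates]
        main_df = pd.DataFrame(rows)
        for col in ("rd", "se", "ci_low", "ci_high"):
            main_df[f"{col}_pct"] = main_df[col] * 100.0
        main_df.to_csv(out / "effects_main.csv", index=False)
        if subgroup_estimates:
            sub_df = pd.DataFrame([e.to_row() for e in subgroup_estimates])
            for col in ("rd", "se", "ci_low", "ci_high"):
                sub_df[f"{col}_pct"] = sub_df[col] * 100.0
            sub_df.to_csv(out / "effects_subgroups.csv", index=False)

        with open(out / "tables.txt", "w") as fh:
            for outcome in config.outcomes:
                fam, w = outcome.rsplit("_", 1)
                sel = [e for e in estimates
                       if e.outcome == fam and f"{e.window}d" == w]
                if not sel:
                    continue
                fh.write(f"== {fam}, {w} window: risk differences "
                         "(percentage points, admit vs discharge) ==\n")
                fh.write(render_effect_table(sel, "main").to_string())
                fh.write("\n\n")
            if subgroup_estimates:
                fh.write("== subgroups, 30d window (latent model) ==\n")
                fh.write(render_effect_table(subgroup_estimates,
                                             "subgroup").to_string())
                fh.write("\n")
        done("report")
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise

    manifest["timing_s"] = timing
    manifest["filter_report"] = report.to_dict() | {"retained_ids": "..."}
    if gt is not None:
        manifest["ground_truth_ate"] = gt.true_ate
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
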