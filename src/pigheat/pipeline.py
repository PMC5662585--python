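"""End-to-end run: simulate -> derive -> rfi -> mixed models -> correlations.

A run is fully determined by its :class:`RunConfig` (cohort calibration,
schedule, traits, candidate covariance structures, master seed); the config
is archived next to the outputs so any run can be reproduced from the
archive alone.  Every stage writes plain CSV/JSON tables shaped like the
study's report tables: the feed-requirement estimate table, per-trait
covariance-structure rankings with the interaction-pruning trail, period
LS-means tables, a carcass LS-means table, and the correlation families.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlations as corrmod
from . import phenotypes as ph
from . import rfi as rfimod
from .cohort import CohortConfig, CohortTables, default_config, generate_cohort
from .lmm import (
    LmmError,
    ModelSpec,
    ls_means,
    prune_interactions,
    select_structure,
)
from .study_design import ExperimentSchedule, build_default_schedule

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

#: model-4 interaction set (period is nested in climate)
MODEL4_INTERACTIONS = [
    "line*climate",
    "line*period(climate)",
    "line*room",
    "line*diet",
    "diet*climate",
    "diet*period(climate)",
    "diet*room",
    "room*climate",
    "room*period(climate)",
]
MODEL4_MAIN = ["line", "climate", "period(climate)", "diet", "room", "age_at_start"]

#: traits measured once per HS cycle: same model without climate terms
LOSS_MAIN = ["line", "cycle", "diet", "room", "age_at_start"]
LOSS_INTERACTIONS = ["line*cycle", "line*room", "line*diet", "diet*cycle",
                     "diet*room", "room*cycle"]

#: carcass model: line, diet, room, age, BW covariate, random litter
MODEL5_MAIN = ["line", "diet", "room", "age_at_start"]
MODEL5_INTERACTIONS = ["line*diet", "line*room", "diet*room"]


@dataclass
class RunConfig:
    """Serializable description of one full pipeline run."""

    cohort: CohortConfig = field(default_factory=lambda: default_config())
    schedule: ExperimentSchedule = field(default_factory=build_default_schedule)
    traits: tuple = ("bwg_kgd", "fi_kgd")
    loss_traits: tuple = ("loss_bwg_kgd",)
    structures: tuple = ("cs", "ar1", "arh1", "toep", "un")
    carcass: bool = True
    outdir: str = "pigheat_run"
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "cohort": self.cohort.to_dict(),
                "schedule": self.schedule.to_dict(),
                "traits": list(self.traits),
                "loss_traits": list(self.loss_traits),
                "structures": list(self.structures),
                "carcass": self.carcass,
                "outdir": self.outdir,
                "seed": self.seed,
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        return cls(
            cohort=CohortConfig.from_dict(d["cohort"]),
            schedule=ExperimentSchedule.from_dict(d["schedule"]),
            traits=tuple(d.get("traits", ("bwg_kgd", "fi_kgd"))),
            loss_traits=tuple(d.get("loss_traits", ("loss_bwg_kgd",))),
            structures=tuple(d.get("structures", ("cs", "ar1", "arh1", "toep", "un"))),
            carcass=bool(d.get("carcass", True)),
            outdir=d.get("outdir", "pigheat_run"),
            seed=int(d.get("seed", 0)),
        )


def _repeated_data(tables: CohortTables, phen: pd.DataFrame,
                   schedule: ExperimentSchedule) -> pd.DataFrame:
    start = {p.label: p.start_day for p in schedule.periods}
    d = phen.merge(tables.pigs, on="pig_id", how="inner").copy()
    d["room"] = d["room"].astype(str)
    d["period_index"] = d["period"].map(start).astype(float)
    return d


def _loss_data(tables: CohortTables, losses: pd.DataFrame,
               schedule: ExperimentSchedule) -> pd.DataFrame:
    start = {p.label: p.start_day for p in schedule.periods}
    d = losses.merge(tables.pigs, on="pig_id", how="inner").copy()
    d["room"] = d["room"].astype(str)
    d["cycle_index"] = d["cycle"].map(start).astype(float)
    return d


def _fit_trait(trait, data, main, interactions, repeated, structures, seed):
    """Prune interactions (compound-symmetry working model), then select the
    residual covariance structure for the pruned fixed effects."""
    spec = ModelSpec(
        response=trait,
        fixed=main + interactions,
        random=["litter_id(line)"],
        repeated=repeated,
        categorical=("line", "climate", "diet", "room", "cycle"),
    )
    work = spec.with_structure("cs") if repeated else spec
    final_spec, _, trail = prune_interactions(work, data, alpha=0.10, seed=seed)
    if repeated:
        sel = select_structure(final_spec, data, list(structures), seed=seed)
        fit = sel.fits[sel.chosen]
        ranking = sel.ranking
        lrt = sel.lrt
    else:
        from .lmm import fit_lmm

        fit = fit_lmm(final_spec, data, seed=seed)
        ranking, lrt = pd.DataFrame(), None
    return final_spec, fit, trail, ranking, lrt


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    if isinstance(o, dict):
        return {str(k): _jsonable(v) for k, v in o.items()}
    if isinstance(o, (list, tuple)):
        return [_jsonable(v) for v in o]
    return o


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write the report bundle, return it in memory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def stage(name):
        t0 = time.time()

        def done(**info):
            line = f"{name}: {time.time() - t0:.2f}s " + " ".join(
                f"{k}={v}" for k, v in info.items()
            )
            log_lines.append(line)
            logger.info(line)

        return done

    (out / "config.yaml").write_text(config.to_yaml())
    report: dict = {}
    schedule = config.schedule

    done = stage("simulate")
    cohort_cfg = config.cohort
    if cohort_cfg.seed != config.seed:
        from dataclasses import replace

        cohort_cfg = replace(cohort_cfg, seed=config.seed)
    tables = generate_cohort(cohort_cfg, schedule)
    tables.write(out / "cohort")
    done(pigs=len(tables.pigs))

    done = stage("derive")
    derived = ph.derive_all(tables.bw, tables.daily_fi, tables.scans, schedule)
    phen, losses = derived.phenotypes, derived.losses
    done(rows=len(phen))

    done = stage("rfi")
    coef_tn = rfimod.fit_rfi_tn(phen)
    phen = rfimod.apply_rfi(coef_tn, phen)
    coef_hs = rfimod.fit_rfi_tn(phen, climate="HS")
    growth_coef, phen = rfimod.residual_growth(phen)
    rfi_json = {
        "tn": coef_tn.to_dict(),
        "hs_refit": coef_hs.to_dict(),
        "residual_growth": growth_coef.to_dict(),
    }
    (out / "rfi_fit.json").write_text(json.dumps(_jsonable(rfi_json), indent=2))
    phen.to_csv(out / "period_phenotypes.csv", index=False)
    losses.to_csv(out / "losses.csv", index=False)
    report["rfi"] = rfi_json
    done(tn_r2=round(coef_tn.r_squared, 3), hs_r2=round(coef_hs.r_squared, 3))

    done = stage("feed_requirements")
    try:
        feedreq, _ = rfimod.fit_feed_requirements(phen, tables.pigs, seed=config.seed)
        feedreq.to_csv(out / "feed_requirements.csv", index=False)
        report["feed_requirements"] = feedreq
        done(rows=len(feedreq))
    except (LmmError, np.linalg.LinAlgError) as e:
        logger.warning("feed-requirement model skipped: %s", e)
        done(skipped=type(e).__name__)

    rep_data = _repeated_data(tables, phen, schedule)
    repeated = {"subject": "pig_id", "time": "period_index", "structure": "cs"}
    report["lmm"] = {}
    for trait in config.traits:
        done = stage(f"lmm:{trait}")
        try:
            final_spec, fit, trail, ranking, lrt = _fit_trait(
                trait, rep_data, MODEL4_MAIN, MODEL4_INTERACTIONS,
                repeated, config.structures, config.seed,
            )
            lsm_lc = ls_means(fit, ("line", "climate"))
            lsm_lp = ls_means(fit, ("line", "period"))
            entry = {
                "fixed": final_spec.fixed,
                "structure": fit.structure,
                "ranking": ranking,
                "lrt": lrt,
                "pruning_trail": trail,
                "term_tests": fit.term_tests,
                "lsmeans_line_climate": lsm_lc.table.assign(
                    level=lsm_lc.table["level"].astype(str)
                ),
                "lsmeans_line_period": lsm_lp.table.assign(
                    level=lsm_lp.table["level"].astype(str)
                ),
            }
            report["lmm"][trait] = entry
            (out / f"lmm_{trait}.json").write_text(
                json.dumps(_jsonable(entry), indent=2)
            )
            entry["lsmeans_line_climate"].to_csv(
                out / f"lsmeans_{trait}_line_climate.csv", index=False
            )
            entry["lsmeans_line_period"].to_csv(
                out / f"lsmeans_{trait}_line_period.csv", index=False
            )
            done(structure=fit.structure, terms=len(final_spec.fixed))
        except (LmmError, np.linalg.LinAlgError, ValueError) as e:
            logger.warning("trait %s: mixed model skipped (%s)", trait, e)
            done(skipped=type(e).__name__)

    if len(schedule.hs_cycles) >= 2:
        loss_data = _loss_data(tables, losses, schedule)
        loss_rep = {"subject": "pig_id", "time": "cycle_index", "structure": "cs"}
        for trait in config.loss_traits:
            done = stage(f"lmm:{trait}")
            try:
                final_spec, fit, trail, ranking, lrt = _fit_trait(
                    trait, loss_data, LOSS_MAIN, LOSS_INTERACTIONS,
                    loss_rep, config.structures, config.seed,
                )
                lsm = ls_means(fit, ("line", "cycle"))
                entry = {
                    "fixed": final_spec.fixed,
                    "structure": fit.structure,
                    "ranking": ranking,
                    "lrt": lrt,
                    "pruning_trail": trail,
                    "term_tests": fit.term_tests,
                    "lsmeans_line_cycle": lsm.table.assign(
                        level=lsm.table["level"].astype(str)
                    ),
                }
                report["lmm"][trait] = entry
                (out / f"lmm_{trait}.json").write_text(
                    json.dumps(_jsonable(entry), indent=2)
                )
                done(structure=fit.structure)
            except (LmmError, np.linalg.LinAlgError, ValueError) as e:
                logger.warning("trait %s: mixed model skipped (%s)", trait, e)
                done(skipped=type(e).__name__)

    if config.carcass:
        done = stage("carcass")
        try:
            cdata = tables.slaughter.merge(tables.pigs, on="pig_id").copy()
            cdata["room"] = cdata["room"].astype(str)
            rows = []
            for trait in ("lean_pct", "loind_mm", "hcw_kg"):
                spec = ModelSpec(
                    response=trait,
                    fixed=MODEL5_MAIN + MODEL5_INTERACTIONS,
                    random=["litter_id(line)"],
                    categorical=("line", "diet", "room"),
                )
                final_spec, fit, _trail = prune_interactions(
                    spec, cdata, alpha=0.10, seed=config.seed
                )
                lsm = ls_means(fit, "line")
                for _, r in lsm.table.iterrows():
                    rows.append(
                        {
                            "trait": trait, "line": r["level"][0],
                            "estimate": r["estimate"], "se": r["se"],
                            "letters": r["letters"],
                        }
                    )
            carcass_tbl = pd.DataFrame(rows)
            carcass_tbl.to_csv(out / "carcass_lsmeans.csv", index=False)
            report["carcass"] = carcass_tbl
            done(rows=len(rows))
        except (LmmError, np.linalg.LinAlgError, ValueError) as e:
            logger.warning("carcass models skipped (%s)", e)
            done(skipped=type(e).__name__)

    done = stage("correlate")
    corr = corrmod.trait_correlation_report(
        phen, losses, tables.slaughter, tables.pigs, tables.scans, schedule
    )
    corr.to_csv(out / "correlations.csv", index=False)
    report["correlations"] = corr
    done(rows=len(corr))

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    report["log"] = log_lines
    return report
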