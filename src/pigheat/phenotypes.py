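"""Per-pig, per-period trait derivation from raw longitudinal tables.

Raw inputs are measured body weights (one day before each period boundary),
daily feed disappearance, and two ultrasound scans.  This module completes
body weight at the period boundaries, then derives per-period body weight
gain (BWG, kg/d), feed intake (FI, kg/d), metabolic body weight
(mean-period BW^0.75), the assigned backfat, feed conversion efficiency
(FCE = BWG/FI, negative gains allowed), and the per-cycle heat-stress drops
LossBWG and LossFI.

Boundary completion ("sequential forward fill"): boundaries are processed
chronologically.  For a period [s, e) whose end-boundary BW is unmeasured
but whose day e-1 is measured, the period growth rate is taken from the
already-completed start BW and the day e-1 measurement,
``rate = (BW(e-1) - BW(s)) / (e-1-s)``, and ``BW(e) = BW(e-1) + rate``.
This makes each period's derived BWG identical to the measured-interval
rate (e.g. BWG over HS1 equals (BW23 - BW20)/3) and the per-period gains
telescope exactly to the total measured gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .study_design import HS, TN, ExperimentSchedule

logger = logging.getLogger(__name__)


class PhenotypeError(ValueError):
    pass


def pct_lean(bft_mm, loin_depth_mm):
    """Carcass lean percentage from the Fat-O-Meater equation.

    ``58.86 - 0.61 * BFT + 0.12 * LoinD`` with backfat in mm and loin depth
    in mm.  Inputs must be non-negative; vectorized.
    """
    bft = np.asarray(bft_mm, dtype=float)
    loin = np.asarray(loin_depth_mm, dtype=float)
    if np.any(bft < 0) or np.any(loin < 0):
        raise PhenotypeError("backfat and loin depth must be non-negative")
    out = 58.86 - 0.61 * bft + 0.12 * loin
    return float(out) if out.ndim == 0 else out


def fce(bwg, fi):
    """Feed conversion efficiency, gain per unit feed (negative gain allowed)."""
    fi = np.asarray(fi, dtype=float)
    if np.any(fi <= 0):
        raise PhenotypeError("FCE undefined for non-positive feed intake")
    out = np.asarray(bwg, dtype=float) / fi
    return float(out) if out.ndim == 0 else out


def fcr(bwg, fi):
    """Feed conversion ratio (feed per unit gain); NaN at zero gain.

    Kept for completeness; FCE is the reported efficiency because FCR is
    undefined at zero gain and misleading under weight loss.
    """
    bwg = np.asarray(bwg, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bwg == 0, np.nan, np.asarray(fi, dtype=float) / bwg)
    return float(out) if out.ndim == 0 else out


def assign_bft(scan_table: pd.DataFrame, schedule: ExperimentSchedule) -> pd.DataFrame:
    """Backfat assigned to each period from the two scans.

    First-scan value for TN1 and the first HS cycle, last-scan value for the
    last HS cycle and the final TN period, the mean of the two scans for the
    middle periods.
    """
    first_day, last_day = schedule.scan_days
    wide = scan_table.pivot_table(index="pig_id", columns="day", values="bft_mm")
    labels = [p.label for p in schedule.periods]
    early = {labels[0]}
    if len(labels) > 1:
        early.add(labels[1])
    late = set(labels[-2:]) if len(labels) > 1 else set(labels)
    rows = []
    for pig_id, r in wide.iterrows():
        b_first, b_last = r.get(first_day, np.nan), r.get(last_day, np.nan)
        for lab in labels:
            if lab in early:
                v = b_first
            elif lab in late:
                v = b_last
            else:
                v = (b_first + b_last) / 2.0
            rows.append({"pig_id": pig_id, "period": lab, "bft_mm": v})
    return pd.DataFrame(rows)


def estimate_boundary_bw(
    bw_table: pd.DataFrame,
    schedule: ExperimentSchedule,
    method: str = "sequential",
) -> pd.DataFrame:
    """Complete BW at every period-boundary day for each pig.

    ``bw_table`` columns: ``pig_id, day, bw_kg`` (measured days).  Returns
    the measured rows plus estimated boundary rows, with an ``estimated``
    flag.  ``method="sequential"`` (default) is the forward fill described in
    the module docstring; ``method="next_period"`` instead shifts each
    measured pre-boundary BW with the *following* period's measured-interval
    rate.  Pigs missing a scheduled measured BW keep their unaffected
    boundaries; downstream periods that need the missing anchor are dropped
    (and logged), not the whole pig.
    """
    if method not in ("sequential", "next_period"):
        raise ValueError(f"unknown method {method!r}")
    out_rows = []
    for pig_id, g in bw_table.groupby("pig_id", sort=True):
        bw = dict(zip(g["day"].astype(int), g["bw_kg"].astype(float)))
        for d in bw:
            out_rows.append(
                {"pig_id": pig_id, "day": d, "bw_kg": bw[d], "estimated": False}
            )
        for i, p in enumerate(schedule.periods):
            s, e = p.start_day, p.end_day
            if e in bw:
                continue
            nxt = schedule.periods[i + 1] if i + 1 < len(schedule.periods) else None
            if method == "next_period" and nxt is not None:
                # attribute the (e-1, e] shift to the following period's
                # measured-interval rate: (BW(next end - 1) - BW(e-1)) / span
                anchor, meas = e - 1, nxt.end_day - 1
                if anchor in bw and meas in bw:
                    rate = (bw[meas] - bw[anchor]) / (meas - anchor)
                    bw[e] = bw[anchor] + rate
                    out_rows.append(
                        {"pig_id": pig_id, "day": e, "bw_kg": bw[e], "estimated": True}
                    )
                    continue
            anchor, meas = s, e - 1
            if meas in bw and anchor in bw:
                rate = (bw[meas] - bw[anchor]) / (meas - anchor)
                bw[e] = bw[meas] + rate
                out_rows.append(
                    {"pig_id": pig_id, "day": e, "bw_kg": bw[e], "estimated": True}
                )
                continue
            # chain restart: bridge the boundary with the following period's
            # measured rate so one missing weighing only drops the periods
            # that genuinely need it
            if meas in bw and nxt is not None and (nxt.end_day - 1) in bw:
                far = nxt.end_day - 1
                rate = (bw[far] - bw[meas]) / (far - meas)
                bw[e] = bw[meas] + rate
                out_rows.append(
                    {"pig_id": pig_id, "day": e, "bw_kg": bw[e], "estimated": True}
                )
                logger.warning(
                    "pig %s: period %s start BW missing; boundary day %s bridged "
                    "with the following period's rate",
                    pig_id, p.label, e,
                )
                continue
            logger.warning(
                "pig %s: missing BW anchor for period %s; boundary day %s "
                "not estimated",
                pig_id, p.label, e,
            )
    out = pd.DataFrame(out_rows).sort_values(["pig_id", "day"])
    return out.reset_index(drop=True)


def derive_period_phenotypes(
    bw_completed: pd.DataFrame,
    daily_fi_table: pd.DataFrame,
    scan_table: pd.DataFrame,
    schedule: ExperimentSchedule,
) -> pd.DataFrame:
    """One row per pig per period: bwg, fi, mbw, assigned bft, fce.

    ``bwg = (BW_end - BW_start)/span``; ``fi`` is the mean daily feed
    disappearance over the half-open period; ``mbw`` is the start/end mean BW
    to the 0.75 power.  At most one missing FI day per period is imputed by
    the period mean of the remaining days; more are left missing.  Periods
    lacking a boundary BW are omitted (logged).  The ``rfi`` column is
    initialised to NaN and filled by the RFI stage.
    """
    bft = assign_bft(scan_table, schedule).set_index(["pig_id", "period"])["bft_mm"]
    bw = bw_completed.set_index(["pig_id", "day"])["bw_kg"]
    fi_by_pig = {
        pid: dict(zip(g["day"].astype(int), g["fi_kg"].astype(float)))
        for pid, g in daily_fi_table.groupby("pig_id")
    }
    rows = []
    for pig_id in bw_completed["pig_id"].unique():
        fi_days = fi_by_pig.get(pig_id, {})
        for p in schedule.periods:
            try:
                bw_s = bw.loc[(pig_id, p.start_day)]
                bw_e = bw.loc[(pig_id, p.end_day)]
            except KeyError:
                logger.warning(
                    "pig %s: period %s skipped (missing boundary BW)",
                    pig_id,
                    p.label,
                )
                continue
            vals = [fi_days[d] for d in p.days if d in fi_days]
            n_missing = p.span - len(vals)
            if n_missing == 1 and vals:
                vals.append(float(np.mean(vals)))  # single-day imputation
            elif n_missing > 1:
                logger.warning(
                    "pig %s: period %s has %d missing FI days; FI left missing",
                    pig_id,
                    p.label,
                    n_missing,
                )
                vals = []
            fi_val = float(np.mean(vals)) if vals else np.nan
            bwg = (bw_e - bw_s) / p.span
            mbw = ((bw_s + bw_e) / 2.0) ** 0.75
            rows.append(
                {
                    "pig_id": pig_id,
                    "period": p.label,
                    "climate": p.climate,
                    "bwg_kgd": bwg,
                    "fi_kgd": fi_val,
                    "mbw_kg075": mbw,
                    "bft_mm": bft.get((pig_id, p.label), np.nan),
                    "fce": bwg / fi_val if fi_val and fi_val > 0 else np.nan,
                    "rfi_kgd": np.nan,
                }
            )
    return pd.DataFrame(rows)


def compute_losses(phenotypes: pd.DataFrame, schedule: ExperimentSchedule) -> pd.DataFrame:
    """Per-pig, per-HS-cycle drops: loss = HS value minus preceding TN value.

    Negative values are drops.  A cycle is omitted (logged) when either
    member of its TN/HS pair is missing.
    """
    idx = phenotypes.set_index(["pig_id", "period"])
    rows = []
    for pig_id in phenotypes["pig_id"].unique():
        for tn_lab, hs_lab in schedule.tn_hs_pairs():
            try:
                tn = idx.loc[(pig_id, tn_lab)]
                hs = idx.loc[(pig_id, hs_lab)]
            except KeyError:
                logger.warning(
                    "pig %s: cycle %s omitted (missing TN or HS phenotype)",
                    pig_id,
                    hs_lab,
                )
                continue
            rows.append(
                {
                    "pig_id": pig_id,
                    "cycle": hs_lab,
                    "loss_bwg_kgd": hs["bwg_kgd"] - tn["bwg_kgd"],
                    "loss_fi_kgd": hs["fi_kgd"] - tn["fi_kgd"],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DerivedTables:
    """Bundle of derived per-period phenotypes and per-cycle losses."""

    phenotypes: pd.DataFrame
    losses: pd.DataFrame


def derive_all(
    bw_table: pd.DataFrame,
    daily_fi_table: pd.DataFrame,
    scan_table: pd.DataFrame,
    schedule: ExperimentSchedule,
    method: str = "sequential",
) -> DerivedTables:
    """Boundary completion + period phenotypes + losses in one call."""
    completed = estimate_boundary_bw(bw_table, schedule, method=method)
    phen = derive_period_phenotypes(completed, daily_fi_table, scan_table, schedule)
    losses = compute_losses(phen, schedule)
    return DerivedTables(phenotypes=phen, losses=losses)
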