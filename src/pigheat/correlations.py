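"""Partial correlations among derived traits after design adjustment.

All trait correlations are computed after residualising both traits on the
design factors (line, diet, room; plus period/cycle where values are
pooled), i.e. Pearson correlations of OLS residuals, with degrees of
freedom reduced by the number of adjuster columns.  This mirrors how
repeatability of the heat-stress response and the production/robustness
trade-off are quantified in this kind of study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .study_design import ExperimentSchedule

__all__ = ["PartialCorrResult", "partial_corr", "trait_correlation_report",
           "pooled_tradeoff_correlation", "CorrelationError"]


class CorrelationError(ValueError):
    pass


@dataclass
class PartialCorrResult:
    trait_x: str
    trait_y: str
    adjusters: tuple
    r: float
    df: int
    p: float
    n: int


def _adjuster_design(data: pd.DataFrame, adjusters) -> np.ndarray:
    cols = [np.ones((len(data), 1))]
    for a in adjusters:
        s = data[a]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            levels = sorted(s.astype(str).unique())
            for lev in levels[1:]:
                cols.append((s.astype(str) == lev).to_numpy(float)[:, None])
        else:
            cols.append(np.asarray(s, float)[:, None])
    return np.hstack(cols)


def partial_corr(
    x: str, y: str, adjusters, data: pd.DataFrame
) -> PartialCorrResult:
    """Pearson correlation of ``x`` and ``y`` after removing the adjusters.

    Factors are dummy-coded, covariates enter linearly.  The p-value comes
    from ``t = r * sqrt(df / (1 - r^2))`` with ``df = n - 2 - k`` where ``k``
    is the number of (non-intercept) adjuster columns.  With no adjusters
    this is the plain Pearson correlation.
    """
    adjusters = tuple(adjusters)
    d = data.dropna(subset=[x, y, *adjusters])
    n = len(d)
    D = _adjuster_design(d, adjusters)
    k = D.shape[1] - 1
    if n <= k + 2:
        raise CorrelationError(
            f"need n > {k + 2} complete rows for {len(adjusters)} adjusters, got {n}"
        )
    xv = np.asarray(d[x], float)
    yv = np.asarray(d[y], float)
    bx, *_ = np.linalg.lstsq(D, xv, rcond=None)
    by, *_ = np.linalg.lstsq(D, yv, rcond=None)
    rx = xv - D @ bx
    ry = yv - D @ by
    sx, sy = float(rx @ rx), float(ry @ ry)
    if sx <= 1e-12 * (float(xv @ xv) + 1.0) or sy <= 1e-12 * (float(yv @ yv) + 1.0):
        raise CorrelationError("zero residual variance; correlation undefined")
    r = float((rx @ ry) / np.sqrt(sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return PartialCorrResult(x, y, adjusters, r, df, p, n)


_DESIGN_ADJ = ("line", "diet", "room")


def _wide(df: pd.DataFrame, index: str, columns: str, values: str) -> pd.DataFrame:
    return df.pivot_table(index=index, columns=columns, values=values, aggfunc="first")


def pooled_tradeoff_correlation(
    phenotypes: pd.DataFrame,
    losses: pd.DataFrame,
    pigs: pd.DataFrame,
    schedule: ExperimentSchedule,
    trait: str = "bwg_kgd",
    loss_trait: str = "loss_bwg_kgd",
) -> PartialCorrResult:
    """Pooled correlation between TN-period performance and the next HS drop.

    Stacks (TN value, following-cycle loss) pairs over all HS cycles and
    correlates them after adjusting for line, diet, room and cycle (the
    pooled values are additionally adjusted for period).
    """
    wide = _wide(phenotypes, "pig_id", "period", trait)
    lw = _wide(losses, "pig_id", "cycle", loss_trait)
    meta = pigs.set_index("pig_id")
    frames = []
    for tn_lab, hs_lab in schedule.tn_hs_pairs():
        if tn_lab not in wide.columns or hs_lab not in lw.columns:
            continue
        sub = pd.DataFrame({"x": wide[tn_lab], "y": lw[hs_lab]})
        sub["cycle"] = hs_lab
        frames.append(sub.join(meta[["line", "diet", "room"]]))
    stacked = pd.concat(frames).reset_index(drop=True)
    stacked["room"] = stacked["room"].astype(str)
    return partial_corr("x", "y", _DESIGN_ADJ + ("cycle",), stacked)


def trait_correlation_report(
    phenotypes: pd.DataFrame,
    losses: pd.DataFrame,
    slaughter: pd.DataFrame,
    pigs: pd.DataFrame,
    scans: pd.DataFrame,
    schedule: ExperimentSchedule,
) -> pd.DataFrame:
    """The study's correlation families as one tidy table.

    Families: BWG across TN periods; BWG across HS periods; BWG in
    consecutive periods; LossBWG / LossFI repeatability across cycles;
    TN BWG vs the following cycle's LossBWG (per cycle and pooled); mean
    LossFI and mean LossBWG vs carcass traits (backfat at both scans, lean
    percentage, loin depth, hot carcass weight).  Per-cycle correlations
    adjust for line, diet and room; pooled values additionally for cycle.
    """
    meta = pigs.set_index("pig_id")[["line", "diet", "room"]].copy()
    meta["room"] = meta["room"].astype(str)
    bwg = _wide(phenotypes, "pig_id", "period", "bwg_kgd").join(meta)
    lbw = _wide(losses, "pig_id", "cycle", "loss_bwg_kgd")
    lfi = _wide(losses, "pig_id", "cycle", "loss_fi_kgd")
    rows = []

    def add(family, x, y, res, cycle=""):
        rows.append(
            {
                "family": family, "x": x, "y": y, "cycle": cycle,
                "adjusters": "+".join(res.adjusters),
                "r": res.r, "df": res.df, "p": res.p, "n": res.n,
            }
        )

    tn_periods = [p.label for p in schedule.periods if p.climate == "TN"]
    hs_periods = schedule.hs_cycles
    for fam, labels in (("bwg_tn", tn_periods), ("bwg_hs", hs_periods)):
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = labels[i], labels[j]
                if a in bwg.columns and b in bwg.columns:
                    add(fam, f"bwg_{a}", f"bwg_{b}", partial_corr(a, b, _DESIGN_ADJ, bwg))
    all_periods = [p.label for p in schedule.periods]
    for a, b in zip(all_periods[:-1], all_periods[1:]):
        if a in bwg.columns and b in bwg.columns:
            add("bwg_consecutive", f"bwg_{a}", f"bwg_{b}",
                partial_corr(a, b, _DESIGN_ADJ, bwg))

    for fam, lw in (("loss_bwg_repeat", lbw), ("loss_fi_repeat", lfi)):
        d = lw.join(meta)
        cyc = [c for c in hs_periods if c in lw.columns]
        for i in range(len(cyc)):
            for j in range(i + 1, len(cyc)):
                add(fam, f"{fam}_{cyc[i]}", f"{fam}_{cyc[j]}",
                    partial_corr(cyc[i], cyc[j], _DESIGN_ADJ, d))

    lbj = bwg.join(lbw.add_prefix("loss_"))
    for tn_lab, hs_lab in schedule.tn_hs_pairs():
        if tn_lab in lbj.columns and f"loss_{hs_lab}" in lbj.columns:
            add("tradeoff", f"bwg_{tn_lab}", f"loss_bwg_{hs_lab}",
                partial_corr(tn_lab, f"loss_{hs_lab}", _DESIGN_ADJ, lbj), cycle=hs_lab)
    add("tradeoff", "bwg_tn", "loss_bwg_next",
        pooled_tradeoff_correlation(phenotypes, losses, pigs, schedule),
        cycle="pooled")

    # mean losses vs carcass traits
    carcass = slaughter.set_index("pig_id").join(meta)
    sc = scans.pivot_table(index="pig_id", columns="day", values="bft_mm")
    sc.columns = [f"bft_d{int(c)}" for c in sc.columns]
    carcass = carcass.join(sc)
    carcass["mean_loss_fi"] = lfi.mean(axis=1)
    carcass["mean_loss_bwg"] = lbw.mean(axis=1)
    targets = [c for c in carcass.columns if c.startswith("bft_d")]
    targets += [c for c in ("lean_pct", "loind_mm", "hcw_kg") if c in carcass.columns]
    for mean_loss in ("mean_loss_fi", "mean_loss_bwg"):
        for tgt in targets:
            try:
                add("loss_vs_carcass", mean_loss, tgt,
                    partial_corr(mean_loss, tgt, _DESIGN_ADJ, carcass))
            except CorrelationError:
                continue
    return pd.DataFrame(rows)
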